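"""End-to-end composition of the measurement-side stages."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from . import identification, morphometrics
from .identification import AssignmentResult, ConsensusKaryotype
from .types import ChromatidMeasurement, ChromosomeMetrics, KaryotypeTemplate


def analyze_karyotype(
    measurements: Iterable[ChromatidMeasurement],
    template: KaryotypeTemplate,
    ambiguity_tol: float = identification.DEFAULT_AMBIGUITY_TOL,
) -> tuple[ConsensusKaryotype, list[AssignmentResult], list[ChromosomeMetrics]]:
    """Measurements -> metrics -> per-metaphase assignment -> consensus.

    Metaphases whose chromosome count differs from the template's expected
    2n are reported as outliers and excluded from assignment (they cannot
    be matched one-to-one against the template), but still count toward the
    modal chromosome number.
    """
    metrics = morphometrics.metaphase_metrics(measurements)
    by_metaphase: dict[str, list[ChromosomeMetrics]] = defaultdict(list)
    for m in metrics:
        by_metaphase[m.metaphase_id].append(m)

    results: list[AssignmentResult] = []
    for mid in sorted(by_metaphase):
        ms = by_metaphase[mid]
        if len(ms) != template.n_chromosomes:
            continue
        results.append(
            identification.assign_chromosomes(ms, template, ambiguity_tol)
        )
    consensus = identification.consensus_karyotype(dict(by_metaphase), results)
    return consensus, results, metrics
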