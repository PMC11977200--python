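"""Template-based chromosome identification.

Each measured chromosome of a metaphase is matched to a karyotype-template
type by globally optimal bipartite assignment in normalized (l, i) feature
space, with template types duplicated once per ploidy copy.  This replaces
the manual template comparison of classical karyotyping with a
deterministic, permutation-invariant optimum.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import (
    CardinalityError,
    ChromosomeMetrics,
    KaryotypeTemplate,
    MorphSummary,
)
from . import morphometrics

DEFAULT_AMBIGUITY_TOL = 0.05  # normalized-cost units


@dataclass
class AssignmentResult:
    """Optimal object -> type mapping for one metaphase."""

    metaphase_id: str
    mapping: dict[str, str]  # object_id -> type_label
    total_cost: float
    per_object_cost: dict[str, float]
    ambiguous: set[str] = field(default_factory=set)


def _feature_space(template: KaryotypeTemplate) -> tuple[np.ndarray, np.ndarray]:
    """Template (l, i) points and per-axis scale (std of template values)."""
    pts = np.array([[r.l_pct_median, r.i_median] for r in template.rows], float)
    scale = pts.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return pts, scale


def assignment_cost_matrix(
    metrics: Sequence[ChromosomeMetrics], template: KaryotypeTemplate
) -> np.ndarray:
    """Euclidean distances in (l/sigma_l, i/sigma_i) space between measured
    chromosomes (rows) and template types (columns, one per type)."""
    pts, scale = _feature_space(template)
    obs = np.array([[m.l_pct, m.i] for m in metrics], float)
    diff = obs[:, None, :] - pts[None, :, :]
    return np.sqrt(((diff / scale) ** 2).sum(axis=2))


def assign_chromosomes(
    metrics: Sequence[ChromosomeMetrics],
    template: KaryotypeTemplate,
    ambiguity_tol: float = DEFAULT_AMBIGUITY_TOL,
) -> AssignmentResult:
    """Assign all chromosomes of one metaphase to template types.

    The assignment minimizes the summed normalized (l, i) distance, with
    each type receiving exactly ``ploidy_copies`` objects.  Objects whose
    best and second-best type distances differ by less than
    ``ambiguity_tol`` are flagged ambiguous.
    """
    mids = {m.metaphase_id for m in metrics}
    if len(mids) > 1:
        raise CardinalityError(f"metrics from multiple metaphases: {sorted(mids)}")
    expected = template.n_chromosomes
    if len(metrics) != expected:
        raise CardinalityError(
            f"expected {expected} chromosomes "
            f"({len(template.rows)} types x {template.ploidy_copies} copies), "
            f"got {len(metrics)}"
        )
    # canonical order for determinism under input permutation
    ordered = sorted(metrics, key=lambda m: m.object_id)

    base_cost = assignment_cost_matrix(ordered, template)
    labels = template.type_labels
    # duplicate each type column once per ploidy copy, lexicographic order
    col_order = sorted(range(len(labels)), key=lambda j: labels[j])
    cols = [j for j in col_order for _ in range(template.ploidy_copies)]
    cost = base_cost[:, cols]

    row_ind, col_ind = linear_sum_assignment(cost)
    mapping: dict[str, str] = {}
    per_object: dict[str, float] = {}
    ambiguous: set[str] = set()
    for r, c in zip(row_ind, col_ind):
        obj = ordered[r].object_id
        mapping[obj] = labels[cols[c]]
        per_object[obj] = float(cost[r, c])
        best_two = np.partition(base_cost[r], 1)[:2]
        if best_two[1] - best_two[0] < ambiguity_tol:
            ambiguous.add(obj)
    return AssignmentResult(
        metaphase_id=mids.pop() if mids else "",
        mapping=mapping,
        total_cost=float(cost[row_ind, col_ind].sum()),
        per_object_cost=per_object,
        ambiguous=ambiguous,
    )


def apply_assignment(
    metrics: Sequence[ChromosomeMetrics], result: AssignmentResult
) -> list[ChromosomeMetrics]:
    """Return metrics with ``assigned_type`` filled from an assignment."""
    out = []
    for m in metrics:
        m.assigned_type = result.mapping[m.object_id]
        out.append(m)
    return out


@dataclass
class ConsensusKaryotype:
    """Karyotype reconstructed from several assigned metaphases."""

    two_n: int  # modal chromosome count per metaphase
    counts_per_metaphase: dict[str, int]
    outlier_metaphases: list[str]
    summary: MorphSummary
    category_census: Counter  # category -> number of types (haploid)


def consensus_karyotype(
    metrics_by_metaphase: dict[str, Sequence[ChromosomeMetrics]],
    results: Sequence[AssignmentResult],
) -> ConsensusKaryotype:
    """Combine assigned metaphases into 2n, per-type medians and a census
    of chromosome categories (from median centromeric indices)."""
    if not results:
        raise CardinalityError("no assigned metaphases")
    counts = {mid: len(ms) for mid, ms in metrics_by_metaphase.items()}
    modal = Counter(counts.values()).most_common(1)[0][0]
    outliers = sorted(mid for mid, n in counts.items() if n != modal)

    labeled: list[ChromosomeMetrics] = []
    by_mid = {r.metaphase_id: r for r in results}
    for mid, ms in metrics_by_metaphase.items():
        res = by_mid.get(mid)
        if res is None:
            continue
        labeled.extend(apply_assignment(list(ms), res))

    summary = morphometrics.aggregate(labeled)
    census = Counter(summary.categories.values())
    return ConsensusKaryotype(
        two_n=modal,
        counts_per_metaphase=counts,
        outlier_metaphases=outliers,
        summary=summary,
        category_census=census,
    )
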