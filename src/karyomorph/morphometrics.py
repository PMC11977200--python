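"""Chromosome morphometrics: per-chromosome metrics, Levan-interval
classification, quartile aggregation across metaphases, and homeolog
divergence statistics (IQR overlap and one-way ANOVA with Tukey HSD).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import (
    ChromatidMeasurement,
    ChromosomeMetrics,
    HomeologComparison,
    MorphSummary,
    PairingError,
    StatisticsError,
    SummaryRow,
    ValidationError,
    base_chromosome,
    significance_code,
)

logger = logging.getLogger(__name__)

METRICS = ("l_pct", "r1", "i")

# Levan-style category intervals on the centromeric-index (0-50) scale.
# Boundaries are inclusive on the left: i >= 37.5 metacentric, 25 <= i < 37.5
# submetacentric, 12.5 <= i < 25 subtelocentric, 0 < i < 12.5 acrocentric,
# i = 0 telocentric (no p arm).
META_BOUND = 37.5
SUBMETA_BOUND = 25.0
SUBTELO_BOUND = 12.5


def classify(i: float) -> str:
    """Classify a centromeric index into m/sm/st/a/t."""
    if not (0.0 <= i <= 50.0):
        raise ValidationError(f"centromeric index outside [0, 50]: {i}")
    if i >= META_BOUND:
        return "m"
    if i >= SUBMETA_BOUND:
        return "sm"
    if i >= SUBTELO_BOUND:
        return "st"
    if i > 0.0:
        return "a"
    return "t"


def chromatids_to_chromosome(
    chromatids: Sequence[ChromatidMeasurement],
) -> tuple[float, float]:
    """Average the two sister chromatids of one physical chromosome.

    Returns the (p, q) arm lengths as arithmetic means of the chromatid
    measurements.  A single chromatid passes through with a warning.
    """
    if not chromatids:
        raise PairingError("no chromatid measurements supplied")
    keys = {(c.metaphase_id, c.object_id) for c in chromatids}
    if len(keys) > 1:
        raise PairingError(f"chromatids from different objects: {sorted(keys)}")
    if len(chromatids) > 2:
        raise PairingError(f"more than two chromatids for object {keys.pop()}")
    if len(chromatids) == 1:
        logger.warning(
            "single chromatid for object %s; values pass through unaveraged",
            chromatids[0].object_id,
        )
    p = float(np.mean([c.p_len for c in chromatids]))
    q = float(np.mean([c.q_len for c in chromatids]))
    return p, q


def compute_metrics(
    p: float,
    q: float,
    metaphase_total: float,
    metaphase_id: str = "",
    object_id: str = "",
) -> ChromosomeMetrics:
    """Compute l (%), arm ratios and centromeric index for one chromosome.

    ``metaphase_total`` is the summed length (p+q over all chromosomes) of
    the metaphase, used to normalize l.  Inputs with p > q are swapped to
    enforce the short-arm orientation and flagged.
    """
    if metaphase_total <= 0:
        raise ValidationError(f"metaphase_total must be > 0, got {metaphase_total}")
    if p <= 0 or q <= 0:
        raise ValidationError(f"arm lengths must be positive, got p={p}, q={q}")
    swapped = p > q
    if swapped:
        p, q = q, p
    r1 = p / q
    return ChromosomeMetrics(
        metaphase_id=metaphase_id,
        object_id=object_id,
        p=p,
        q=q,
        l_pct=100.0 * (p + q) / metaphase_total,
        r1=r1,
        r2=q / p,
        i=100.0 * p / (p + q),
        category=classify(100.0 * p / (p + q)),
        arms_swapped=swapped,
    )


def metaphase_metrics(
    measurements: Iterable[ChromatidMeasurement],
) -> list[ChromosomeMetrics]:
    """Pair chromatids and compute metrics for every chromosome of every
    metaphase in a measurement table."""
    by_object: dict[tuple[str, str], list[ChromatidMeasurement]] = defaultdict(list)
    for m in measurements:
        by_object[(m.metaphase_id, m.object_id)].append(m)

    arms = {key: chromatids_to_chromosome(recs) for key, recs in by_object.items()}
    totals: dict[str, float] = defaultdict(float)
    for (mid, _), (p, q) in arms.items():
        totals[mid] += p + q

    return [
        compute_metrics(p, q, totals[mid], metaphase_id=mid, object_id=oid)
        for (mid, oid), (p, q) in sorted(arms.items())
    ]


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    # linear interpolation between order statistics (numpy default, "type 7")
    q1, q2, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(q2), float(q3)


def aggregate(
    metrics: Sequence[ChromosomeMetrics],
    valid_types: Optional[Sequence[str]] = None,
) -> MorphSummary:
    """Aggregate labeled per-chromosome metrics into per-type quartile
    summaries.  Medians are computed independently per metric (the median of
    i is not derived from the median of r1); the category of each type comes
    from its median i."""
    by_type: dict[str, list[ChromosomeMetrics]] = defaultdict(list)
    for m in metrics:
        if m.assigned_type is None:
            raise StatisticsError(
                f"unlabeled chromosome {m.object_id} in metaphase {m.metaphase_id}"
            )
        if valid_types is not None and m.assigned_type not in valid_types:
            raise StatisticsError(f"unknown type label {m.assigned_type!r}")
        by_type[m.assigned_type].append(m)

    rows: list[SummaryRow] = []
    categories: dict[str, str] = {}
    for type_label in sorted(by_type):
        group = by_type[type_label]
        for metric in METRICS:
            values = [getattr(m, metric) for m in group]
            q1, q2, q3 = _quartiles(values)
            rows.append(SummaryRow(type_label, metric, q1, q2, q3, len(values)))
            if metric == "i":
                categories[type_label] = classify(q2)
    return MorphSummary(rows=rows, categories=categories)


# --------------------------------------------------------------------------
# Homeolog divergence
# --------------------------------------------------------------------------

def homeolog_pairs(type_labels: Sequence[str]) -> list[tuple[str, str]]:
    """Pair chromosome types sharing a numeral across subgenomes
    (1L with 1S, ..., 9_10L with 9_10S).  Raises on orphans."""
    by_base: dict[str, list[str]] = defaultdict(list)
    for label in type_labels:
        by_base[base_chromosome(label)].append(label)
    pairs: list[tuple[str, str]] = []
    orphans: list[str] = []
    for base in sorted(by_base):
        members = sorted(by_base[base])
        if len(members) == 2:
            pairs.append((members[0], members[1]))
        else:
            orphans.extend(members)
    if orphans:
        raise PairingError(f"unpaired chromosome type(s): {orphans}")
    return pairs


def homeolog_divergence(summary: MorphSummary, metric: str = "l_pct") -> pd.DataFrame:
    """Per-homeolog-pair IQR comparison for one metric.

    Returns a DataFrame with the two Q1-Q3 intervals, a ``disjoint`` flag,
    the inter-interval gap (0 when overlapping) and a divergence rank
    ordering pairs by decreasing gap.
    """
    records = []
    for a, b in homeolog_pairs(summary.type_labels):
        ra, rb = summary.get(a, metric), summary.get(b, metric)
        gap = max(ra.q1, rb.q1) - min(ra.q3, rb.q3)
        records.append(
            {
                "pair": f"{a}|{b}",
                "metric": metric,
                "q1_a": ra.q1, "q3_a": ra.q3,
                "q1_b": rb.q1, "q3_b": rb.q3,
                "disjoint": gap > 0,
                "gap": max(0.0, gap),
            }
        )
    df = pd.DataFrame(records)
    df["divergence_rank"] = (
        df["gap"].rank(ascending=False, method="first").astype(int)
    )
    return df.sort_values("divergence_rank").reset_index(drop=True)


def homeolog_anova(
    metrics: Sequence[ChromosomeMetrics],
    metric: str = "l_pct",
    summary: Optional[MorphSummary] = None,
) -> list[HomeologComparison]:
    """One-way ANOVA across all chromosome-type groups followed by Tukey
    HSD over all pairwise contrasts, restricted to the homeolog pairs.

    The ANOVA is computed once over the full karyotype (all 18 groups),
    matching an analysis of the complete measurement table rather than
    per-pair tests.
    """
    if metric not in METRICS:
        raise StatisticsError(f"unknown metric {metric!r}")
    by_type: dict[str, list[float]] = defaultdict(list)
    for m in metrics:
        if m.assigned_type is None:
            raise StatisticsError("all chromosomes must carry assigned_type")
        by_type[m.assigned_type].append(getattr(m, metric))
    small = [t for t, vals in sorted(by_type.items()) if len(vals) < 2]
    if small:
        raise StatisticsError(f"fewer than 2 observations for group(s): {small}")

    groups = sorted(by_type)
    f_stat, p_val = stats.f_oneway(*(by_type[g] for g in groups))

    values = np.concatenate([by_type[g] for g in groups])
    labels = np.concatenate([[g] * len(by_type[g]) for g in groups])
    tukey = pairwise_tukeyhsd(values, labels)
    adj_p = {}
    for (g1, g2), p in zip(
        ((tukey.groupsunique[i], tukey.groupsunique[j])
         for i, j in zip(*np.triu_indices(len(tukey.groupsunique), k=1))),
        tukey.pvalues,
    ):
        adj_p[frozenset((g1, g2))] = float(p)

    iqr_overlap: dict[tuple[str, str], bool] = {}
    if summary is not None:
        div = homeolog_divergence(summary, metric=metric)
        for _, row in div.iterrows():
            a, b = row["pair"].split("|")
            iqr_overlap[(a, b)] = not bool(row["disjoint"])

    comparisons = []
    for a, b in homeolog_pairs(groups):
        p_adj = adj_p[frozenset((a, b))]
        comparisons.append(
            HomeologComparison(
                pair=(a, b),
                metric=metric,
                anova_f=float(f_stat),
                anova_p=float(p_val),
                tukey_adj_p=p_adj,
                significance=significance_code(p_adj),
                iqr_overlap=iqr_overlap.get((a, b)),
            )
        )
    return comparisons


def summary_frame(summary: MorphSummary) -> pd.DataFrame:
    """MorphSummary as a tidy DataFrame (type, metric, Q1, Q2, Q3, n,
    category-from-median-i)."""
    return pd.DataFrame(
        [
            {
                "type": r.type_label,
                "metric": r.metric,
                "Q1": r.q1,
                "Q2": r.q2,
                "Q3": r.q3,
                "n": r.n,
                "category": summary.categories.get(r.type_label, ""),
            }
            for r in summary.rows
        ]
    )
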