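"""Synthetic-data generation for every pipeline stage.

``generate_metaphases`` emulates pixel measurement of metaphase spreads:
between-metaphase magnification differences (lognormal spread scale),
multiplicative per-arm measurement noise, and within-chromosome chromatid
noise, around a karyotype template.  ``generate_marker_scenario`` applies
explicit rearrangement operations (translocation, end-to-end fusion,
pericentromeric inversion) to a duplicated two-copy reference marker map
and emits the ground-truth calls.  ``generate_signals`` draws a FISH
signal table with per-row dropout.  All generators are fully determined
by their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ChromatidMeasurement,
    ConfigError,
    FishSignal,
    KaryotypeTemplate,
    MarkerLocus,
    MarkerMap,
    ScenarioError,
    SimulationConfig,
    TemplateRow,
)


# --------------------------------------------------------------------------
# Metaphase measurements
# --------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV.

    Lognormal noise keeps arm lengths strictly positive, unlike additive
    Gaussian noise, which would require truncation.
    """
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def normalized_template(template: KaryotypeTemplate) -> KaryotypeTemplate:
    """Template with l rescaled so the full complement sums to exactly 100%.

    Published per-type medians need not sum exactly to the theoretical
    total (rounding); the generator works on the normalized template, so
    the noise-free pipeline is its exact inverse.
    """
    total = template.haploid_l_sum() * template.ploidy_copies
    factor = 100.0 / total
    rows = [replace(r, l_pct_median=r.l_pct_median * factor) for r in template.rows]
    return KaryotypeTemplate(rows=rows, ploidy_copies=template.ploidy_copies)


def generate_metaphases(
    config: SimulationConfig,
) -> tuple[list[ChromatidMeasurement], pd.DataFrame]:
    """Simulate per-chromatid arm measurements for ``n_metaphases`` spreads.

    Returns the measurement records and a sidecar truth table
    (metaphase_id, object_id, type_label, true p/q in pixels).  Object ids
    are shuffled within each metaphase so they carry no type information.
    """
    rng = np.random.default_rng(config.seed)
    template = normalized_template(config.template)
    types = [
        row for row in template.rows for _ in range(template.ploidy_copies)
    ]
    n_obj = len(types)

    records: list[ChromatidMeasurement] = []
    truth_rows = []
    for m in range(config.n_metaphases):
        mid = f"M{m + 1:02d}"
        scale = config.scale_mean_px * _lognormal_factor(rng, config.scale_cv, ())
        order = rng.permutation(n_obj)
        for slot, idx in enumerate(order):
            row = types[idx]
            oid = f"obj{slot + 1:02d}"
            length = scale * row.l_pct_median / 100.0
            p_true = length * row.i_median / 100.0
            q_true = length * (1.0 - row.i_median / 100.0)
            p_obs = p_true * _lognormal_factor(rng, config.arm_noise_cv, ())
            q_obs = q_true * _lognormal_factor(rng, config.arm_noise_cv, ())
            for chromatid in (1, 2):
                records.append(
                    ChromatidMeasurement(
                        metaphase_id=mid,
                        object_id=oid,
                        chromatid_index=chromatid,
                        p_len=float(
                            p_obs * _lognormal_factor(rng, config.chromatid_noise_cv, ())
                        ),
                        q_len=float(
                            q_obs * _lognormal_factor(rng, config.chromatid_noise_cv, ())
                        ),
                    )
                )
            truth_rows.append(
                {
                    "metaphase_id": mid,
                    "object_id": oid,
                    "type_label": row.type_label,
                    "p_true": float(p_true),
                    "q_true": float(q_true),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth


# --------------------------------------------------------------------------
# Marker-map scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Translocate:
    """Move one gene to the proximal (pericentromeric) end of another
    chromosome's arm, in one subgenome copy (or all when copy is None)."""

    gene: str
    dest_chromosome: str
    dest_arm: str = "q"
    copy: Optional[str] = None


@dataclass(frozen=True)
class Fuse:
    """End-to-end fusion of two chromosomes through the given arms.

    ``retained`` names the chromosome whose centromere persists.  The fused
    arm of the product (retained's fused arm extended by the whole lost
    chromosome) is labeled q; the retained chromosome's other arm becomes p.
    """

    chrom_a: str
    arm_a: str
    chrom_b: str
    arm_b: str
    retained: str
    copy: Optional[str] = None

    def __post_init__(self) -> None:
        if self.retained not in (self.chrom_a, self.chrom_b):
            raise ScenarioError(
                f"retained centromere {self.retained!r} is neither fused chromosome"
            )


@dataclass(frozen=True)
class Invert:
    """Pericentromeric inversion spanning ``p_depth`` proximal markers of
    the p arm and ``q_depth`` proximal markers of the q arm."""

    chromosome: str
    p_depth: int
    q_depth: int
    copy: Optional[str] = None


ScenarioSpec = Union[Translocate, Fuse, Invert]

_Slot = tuple[str, str]  # (gene, region)


class _CopyState:
    """Mutable per-copy arrangement: chromosome -> arm -> ordered genes."""

    def __init__(self, reference: MarkerMap):
        self.chroms: dict[str, dict[str, list[_Slot]]] = {}
        for locus in sorted(
            reference.loci,
            key=lambda l: (l.chromosome, l.arm, l.rank if l.rank is not None else 10**6),
        ):
            arms = self.chroms.setdefault(locus.chromosome, {"p": [], "q": []})
            arms[locus.arm].append((locus.gene, locus.region))

    def find(self, gene: str) -> tuple[str, str, int]:
        for chrom, arms in self.chroms.items():
            for arm, slots in arms.items():
                for k, (g, _) in enumerate(slots):
                    if g == gene:
                        return chrom, arm, k
        raise ScenarioError(f"gene {gene!r} not present")

    def translocate(self, spec: Translocate) -> None:
        chrom, arm, k = self.find(spec.gene)
        slot = self.chroms[chrom][arm].pop(k)
        if spec.dest_chromosome not in self.chroms:
            raise ScenarioError(f"chromosome {spec.dest_chromosome!r} not present")
        dest = self.chroms[spec.dest_chromosome][spec.dest_arm]
        dest.insert(0, (slot[0], "pericentromeric"))

    def fuse(self, spec: Fuse) -> str:
        for chrom in (spec.chrom_a, spec.chrom_b):
            if chrom not in self.chroms:
                raise ScenarioError(f"chromosome {chrom!r} not present")
        lost = spec.chrom_b if spec.retained == spec.chrom_a else spec.chrom_a
        arm_ret = spec.arm_a if spec.retained == spec.chrom_a else spec.arm_b
        arm_lost = spec.arm_b if spec.retained == spec.chrom_a else spec.arm_a
        ret_arms = self.chroms.pop(spec.retained)
        lost_arms = self.chroms.pop(lost)
        other_ret = "q" if arm_ret == "p" else "p"
        other_lost = "q" if arm_lost == "p" else "p"
        fused = (
            ret_arms[arm_ret]
            + list(reversed(lost_arms[arm_lost]))
            + lost_arms[other_lost]
        )
        new_label = f"{spec.chrom_a}_{spec.chrom_b}"
        self.chroms[new_label] = {"p": ret_arms[other_ret], "q": fused}
        return new_label

    def invert(self, spec: Invert) -> None:
        if spec.chromosome not in self.chroms:
            raise ScenarioError(f"chromosome {spec.chromosome!r} not present")
        arms = self.chroms[spec.chromosome]
        p, q = arms["p"], arms["q"]
        if spec.p_depth > len(p) or spec.q_depth > len(q):
            raise ScenarioError(
                f"inversion depth exceeds marker count on {spec.chromosome}"
            )
        new_p = q[: spec.q_depth] + p[spec.p_depth:]
        new_q = p[: spec.p_depth] + q[spec.q_depth:]
        arms["p"], arms["q"] = new_p, new_q

    def loci(self, species: str, copy_tag: str) -> list[MarkerLocus]:
        out = []
        for chrom in sorted(self.chroms):
            for arm in ("p", "q"):
                for rank, (gene, region) in enumerate(self.chroms[chrom][arm], 1):
                    out.append(
                        MarkerLocus(
                            species=species,
                            gene=gene,
                            chromosome=f"{chrom}{copy_tag}",
                            arm=arm,
                            rank=rank,
                            region=region,
                            copy=copy_tag,
                        )
                    )
        return out


def generate_marker_scenario(
    reference: MarkerMap,
    scenario: Sequence[ScenarioSpec],
    seed: int = 0,
    copy_tags: tuple[str, str] = ("L", "S"),
    species: str = "simulated",
) -> tuple[MarkerMap, list[dict]]:
    """Apply rearrangement specs to a duplicated two-copy reference map.

    Returns the target map and the ground-truth call list (one dict per
    spec with the fields the corresponding detector should recover).  The
    ``seed`` is accepted for interface uniformity; the construction itself
    is deterministic.
    """
    states = {tag: _CopyState(reference) for tag in copy_tags}
    truth: list[dict] = []
    for spec in scenario:
        tags = copy_tags if spec.copy is None else (spec.copy,)
        for tag in tags:
            if tag not in states:
                raise ScenarioError(f"unknown copy tag {tag!r}")
            if isinstance(spec, Translocate):
                src = states[tag].find(spec.gene)[0]
                states[tag].translocate(spec)
                truth.append(
                    {
                        "kind": "translocation",
                        "copy": tag,
                        "gene": spec.gene,
                        "source": src,
                        "destination": spec.dest_chromosome,
                    }
                )
            elif isinstance(spec, Fuse):
                label = states[tag].fuse(spec)
                lost = spec.chrom_b if spec.retained == spec.chrom_a else spec.chrom_a
                arm_lost = spec.arm_b if spec.retained == spec.chrom_a else spec.arm_a
                arm_ret = spec.arm_a if spec.retained == spec.chrom_a else spec.arm_b
                truth.append(
                    {
                        "kind": "fusion",
                        "copy": tag,
                        "target_chromosome": f"{label}{tag}",
                        "fused_arms": (arm_lost, arm_ret),
                        "centromere_lost": lost,
                        "centromere_retained": spec.retained,
                    }
                )
            elif isinstance(spec, Invert):
                states[tag].invert(spec)
                truth.append(
                    {
                        "kind": "inversion",
                        "copy": tag,
                        "chromosome": f"{spec.chromosome}{tag}",
                    }
                )
            else:  # pragma: no cover - guarded by type union
                raise ScenarioError(f"unknown scenario spec {spec!r}")
    loci = [
        locus for tag in copy_tags for locus in states[tag].loci(species, tag)
    ]
    return MarkerMap(species=species, loci=loci, role="target"), truth


# --------------------------------------------------------------------------
# FISH signal tables
# --------------------------------------------------------------------------

def generate_signals(
    template: KaryotypeTemplate,
    pattern: Sequence[FishSignal],
    dropout_prob: float = 0.0,
    seed: int = 0,
) -> list[FishSignal]:
    """Draw a FISH signal table from a placement pattern with per-row
    dropout at ``dropout_prob`` (simulating hybridization failure)."""
    if not 0.0 <= dropout_prob <= 1.0:
        raise ConfigError(f"dropout_prob must be in [0, 1], got {dropout_prob}")
    valid = set(template.type_labels)
    for s in pattern:
        if s.chromosome not in valid:
            raise ScenarioError(f"pattern places probe on unknown type {s.chromosome!r}")
    rng = np.random.default_rng(seed)
    return [s for s in pattern if rng.random() >= dropout_prob]
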