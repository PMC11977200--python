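"""Domain types shared across the pipeline.

The objects here mirror the quantities of classical karyomorphometry
(Levan-style arm measurements and centromeric indices), FISH marker maps
at arm+rank resolution, and NOR character states on a species phylogeny.
All lengths are in pixels; chromosome length ``l`` is expressed as a
percentage of the total metaphase length; the centromeric index ``i`` is
the short-arm percentage, 100*p/(p+q), on the 0-50 scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class KaryomorphError(Exception):
    """Base class for all package errors."""


class SchemaError(KaryomorphError):
    """A tabular input is missing required columns."""


class ValidationError(KaryomorphError):
    """A record violates a domain invariant."""


class PairingError(KaryomorphError):
    """Records that should refer to the same object do not."""


class CardinalityError(KaryomorphError):
    """An input has the wrong number of objects."""


class StatisticsError(KaryomorphError):
    """A statistical routine received degenerate input."""


class ScenarioError(KaryomorphError):
    """A simulation scenario references absent genes or chromosomes."""


class ConfigError(KaryomorphError):
    """A simulation or run configuration is invalid."""


# --------------------------------------------------------------------------
# Chromosome label helpers
# --------------------------------------------------------------------------

_SUBGENOME_RE = re.compile(r"^(.*?[0-9_]+)([LSab])$")


def parse_subgenome(label: str) -> str:
    """Parse the subgenome tag from a trailing L/S (subgenus *Xenopus*)
    or a/b (subgenus *Silurana*) suffix of a chromosome label.

    Returns "none" for untagged labels such as "7" or "9".
    """
    m = _SUBGENOME_RE.match(label)
    return m.group(2) if m else "none"


def base_chromosome(label: str) -> str:
    """Chromosome label with any subgenome suffix stripped ("9_10L" -> "9_10")."""
    m = _SUBGENOME_RE.match(label)
    return m.group(1) if m else label


CATEGORIES = ("m", "sm", "st", "a", "t")
ARMS = ("p", "q")
REGIONS = ("telomeric", "pericentromeric", "interstitial", "unknown")


# --------------------------------------------------------------------------
# Measurement-side types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatidMeasurement:
    """Raw p/q arm lengths (pixels) of one chromatid in one metaphase."""

    metaphase_id: str
    object_id: str
    chromatid_index: int
    p_len: float
    q_len: float

    def __post_init__(self) -> None:
        if self.chromatid_index not in (1, 2):
            raise ValidationError(
                f"chromatid_index must be 1 or 2, got {self.chromatid_index}"
            )
        if not (self.p_len > 0 and self.q_len > 0):
            raise ValidationError(
                f"arm lengths must be positive, got p={self.p_len}, q={self.q_len} "
                f"(metaphase {self.metaphase_id}, object {self.object_id})"
            )


@dataclass
class ChromosomeMetrics:
    """Derived morphometrics of one measured chromosome.

    ``p`` and ``q`` are chromatid-averaged arm lengths in pixels, oriented so
    that p <= q (a swap of violating inputs is recorded in ``arms_swapped``).
    """

    metaphase_id: str
    object_id: str
    p: float
    q: float
    l_pct: float
    r1: float
    r2: float
    i: float
    category: str
    assigned_type: Optional[str] = None
    arms_swapped: bool = False

    def __post_init__(self) -> None:
        if self.p > self.q:
            raise ValidationError("orientation rule violated: p > q after construction")
        if not (0 < self.i <= 50):
            raise ValidationError(f"centromeric index out of (0, 50]: {self.i}")
        if abs(self.r1 * self.r2 - 1.0) > 1e-9:
            raise ValidationError("arm ratios inconsistent: r1*r2 != 1")
        if abs(self.i - 100.0 * self.r1 / (1.0 + self.r1)) > 1e-9:
            raise ValidationError("i inconsistent with r1")


@dataclass(frozen=True)
class TemplateRow:
    type_label: str
    l_pct_median: float
    i_median: float
    category: str
    subgenome: str = "none"


@dataclass
class KaryotypeTemplate:
    """Per-chromosome-type reference medians used for identification and
    simulation.  ``l_pct_median`` is the per-chromosome percentage of the
    total (diploid) metaphase length, so the rows of a complete template sum
    to ~100/ploidy_copies."""

    rows: list[TemplateRow]
    ploidy_copies: int = 2

    def __post_init__(self) -> None:
        labels = [r.type_label for r in self.rows]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate type_label in template")
        if self.ploidy_copies < 1:
            raise ValidationError("ploidy_copies must be >= 1")

    @property
    def type_labels(self) -> list[str]:
        return [r.type_label for r in self.rows]

    @property
    def n_chromosomes(self) -> int:
        """Expected chromosome count per metaphase (2n)."""
        return len(self.rows) * self.ploidy_copies

    def row(self, label: str) -> TemplateRow:
        for r in self.rows:
            if r.type_label == label:
                return r
        raise KeyError(label)

    def haploid_l_sum(self) -> float:
        return sum(r.l_pct_median for r in self.rows)


@dataclass(frozen=True)
class SummaryRow:
    """Quartile summary of one metric for one chromosome type."""

    type_label: str
    metric: str  # l_pct | r1 | i
    q1: float
    q2: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.q2 <= self.q3):
            raise ValidationError(
                f"quartiles out of order for {self.type_label}/{self.metric}"
            )
        if self.n < 1:
            raise ValidationError("n must be >= 1")


@dataclass
class MorphSummary:
    """Per-type medians and interquartile ranges across metaphases."""

    rows: list[SummaryRow]
    categories: dict[str, str] = field(default_factory=dict)  # from median i

    def get(self, type_label: str, metric: str) -> SummaryRow:
        for r in self.rows:
            if r.type_label == type_label and r.metric == metric:
                return r
        raise KeyError((type_label, metric))

    @property
    def type_labels(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.type_label not in seen:
                seen.append(r.type_label)
        return seen


def significance_code(p: float) -> str:
    """Map an adjusted p-value to the conventional significance code."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class HomeologComparison:
    """ANOVA/Tukey contrast between a pair of homeologous chromosomes."""

    pair: tuple[str, str]
    metric: str
    anova_f: float
    anova_p: float
    tukey_adj_p: float
    significance: str
    iqr_overlap: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.significance != significance_code(self.tukey_adj_p):
            raise ValidationError("significance code inconsistent with tukey_adj_p")


# --------------------------------------------------------------------------
# Marker / FISH types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerLocus:
    """One gene placement on a chromosome arm, at rank resolution.

    ``rank`` counts 1-based from the centromere outward; ``copy`` is the
    subgenome copy tag (L/S or a/b) of the probe, or "none" when the copy
    could not be assigned.
    """

    species: str
    gene: str
    chromosome: str
    arm: str
    rank: Optional[int] = None
    region: str = "unknown"
    copy: str = "none"

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm code {self.arm!r} for {self.gene}")
        if self.rank is not None and self.rank < 1:
            raise ValidationError(f"rank must be >= 1, got {self.rank}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} for {self.gene}")

    @property
    def effective_copy(self) -> str:
        """Copy tag, falling back to the chromosome's subgenome suffix.

        FISH probes whose homeologous copy is unresolved (copy="none") are
        attributed to the subgenome of the chromosome they hybridize to.
        """
        if self.copy != "none":
            return self.copy
        return parse_subgenome(self.chromosome)


@dataclass
class MarkerMap:
    """The set of gene placements for one species."""

    species: str
    loci: list[MarkerLocus]
    role: str = "target"  # reference | target

    def __post_init__(self) -> None:
        keys = [(l.gene, l.copy, l.chromosome) for l in self.loci]
        if len(keys) != len(set(keys)):
            raise ValidationError(
                f"duplicate (gene, copy, chromosome) entry in map for {self.species}"
            )
        # a resolved copy of a gene may appear only once in the whole map
        tagged = [(l.gene, l.copy) for l in self.loci if l.copy != "none"]
        if len(tagged) != len(set(tagged)):
            raise ValidationError(
                f"duplicate (gene, copy) entry in map for {self.species}"
            )

    @property
    def genes(self) -> set[str]:
        return {l.gene for l in self.loci}


@dataclass(frozen=True)
class FishSignal:
    """One FISH signal: a probe on a chromosome arm region."""

    probe: str
    chromosome: str
    arm: str  # p | q | both
    region: str
    intensity: str = "normal"

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q", "both"):
            raise ValidationError(f"unknown arm code {self.arm!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.intensity not in ("normal", "low"):
            raise ValidationError(f"unknown intensity {self.intensity!r}")


@dataclass(frozen=True)
class SyntenyGroup:
    """Genes of one reference chromosome, ordered by (arm, rank)."""

    chromosome: str
    loci: tuple[MarkerLocus, ...]


@dataclass
class RearrangementCall:
    """One inferred rearrangement (or its explicit absence).

    ``kind`` is one of translocation | fusion | inversion | none.
    ``details`` carries kind-specific structure (fused arms and centromere
    fate for fusions; inverted homeolog and polarity source for inversions).
    Markers inconsistent with the chosen model are listed in ``conflicts``
    and never dropped.
    """

    kind: str
    reference_chromosomes: tuple[str, ...]
    target_chromosome: Optional[str]
    copy: str
    genes: tuple[str, ...]
    details: dict = field(default_factory=dict)
    conflicts: tuple[str, ...] = ()
    confidence: str = "normal"  # normal | low

    def __post_init__(self) -> None:
        if self.kind not in ("translocation", "fusion", "inversion", "none"):
            raise ValidationError(f"unknown rearrangement kind {self.kind!r}")
        if self.kind == "fusion" and len(self.reference_chromosomes) != 2:
            raise ValidationError("fusion requires exactly two reference chromosomes")


@dataclass
class RdnaSummary:
    """Karyotype-level summary of 28S (NOR) and 5S rDNA FISH signals."""

    nor_count: int
    nor_locations: list[tuple[str, str, str]]  # (chromosome, arm, region)
    five_s_missing: list[str]
    both_arm_5s: list[str]
    colocalized: list[str]
    low_intensity: list[str]

    def __post_init__(self) -> None:
        if self.nor_count != len({c for c, _, _ in self.nor_locations}):
            raise ValidationError("nor_count inconsistent with nor_locations")


# --------------------------------------------------------------------------
# Phylogeny-side types
# --------------------------------------------------------------------------

@dataclass
class NorStateMap:
    """species -> NOR-bearing chromosome label (one state per species)."""

    states: dict[str, str]

    def __post_init__(self) -> None:
        for sp, st in self.states.items():
            if not st:
                raise ValidationError(f"empty NOR state for {sp}")


@dataclass
class ParsimonyResult:
    """Result of unordered-state parsimony on the species tree."""

    min_changes: int
    ancestral_sets: dict[str, frozenset[str]]  # node key -> optimal state set
    edges_forced: list[tuple[str, str]]  # change in ALL most-parsimonious recons
    edges_possible: list[tuple[str, str]]  # change in >=1 reconstruction
    reconstruction: dict[str, str]  # one deterministic MPR: node key -> state
    changes: list[tuple[str, str, str, str]]  # (parent, child, from_state, to_state)


@dataclass
class JumpReport:
    """Census of NOR relocation events by subgenome class."""

    intra_subgenome: int
    inter_subgenome: int
    unclassified: int
    events: list[dict]

    @property
    def total(self) -> int:
        return self.intra_subgenome + self.inter_subgenome + self.unclassified


# --------------------------------------------------------------------------
# Simulation config
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the metaphase-measurement simulator.

    Defaults emulate the study design: 11 metaphases of a 2n = 36 karyotype,
    ~5% multiplicative arm-measurement noise, ~2% chromatid-level noise and
    ~15% between-metaphase spread variation around a 10,000 px total.
    """

    template: KaryotypeTemplate
    seed: int = 0
    n_metaphases: int = 11
    scale_mean_px: float = 10_000.0
    scale_cv: float = 0.15
    arm_noise_cv: float = 0.05
    chromatid_noise_cv: float = 0.02

    def __post_init__(self) -> None:
        if self.n_metaphases < 1:
            raise ConfigError("n_metaphases must be >= 1")
        for name in ("scale_cv", "arm_noise_cv", "chromatid_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.scale_mean_px <= 0:
            raise ConfigError("scale_mean_px must be > 0")
        for row in self.template.rows:
            if not (0 < row.i_median <= 50):
                raise ConfigError(
                    f"template i for {row.type_label} outside (0, 50]: {row.i_median}"
                )
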