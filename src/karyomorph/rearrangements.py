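"""Inference of chromosomal rearrangements from FISH marker maps.

A target species' marker map is compared against a reference map that
stands proxy for the ancestral arrangement (here the diploid relative).
Marker positions are arm-resolved, optionally refined by a 1-based rank
from the centromere outward.  Three callers are provided:

* ``detect_translocation`` — a strict minority of a reference chromosome's
  genes mapping to a different target chromosome indicates a translocation.
* ``detect_fusion`` — two reference chromosomes co-occupying one target
  chromosome indicates an end-to-end fusion; the fused arms and the fate of
  the two centromeres are inferred from the arm pattern and marker order
  (the chromosome whose markers from both ancestral arms lie on a single
  target arm has lost its centromere).
* ``detect_inversion`` — homeologous copies of a gene on different arms of
  homeologous chromosomes indicate a pericentromeric inversion, polarized
  against an outgroup; rank-order reversal on the same arm indicates a
  paracentric inversion.

Markers inconsistent with a call are reported as conflicts, never dropped.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .types import (
    FishSignal,
    KaryotypeTemplate,
    MarkerLocus,
    MarkerMap,
    RdnaSummary,
    RearrangementCall,
    SyntenyGroup,
    ValidationError,
    base_chromosome,
    parse_subgenome,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Synteny groups
# --------------------------------------------------------------------------

def build_synteny_groups(reference: MarkerMap) -> list[SyntenyGroup]:
    """One group per reference chromosome, genes ordered by (arm, rank)."""
    if not reference.loci:
        raise ValidationError(f"reference map for {reference.species} is empty")
    by_chrom: dict[str, list[MarkerLocus]] = defaultdict(list)
    for locus in reference.loci:
        if not locus.chromosome:
            raise ValidationError(f"gene {locus.gene} has no chromosome")
        by_chrom[locus.chromosome].append(locus)
    groups = []
    for chrom in sorted(by_chrom):
        loci = sorted(
            by_chrom[chrom],
            key=lambda l: (l.arm, l.rank if l.rank is not None else 10**6, l.gene),
        )
        groups.append(SyntenyGroup(chromosome=chrom, loci=tuple(loci)))
    return groups


def _gene_to_group(groups: Sequence[SyntenyGroup]) -> dict[str, SyntenyGroup]:
    lookup: dict[str, SyntenyGroup] = {}
    for g in groups:
        for locus in g.loci:
            lookup[locus.gene] = g
    return lookup


def _reference_locus(groups: Sequence[SyntenyGroup], gene: str) -> MarkerLocus:
    for g in groups:
        for locus in g.loci:
            if locus.gene == gene:
                return locus
    raise KeyError(gene)


def _target_by_copy(
    target: MarkerMap,
) -> dict[str, list[MarkerLocus]]:
    """Target loci grouped by effective subgenome copy (explicit tag,
    falling back to the chromosome-label suffix)."""
    by_copy: dict[str, list[MarkerLocus]] = defaultdict(list)
    for locus in target.loci:
        by_copy[locus.effective_copy].append(locus)
    return dict(by_copy)


def _group_majorities(
    groups: Sequence[SyntenyGroup], loci: Sequence[MarkerLocus]
) -> dict[str, tuple[Optional[str], dict[str, list[MarkerLocus]]]]:
    """For one subgenome copy: each group's partition of target chromosomes
    and its majority chromosome (None on an exact tie)."""
    gene_group = _gene_to_group(groups)
    per_group: dict[str, dict[str, list[MarkerLocus]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for locus in loci:
        grp = gene_group.get(locus.gene)
        if grp is not None:
            per_group[grp.chromosome][locus.chromosome].append(locus)
    out = {}
    for ref_chrom, partition in per_group.items():
        counts = {chrom: len(ls) for chrom, ls in partition.items()}
        best = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == best)
        total = sum(counts.values())
        majority = winners[0] if (len(winners) == 1 and best > total / 2) else None
        out[ref_chrom] = (majority, {c: list(ls) for c, ls in partition.items()})
    return out


# --------------------------------------------------------------------------
# Translocation
# --------------------------------------------------------------------------

def detect_translocation(
    groups: Sequence[SyntenyGroup], target: MarkerMap
) -> list[RearrangementCall]:
    """Call translocations per (reference chromosome, subgenome copy).

    Within one copy, the genes of each reference chromosome are partitioned
    by the target chromosome they map to.  A strict minority (< half) on a
    different chromosome than the group majority is called translocated;
    an exact half split is reported as ambiguous, not a call.
    """
    calls: list[RearrangementCall] = []
    present_genes = target.genes
    for g in groups:
        if not any(l.gene in present_genes for l in g.loci):
            logger.warning(
                "reference chromosome %s: no genes present in target %s; skipped",
                g.chromosome, target.species,
            )
    for copy in sorted(_target_by_copy(target)):
        loci = _target_by_copy(target)[copy]
        majorities = _group_majorities(groups, loci)
        for ref_chrom in sorted(majorities):
            majority, partition = majorities[ref_chrom]
            if majority is None:
                calls.append(
                    RearrangementCall(
                        kind="none",
                        reference_chromosomes=(ref_chrom,),
                        target_chromosome=None,
                        copy=copy,
                        genes=tuple(
                            sorted(l.gene for ls in partition.values() for l in ls)
                        ),
                        details={"ambiguous_split": True},
                    )
                )
                continue
            if len(partition) == 1:
                calls.append(
                    RearrangementCall(
                        kind="none",
                        reference_chromosomes=(ref_chrom,),
                        target_chromosome=majority,
                        copy=copy,
                        genes=tuple(sorted(l.gene for l in partition[majority])),
                    )
                )
                continue
            for dest_chrom in sorted(c for c in partition if c != majority):
                moved = sorted(l.gene for l in partition[dest_chrom])
                dest_ref = _destination_reference(
                    dest_chrom, majorities
                ) or base_chromosome(dest_chrom)
                calls.append(
                    RearrangementCall(
                        kind="translocation",
                        reference_chromosomes=(ref_chrom, dest_ref),
                        target_chromosome=dest_chrom,
                        copy=copy,
                        genes=tuple(moved),
                        details={
                            "source": ref_chrom,
                            "destination": dest_ref,
                            "region": _consensus_region(partition[dest_chrom]),
                        },
                    )
                )
    return calls


def _destination_reference(dest_chrom, majorities) -> Optional[str]:
    for ref_chrom, (majority, _) in majorities.items():
        if majority == dest_chrom:
            return ref_chrom
    return None


def _consensus_region(loci: Sequence[MarkerLocus]) -> str:
    regions = {l.region for l in loci if l.region != "unknown"}
    return regions.pop() if len(regions) == 1 else "unknown"


# --------------------------------------------------------------------------
# Fusion
# --------------------------------------------------------------------------

def detect_fusion(
    groups: Sequence[SyntenyGroup], target: MarkerMap
) -> list[RearrangementCall]:
    """Call end-to-end fusions per subgenome copy.

    A fusion is indicated where the majorities of two reference chromosomes
    occupy the same target chromosome.  Centromere fate and fused-arm
    orientation are chosen by scoring every orientation hypothesis against
    the observed arm pattern and marker order (see :func:`_score_fusion`).
    """
    calls: list[RearrangementCall] = []
    by_copy = _target_by_copy(target)
    for copy in sorted(by_copy):
        loci = by_copy[copy]
        majorities = _group_majorities(groups, loci)
        hosts: dict[str, list[str]] = defaultdict(list)
        for ref_chrom, (majority, _) in majorities.items():
            if majority is not None:
                hosts[majority].append(ref_chrom)
        for target_chrom in sorted(hosts):
            ref_chroms = sorted(hosts[target_chrom])
            if len(ref_chroms) < 2:
                continue
            # score the two best-supported ancestral chromosomes
            ref_chroms.sort(
                key=lambda rc: (-sum(len(v) for v in majorities[rc][1].values()), rc)
            )
            chrom_a, chrom_b = sorted(ref_chroms[:2])
            call = _call_fusion(
                groups, target_chrom, chrom_a, chrom_b, loci, copy
            )
            if len(ref_chroms) > 2:
                call.details["additional_groups"] = ref_chroms[2:]
            calls.append(call)
    if not calls:
        calls.append(
            RearrangementCall(
                kind="none",
                reference_chromosomes=(),
                target_chromosome=None,
                copy="all",
                genes=(),
                details={"note": "no two reference chromosomes co-occupy a target"},
            )
        )
    return calls


def _call_fusion(groups, target_chrom, chrom_a, chrom_b, loci, copy):
    gene_group = _gene_to_group(groups)
    obs = [
        l for l in loci
        if l.chromosome == target_chrom
        and l.gene in gene_group
        and gene_group[l.gene].chromosome in (chrom_a, chrom_b)
    ]
    candidates = []
    for lost, retained in ((chrom_a, chrom_b), (chrom_b, chrom_a)):
        for f_lost, f_ret, side in itertools.product("pq", "pq", "pq"):
            arm_score, rank_score = _score_fusion(
                groups, obs, lost, retained, f_lost, f_ret, side
            )
            # ties between equally supported orientations default to the
            # retained arm matching the lost chromosome's fusing arm, then
            # break lexicographically for determinism
            candidates.append(
                (
                    (-arm_score, -rank_score, 0 if f_ret == f_lost else 1,
                     lost, f_lost, f_ret, side),
                    (lost, f_lost, f_ret, side),
                )
            )
    _, (lost, f_lost, f_ret, side) = min(candidates)
    retained = chrom_b if lost == chrom_a else chrom_a
    conflicts = _arm_conflicts(groups, obs, lost, retained, f_ret, side)
    n_lost = sum(
        1 for l in obs if _gene_to_group(groups)[l.gene].chromosome == lost
    )
    n_ret = len(obs) - n_lost
    return RearrangementCall(
        kind="fusion",
        reference_chromosomes=(lost, retained),
        target_chromosome=target_chrom,
        copy=copy,
        genes=tuple(sorted(l.gene for l in obs)),
        details={
            "fused_arms": (f_lost, f_ret),
            "centromere_lost": lost,
            "centromere_retained": retained,
            "fused_target_arm": side,
        },
        conflicts=tuple(sorted(conflicts)),
        confidence="low" if min(n_lost, n_ret) < 2 else "normal",
    )


def _fusion_predictions(groups, obs, lost, retained, f_lost, f_ret, side):
    """Predicted target arm and expected along-arm position of each marker
    under one fusion-orientation hypothesis.

    Under hypothesis (lost, retained, fused arms f_lost/f_ret, fused target
    arm ``side``): the retained chromosome keeps its centromere, its f_ret
    arm carries the fusion; every marker of the lost chromosome sits on the
    fused arm, ordered from the junction — f_lost markers by decreasing
    ancestral rank, then the lost chromosome's other arm by increasing rank.
    """
    gene_group = _gene_to_group(groups)
    other_side = "q" if side == "p" else "p"
    predictions = {}
    # expected positions along the fused arm, proximal -> distal
    seq: list[tuple[str, float]] = []
    ret_fused = sorted(
        (l for g in groups if g.chromosome == retained for l in g.loci
         if l.arm == f_ret),
        key=lambda l: (l.rank if l.rank is not None else 10**6, l.gene),
    )
    lost_fused = sorted(
        (l for g in groups if g.chromosome == lost for l in g.loci
         if l.arm == f_lost),
        key=lambda l: (-(l.rank if l.rank is not None else 10**6), l.gene),
    )
    lost_other = sorted(
        (l for g in groups if g.chromosome == lost for l in g.loci
         if l.arm != f_lost),
        key=lambda l: (l.rank if l.rank is not None else 10**6, l.gene),
    )
    for pos, locus in enumerate(ret_fused + lost_fused + lost_other):
        seq.append((locus.gene, float(pos)))
    fused_pos = dict(seq)
    # expected positions on the retained chromosome's other (non-fused) arm
    ret_other = sorted(
        (l for g in groups if g.chromosome == retained for l in g.loci
         if l.arm != f_ret),
        key=lambda l: (l.rank if l.rank is not None else 10**6, l.gene),
    )
    other_pos = {l.gene: float(pos) for pos, l in enumerate(ret_other)}

    for locus in obs:
        src = gene_group[locus.gene].chromosome
        if src == lost or _reference_arm(groups, locus.gene) == f_ret:
            predictions[locus.gene] = (side, fused_pos.get(locus.gene))
        else:
            predictions[locus.gene] = (other_side, other_pos.get(locus.gene))
    return predictions


def _reference_arm(groups, gene: str) -> str:
    return _reference_locus(groups, gene).arm


def _score_fusion(groups, obs, lost, retained, f_lost, f_ret, side):
    """(arm concordance, rank-order concordance) of one hypothesis."""
    predictions = _fusion_predictions(groups, obs, lost, retained, f_lost, f_ret, side)
    arm_score = sum(1 for l in obs if predictions[l.gene][0] == l.arm)
    concordant = [
        l for l in obs
        if predictions[l.gene][0] == l.arm
        and l.rank is not None
        and predictions[l.gene][1] is not None
    ]
    rank_score = 0
    for x, y in itertools.combinations(concordant, 2):
        if x.arm != y.arm:
            continue
        ex, ey = predictions[x.gene][1], predictions[y.gene][1]
        if ex == ey or x.rank == y.rank:
            continue
        if (ex < ey) == (x.rank < y.rank):
            rank_score += 1
    return (arm_score, rank_score)


def _arm_conflicts(groups, obs, lost, retained, f_ret, side):
    # recompute predictions under the winning hypothesis (f_lost is
    # irrelevant for arm predictions, which depend only on side and f_ret)
    predictions = _fusion_predictions(groups, obs, lost, retained, "q", f_ret, side)
    return [l.gene for l in obs if predictions[l.gene][0] != l.arm]


# --------------------------------------------------------------------------
# Inversion
# --------------------------------------------------------------------------

def detect_inversion(
    target: MarkerMap, outgroup: Optional[MarkerMap] = None
) -> list[RearrangementCall]:
    """Call inversions by comparing homeologous gene copies.

    Homeologous copies on different arms of homeologous chromosomes imply a
    pericentromeric inversion on the homeolog whose arm differs from the
    outgroup; rank-order reversal on the same arm implies a paracentric
    inversion.  Without an outgroup the polarity is undetermined.
    """
    out_arm: dict[str, str] = {}
    out_rank: dict[str, Optional[int]] = {}
    if outgroup is not None:
        for l in outgroup.loci:
            out_arm[l.gene] = l.arm
            out_rank[l.gene] = l.rank

    # homeolog occurrences: gene -> base chromosome -> chromosome -> locus
    table: dict[tuple[str, str], dict[str, MarkerLocus]] = defaultdict(dict)
    for l in target.loci:
        base = base_chromosome(l.chromosome)
        if parse_subgenome(l.chromosome) != "none":
            table[(l.gene, base)][l.chromosome] = l

    peri: dict[tuple[str, str], list[str]] = defaultdict(list)  # (base, homeolog)
    peri_regions: dict[tuple[str, str], list[str]] = defaultdict(list)
    undetermined: dict[str, list[str]] = defaultdict(list)
    comparable = False
    for (gene, base), occ in sorted(table.items()):
        if len(occ) < 2:
            continue
        comparable = True
        chroms = sorted(occ)
        arms = {c: occ[c].arm for c in chroms}
        if len(set(arms.values())) == 1:
            continue
        if gene in out_arm:
            differing = [c for c in chroms if arms[c] != out_arm[gene]]
            for c in differing:
                peri[(base, c)].append(gene)
                peri_regions[(base, c)].append(occ[c].region)
        else:
            undetermined[base].append(gene)

    calls: list[RearrangementCall] = []
    for (base, homeolog) in sorted(peri):
        genes = sorted(set(peri[(base, homeolog)]))
        calls.append(
            RearrangementCall(
                kind="inversion",
                reference_chromosomes=(base,),
                target_chromosome=homeolog,
                copy=parse_subgenome(homeolog),
                genes=tuple(genes),
                details={
                    "inversion_type": "pericentromeric",
                    "inverted_homeolog": homeolog,
                    "polarity_source": outgroup.species if outgroup else None,
                },
            )
        )
    for base, genes in sorted(undetermined.items()):
        calls.append(
            RearrangementCall(
                kind="inversion",
                reference_chromosomes=(base,),
                target_chromosome=None,
                copy="none",
                genes=tuple(sorted(set(genes))),
                details={
                    "inversion_type": "pericentromeric",
                    "inverted_homeolog": None,
                    "polarity_source": "undetermined",
                },
                confidence="low",
            )
        )

    calls.extend(_paracentric_calls(table, out_rank, out_arm, outgroup))

    if not calls:
        calls.append(
            RearrangementCall(
                kind="none",
                reference_chromosomes=(),
                target_chromosome=None,
                copy="all",
                genes=(),
                details={
                    "note": (
                        "homeologous copies concordant"
                        if comparable
                        else "no gene observed on both homeologs"
                    )
                },
            )
        )
    return calls


def _paracentric_calls(table, out_rank, out_arm, outgroup):
    """Rank-order reversal of >=2 genes on the same arm of homeologs."""
    # (base, arm) -> chromosome -> {gene: rank}
    per_arm: dict[tuple[str, str], dict[str, dict[str, int]]] = defaultdict(
        lambda: defaultdict(dict)
    )
    for (gene, base), occ in table.items():
        for chrom, locus in occ.items():
            if len(occ) >= 2 and locus.rank is not None:
                per_arm[(base, locus.arm)][chrom][gene] = locus.rank
    calls = []
    for (base, arm), by_chrom in sorted(per_arm.items()):
        chroms = sorted(by_chrom)
        if len(chroms) != 2:
            continue
        shared = sorted(set(by_chrom[chroms[0]]) & set(by_chrom[chroms[1]]))
        if len(shared) < 2:
            continue
        order0 = sorted(shared, key=lambda g: by_chrom[chroms[0]][g])
        order1 = sorted(shared, key=lambda g: by_chrom[chroms[1]][g])
        if order0 != list(reversed(order1)):
            continue
        inverted = None
        if outgroup is not None and all(g in out_rank and out_rank[g] is not None
                                        and out_arm.get(g) == arm for g in shared):
            out_order = sorted(shared, key=lambda g: out_rank[g])
            if order0 == out_order:
                inverted = chroms[1]
            elif order1 == out_order:
                inverted = chroms[0]
        calls.append(
            RearrangementCall(
                kind="inversion",
                reference_chromosomes=(base,),
                target_chromosome=inverted,
                copy=parse_subgenome(inverted) if inverted else "none",
                genes=tuple(shared),
                details={
                    "inversion_type": "paracentric",
                    "arm": arm,
                    "inverted_homeolog": inverted,
                    "polarity_source": (
                        outgroup.species if inverted and outgroup else "undetermined"
                    ),
                },
                confidence="normal" if inverted else "low",
            )
        )
    return calls


# --------------------------------------------------------------------------
# rDNA summary
# --------------------------------------------------------------------------

def summarize_rdna(
    signals: Sequence[FishSignal], template: KaryotypeTemplate
) -> RdnaSummary:
    """Summarize 28S (NOR) and 5S rDNA FISH signals over a karyotype."""
    valid = set(template.type_labels)
    for s in signals:
        if s.chromosome not in valid:
            raise ValidationError(f"signal on unknown chromosome {s.chromosome!r}")

    nor_locations: list[tuple[str, str, str]] = []
    seen_nor: set[str] = set()
    five_s: dict[str, list[FishSignal]] = defaultdict(list)
    low: set[str] = set()
    for s in signals:
        if s.intensity == "low":
            low.add(s.chromosome)
        if s.probe == "28S":
            if s.chromosome not in seen_nor:
                nor_locations.append((s.chromosome, s.arm, s.region))
                seen_nor.add(s.chromosome)
        elif s.probe == "5S":
            five_s[s.chromosome].append(s)

    both_arm = sorted(
        c for c, sigs in five_s.items()
        if any(s.arm == "both" for s in sigs)
        or {"p", "q"} <= {s.arm for s in sigs}
    )
    missing = sorted(c for c in valid if c not in five_s)
    colocalized = sorted(seen_nor & set(five_s))
    return RdnaSummary(
        nor_count=len(seen_nor),
        nor_locations=nor_locations,
        five_s_missing=missing,
        both_arm_5s=both_arm,
        colocalized=colocalized,
        low_intensity=sorted(low),
    )
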