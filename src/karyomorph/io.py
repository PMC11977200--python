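"""Readers and writers for the pipeline's tabular and tree formats.

All tables are comma-delimited CSV with a header (TSV auto-detected from a
``.tsv``/``.tab`` extension); trees are newick.  Every reader validates
against the domain invariants and raises a typed error rather than returning
a partially constructed object.
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd

from .types import (
    ChromatidMeasurement,
    FishSignal,
    KaryotypeTemplate,
    MarkerLocus,
    MarkerMap,
    NorStateMap,
    SchemaError,
    TemplateRow,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]

MEASUREMENT_COLUMNS = ["metaphase_id", "object_id", "chromatid_index", "p_len", "q_len"]
MARKER_COLUMNS = ["species", "gene", "chromosome", "arm", "rank", "region", "copy"]
SIGNAL_COLUMNS = ["probe", "chromosome", "arm", "region", "intensity"]
TEMPLATE_COLUMNS = ["type_label", "l_pct_median", "i_median", "category", "subgenome"]
STATE_COLUMNS = ["species", "nor_chromosome"]


def _sep_for(path: PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path: PathLike, required: list[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str,
                     skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# --------------------------------------------------------------------------
# Measurements
# --------------------------------------------------------------------------

def read_measurements(path: PathLike) -> list[ChromatidMeasurement]:
    """Read a per-chromatid arm-length table.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (citing the 1-based data row) for invalid values.
    """
    df = _read_table(path, MEASUREMENT_COLUMNS)
    records: list[ChromatidMeasurement] = []
    seen: set[tuple] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = ChromatidMeasurement(
                metaphase_id=str(row.metaphase_id),
                object_id=str(row.object_id),
                chromatid_index=int(row.chromatid_index),
                p_len=float(row.p_len),
                q_len=float(row.q_len),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
        key = (rec.metaphase_id, rec.object_id, rec.chromatid_index)
        if key in seen:
            raise ValidationError(
                f"{path}: row {idx}: duplicate (metaphase, object, chromatid) {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def write_measurements(records: Iterable[ChromatidMeasurement], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "metaphase_id": r.metaphase_id,
                "object_id": r.object_id,
                "chromatid_index": r.chromatid_index,
                "p_len": repr(r.p_len),
                "q_len": repr(r.q_len),
            }
            for r in records
        ],
        columns=MEASUREMENT_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# Marker maps
# --------------------------------------------------------------------------

def read_marker_map(path: PathLike, role: str = "target") -> MarkerMap:
    """Read a marker-locus map (one species per file)."""
    df = _read_table(path, MARKER_COLUMNS)
    loci: list[MarkerLocus] = []
    species = None
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rank_raw = row.rank
        rank = None if (pd.isna(rank_raw) or str(rank_raw) == "") else int(float(rank_raw))
        region = row.region if not pd.isna(row.region) else "unknown"
        copy = row.copy if not pd.isna(row.copy) else "none"
        try:
            locus = MarkerLocus(
                species=str(row.species),
                gene=str(row.gene),
                chromosome=str(row.chromosome),
                arm=str(row.arm),
                rank=rank,
                region=str(region),
                copy=str(copy),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
        loci.append(locus)
        species = species or locus.species
    if species is None:
        raise ValidationError(f"{path}: marker map is empty")
    try:
        return MarkerMap(species=species, loci=loci, role=role)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_marker_map(marker_map: MarkerMap, path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "species": l.species,
                "gene": l.gene,
                "chromosome": l.chromosome,
                "arm": l.arm,
                "rank": "" if l.rank is None else l.rank,
                "region": l.region,
                "copy": l.copy,
            }
            for l in marker_map.loci
        ],
        columns=MARKER_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# FISH signals
# --------------------------------------------------------------------------

def read_fish_signals(path: PathLike) -> list[FishSignal]:
    df = _read_table(path, SIGNAL_COLUMNS)
    signals: list[FishSignal] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        intensity = row.intensity if not pd.isna(row.intensity) else "normal"
        try:
            signals.append(
                FishSignal(
                    probe=str(row.probe),
                    chromosome=str(row.chromosome),
                    arm=str(row.arm),
                    region=str(row.region),
                    intensity=str(intensity),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return signals


def write_fish_signals(signals: Iterable[FishSignal], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "probe": s.probe,
                "chromosome": s.chromosome,
                "arm": s.arm,
                "region": s.region,
                "intensity": s.intensity,
            }
            for s in signals
        ],
        columns=SIGNAL_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# Karyotype template
# --------------------------------------------------------------------------

def read_template(path: PathLike, ploidy_copies: int = 2) -> KaryotypeTemplate:
    """Read a karyotype template.

    The haploid ``l_pct_median`` column of a complete template is expected
    to sum to 100/ploidy_copies; a deviation beyond 1 percentage point is
    logged as a warning but the template is still returned.
    """
    df = _read_table(path, TEMPLATE_COLUMNS)
    rows: list[TemplateRow] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        subgenome = row.subgenome if not pd.isna(row.subgenome) else "none"
        try:
            rows.append(
                TemplateRow(
                    type_label=str(row.type_label),
                    l_pct_median=float(row.l_pct_median),
                    i_median=float(row.i_median),
                    category=str(row.category),
                    subgenome=str(subgenome),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    template = KaryotypeTemplate(rows=rows, ploidy_copies=ploidy_copies)
    total = template.haploid_l_sum() * ploidy_copies
    if abs(total - 100.0) > 1.0:
        logger.warning(
            "%s: template l_pct x ploidy sums to %.2f%%, expected ~100%%", path, total
        )
    return template


def write_template(template: KaryotypeTemplate, path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "type_label": r.type_label,
                "l_pct_median": repr(r.l_pct_median),
                "i_median": repr(r.i_median),
                "category": r.category,
                "subgenome": r.subgenome,
            }
            for r in template.rows
        ],
        columns=TEMPLATE_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


# --------------------------------------------------------------------------
# Tree and NOR states
# --------------------------------------------------------------------------

def read_tree(path: PathLike) -> dendropy.Tree:
    """Read a rooted newick species tree; polytomies are preserved.

    Raises :class:`ValidationError` on parse failure or duplicate leaves.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValidationError(f"{path}: newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate leaf label(s): {sorted(dupes)}")
    return tree


def read_nor_states(path: PathLike) -> NorStateMap:
    df = _read_table(path, STATE_COLUMNS)
    states: dict[str, str] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        sp = str(row.species)
        if sp in states:
            raise ValidationError(f"{path}: row {idx}: duplicate species {sp!r}")
        chrom = row.nor_chromosome
        if pd.isna(chrom) or str(chrom) == "":
            continue  # species with no recorded NOR state are simply absent
        states[sp] = str(chrom)
    return NorStateMap(states=states)


def write_nor_states(state_map: NorStateMap, path: PathLike) -> None:
    df = pd.DataFrame(
        sorted(state_map.states.items()), columns=STATE_COLUMNS
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
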