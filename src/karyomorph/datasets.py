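"""Loaders for the bundled in-study fixtures.

The package ships the published *X. pygmaeus* karyotype template (per-type
medians of l, i and r1), the FISH-derived marker maps of four *Xenopus*
species, the rDNA signal table, and the schematic species tree with the
NOR-bearing chromosome of each species, so every stage can run offline.
"""

from __future__ import annotations

from importlib import resources

import dendropy
import pandas as pd

from . import io as kio
from .types import KaryotypeTemplate, MarkerMap, NorStateMap

_SPECIES_FILES = {
    "tropicalis": "markers_tropicalis.csv",
    "laevis": "markers_laevis.csv",
    "pygmaeus": "markers_pygmaeus.csv",
    "mellotropicalis": "markers_mellotropicalis.csv",
}


def _path(name: str):
    return resources.files(__package__).joinpath("data", name)


def load_pygmaeus_template() -> KaryotypeTemplate:
    """The 18-type *X. pygmaeus* karyotype template (2 copies per type)."""
    with resources.as_file(_path("table2_template.csv")) as p:
        return kio.read_template(p, ploidy_copies=2)


def load_reference_arm_ratios() -> dict[str, float]:
    """Published median p/q arm ratios (r1) per chromosome type."""
    with resources.as_file(_path("table2_template.csv")) as p:
        df = pd.read_csv(p, comment="#")
    return dict(zip(df["type_label"], df["r1_median"].astype(float)))


def load_marker_map(species: str) -> MarkerMap:
    """Bundled marker map; species is one of tropicalis, laevis, pygmaeus,
    mellotropicalis (the tropicalis map is the ancestral-proxy reference)."""
    try:
        fname = _SPECIES_FILES[species]
    except KeyError:
        raise KeyError(
            f"no bundled map for {species!r}; choose from {sorted(_SPECIES_FILES)}"
        ) from None
    role = "reference" if species == "tropicalis" else "target"
    with resources.as_file(_path(fname)) as p:
        return kio.read_marker_map(p, role=role)


def load_rdna_signals():
    """The *X. pygmaeus* 28S/5S FISH signal table."""
    with resources.as_file(_path("fig_rdna_signals.csv")) as p:
        return kio.read_fish_signals(p)


def load_species_tree() -> dendropy.Tree:
    """The schematic 13-leaf pipid species tree (Hymenochirus outgroup)."""
    with resources.as_file(_path("species_tree.nwk")) as p:
        return kio.read_tree(p)


def load_nor_states() -> NorStateMap:
    """NOR-bearing chromosome states for the 12 Xenopus species."""
    with resources.as_file(_path("nor_states.csv")) as p:
        return kio.read_nor_states(p)
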