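"""Packaged reference fixtures.

Small curated TSVs shipped with the package:

* the lectin -> glycan-binding-specificity annotation table compiled from
  the literature and UniProt (79 lectins);
* the published bound-glycan lists (with average RFU) for the SNA-I, SNA-II
  and ConA array-node groups, by community -- the inputs of the determinant
  motif analyses.
"""

from __future__ import annotations

from importlib import resources

from .enrichment import AnnotationMap, read_annotation_file
from .motif import GlycanStructure, read_glycan_tsv

__all__ = [
    "load_lectin_annotations",
    "load_sna_glycans",
    "load_cona_glycans",
]

_SNA_PANELS = {
    # 10 SNA-I array nodes from community 3: complex sialylated N-glycans
    "sna1_community3": "sna1_community3_glycans.tsv",
    # 5 SNA-I array nodes from community 1 (panel with AGP / Transferrin)
    "sna1_community1": "sna1_community1_glycans.tsv",
    # 4 SNA-II array nodes from community 3: mainly mannose glycans
    "sna2_community3": "sna2_community3_glycans.tsv",
}

_CONA_PANELS = {
    "cona_community1": "cona_community1_glycans.tsv",
    "cona_community2": "cona_community2_glycans.tsv",
    "cona_community3": "cona_community3_glycans.tsv",
}


def _data_path(filename: str):
    return resources.files("glynet.data").joinpath(filename)


def load_lectin_annotations() -> AnnotationMap:
    """The curated lectin specificity table as an :class:`AnnotationMap`."""
    with resources.as_file(_data_path("lectin_specificities.tsv")) as path:
        return read_annotation_file(path)


def load_sna_glycans(panel: str) -> list[GlycanStructure]:
    """Bound-glycan list of an SNA node group; see :data:`_SNA_PANELS` keys."""
    if panel not in _SNA_PANELS:
        raise KeyError(f"unknown SNA panel {panel!r}; one of {sorted(_SNA_PANELS)}")
    with resources.as_file(_data_path(_SNA_PANELS[panel])) as path:
        return read_glycan_tsv(path)


def load_cona_glycans(panel: str) -> list[GlycanStructure]:
    """Bound-glycan list of a ConA node group; see :data:`_CONA_PANELS` keys."""
    if panel not in _CONA_PANELS:
        raise KeyError(f"unknown ConA panel {panel!r}; one of {sorted(_CONA_PANELS)}")
    with resources.as_file(_data_path(_CONA_PANELS[panel])) as path:
        return read_glycan_tsv(path)
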