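"""Packaged comparative dataset: 12 intertidal eubrachyuran crab species.

``load_trait_table`` returns the per-species comparative data — province,
substrate, mean microhabitat temperature (MHT, with its SEM over 7-15 field
measurements), and the lower (LL50) and upper (UL50) critical thermal limits
in deg C.

``load_surrogate_tree`` returns a SURROGATE phylogeny: the study's actual
16S molecular tree (branch lengths included) was never published, so the
packaged tree encodes only the accepted family-level taxonomy of the 12
species with arbitrary small integer branch lengths. It supports
demonstrations and pipeline runs; any statistic that depends on branch
lengths is therefore not comparable to values computed on the molecular
tree, and downstream reports say so.

``load_accessions`` returns GenBank 16S accession metadata for the 12 focal
species (metadata only; no sequence retrieval happens anywhere in the
package).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tree import Phylogeny, read_newick

__all__ = ["load_trait_table", "load_surrogate_tree", "load_accessions", "PROVINCE_TM"]

#: annual mean seawater temperature (deg C) defining each province
PROVINCE_TM = {"Brazilian": 26.0, "Argentinian": 15.0, "Magellanic": 9.0}


def _data_path(name: str):
    return resources.files("phylotherm") / "data" / name


def load_trait_table() -> pd.DataFrame:
    """Species-level trait table (12 species, three provinces)."""
    with resources.as_file(_data_path("trait_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_surrogate_tree() -> Phylogeny:
    """Taxonomy-informed surrogate tree over the 12 species (see module docs)."""
    with resources.as_file(_data_path("surrogate_tree.nwk")) as p:
        return read_newick(str(p))


def load_accessions() -> pd.DataFrame:
    """GenBank accession metadata for the 12 focal species."""
    with resources.as_file(_data_path("accessions.tsv")) as p:
        return pd.read_csv(p, sep="\t")
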