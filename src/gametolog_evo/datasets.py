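"""Packaged desk-scale fixtures: 25-species time tree, ancestral-Y presence
matrix (synthetic transcription, see file headers) and life-history traits."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import Phylogeny, PresenceMatrix, read_newick, read_presence_matrix, read_trait_table

#: phylogenetic group of each packaged species: Pr primates (incl. tree shrew),
#: Ro rodents (incl. rabbit), La laurasiatheria, At afrotheria/xenarthra
PLACENTAL_GROUPS: dict[str, str] = {
    "tree_shrew": "Pr", "mouse_lemur": "Pr", "marmoset": "Pr", "macaque": "Pr",
    "gorilla": "Pr", "human": "Pr", "chimpanzee": "Pr",
    "rabbit": "Ro", "guinea_pig": "Ro", "hamster": "Ro", "mouse": "Ro", "rat": "Ro",
    "hedgehog": "La", "pig": "La", "cow": "La", "sheep": "La", "horse": "La",
    "cat": "La", "panda": "La", "polar_bear": "La", "red_fox": "La",
    "dog": "La", "gray_wolf": "La",
    "armadillo": "At", "tenrec": "At",
}

ATLANTOGENATA_NODE = "Atlantogenata"


def _path(name: str):
    return resources.files("gametolog_evo.data") / name


def load_placental_tree() -> Phylogeny:
    return read_newick(_path("placental_tree.nwk").read_text())


def load_presence_matrix() -> PresenceMatrix:
    with resources.as_file(_path("presence_matrix.tsv")) as p:
        return read_presence_matrix(p)


def load_trait_table() -> pd.DataFrame:
    with resources.as_file(_path("life_history_traits.tsv")) as p:
        return read_trait_table(p)
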