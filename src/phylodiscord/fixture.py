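"""The bundled Potentilla fixture.

Two consensus-style trees (nuclear ITS+ETS, chloroplast trnL/F+trnS/G)
encode the six major Potentilla clades (Anserina A, Alba B, Fragarioides C,
Reptans D, ivesioid E, Argentea F), their published between-tree placements
and posterior supports, and the five described well-supported
incongruences.  Clade-internal structure that was reported as unresolved
(notably most of the Argentea clade) is encoded as unsupported polytomies,
so it can never generate supported conflicts.  Branch lengths are a uniform
1.0 -- the published figures carry no usable lengths -- so ancestral-state
reconstructions on the fixture are qualitative (state identities, not
probabilities).

The ploidy/morphology table transcribes the study's specimen table
cell-for-cell: reported ploidal levels, clade assignment, style shape
(L Leptostylae / N Nematostylae / G Gomphostylae / C Conostylae) and anther
shape (A-D, blank where voucher material was unusable).  P. clusiana
appears in the table but not in the trees (it was dropped from the
molecular analyses after a recombination screen).
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .mk import MISSING, CharacterMatrix
from .ploidy import parse_ploidy_table
from .trees import Tree, parse_newick

__all__ = ["PotentillaFixture", "potentilla_fixture", "STYLE_STATES", "ANTHER_STATES"]

STYLE_STATES = ["L", "N", "G", "C"]
ANTHER_STATES = ["A", "B", "C", "D"]

_DATA_FILES = (
    "potentilla_nuclear.nwk",
    "potentilla_chloroplast.nwk",
    "potentilla_table_s1.tsv",
)


def _data_path(name: str):
    return resources.files("phylodiscord.data").joinpath(name)


@dataclass
class PotentillaFixture:
    nuclear: Tree
    chloroplast: Tree
    table: pd.DataFrame

    @property
    def ploidy_records(self) -> list:
        return parse_ploidy_table(self.table)

    def character_matrix(self, character: str) -> CharacterMatrix:
        """Style- or anther-shape states for the taxa present in the trees."""
        if character == "style":
            column, alphabet = "style_shape", STYLE_STATES
        elif character == "anther":
            column, alphabet = "anther_shape", ANTHER_STATES
        else:
            raise ValueError(f"unknown character {character!r}")
        in_trees = self.nuclear.leaves
        data = {}
        for _, row in self.table.iterrows():
            if row["taxon"] not in in_trees:
                continue
            state = row[column]
            data[row["taxon"]] = [
                MISSING if pd.isna(state) or state == "" else str(state)
            ]
        return CharacterMatrix(data, list(alphabet), names=[character])

    def copy_to(self, directory) -> list:
        """Export the bundled fixture files; returns the copied paths."""
        out = []
        for name in _DATA_FILES:
            dest = shutil.copy(str(_data_path(name)), directory)
            out.append(dest)
        return out


def potentilla_fixture() -> PotentillaFixture:
    nuclear = parse_newick(_data_path("potentilla_nuclear.nwk").read_text())
    chloroplast = parse_newick(
        _data_path("potentilla_chloroplast.nwk").read_text()
    )
    table = pd.read_csv(
        _data_path("potentilla_table_s1.tsv"), sep="\t", dtype=str
    )
    return PotentillaFixture(nuclear=nuclear, chloroplast=chloroplast, table=table)
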