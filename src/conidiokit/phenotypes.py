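"""Conidiophore architectural phenotype labels.

Three architectures are distinguished in wild *Neurospora crassa*
isolates: Wild-Type conidiophores form linear chains of conidia, Wrap
conidiophores wrap around or stick to hyphal filaments, and Bulky
conidiophores form tight clusters.  Every table in this package uses the
fixed ordering WT < Wrap < Bulky, matching the hypothetical genes A, B
and C of the inheritance model.
"""

from __future__ import annotations

import enum


class PhenotypeLabel(enum.Enum):
    """One of the three conidiophore architectures (gene A, B or C)."""

    WT = "WT"
    WRAP = "Wrap"
    BULKY = "Bulky"

    @property
    def gene(self) -> str:
        """Letter of the hypothetical dominant gene behind this phenotype."""
        return {"WT": "A", "Wrap": "B", "Bulky": "C"}[self.value]

    @property
    def index(self) -> int:
        """Column index in the fixed WT < Wrap < Bulky ordering."""
        return PHENOTYPE_ORDER.index(self)

    @classmethod
    def parse(cls, text: str) -> "PhenotypeLabel":
        """Parse a label from text; accepts names, values and gene letters."""
        key = str(text).strip().lower()
        aliases = {
            "wt": cls.WT, "wild-type": cls.WT, "wildtype": cls.WT, "a": cls.WT,
            "wrap": cls.WRAP, "b": cls.WRAP,
            "bulky": cls.BULKY, "c": cls.BULKY,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown phenotype label: {text!r}") from None


#: Fixed phenotype/column ordering used by every 3x3 table in the package.
PHENOTYPE_ORDER: tuple[PhenotypeLabel, ...] = (
    PhenotypeLabel.WT,
    PhenotypeLabel.WRAP,
    PhenotypeLabel.BULKY,
)
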