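"""Dinucleotide physicochemical property tables.

Physicochemical descriptors (DPCP, DPCP2) and the sequence-order
correlation factors of pseudo dinucleotide composition all need numeric
helix step parameters per dinucleotide.  The bundled table carries the
six A-form RNA base-step parameters — rise, roll, shift, slide, tilt,
twist — over the 16 dinucleotides, taken from the crystallographic step
parameter sets conventionally used by the pseudo-composition descriptor
family.

For sequence-order correlation (pseudo composition) each property is
standardized to mean 0 / unit standard deviation over the 16
dinucleotides, the convention of that descriptor family; the raw values
are the default for the direct property encodings.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

#: Lexicographic dinucleotide order over (A, C, G, U); fixed everywhere.
DINUCLEOTIDES = tuple("".join(p) for p in product("ACGU", repeat=2))

ALL_PROPERTIES = ("rise", "roll", "shift", "slide", "tilt", "twist")

#: Property subset used by the position-resolved encoding (DPCP2).
DPCP2_PROPERTIES = ("rise", "roll", "shift", "slide")

TABLE_VERSION = "rna_dinucleotide_steps.v1"


@dataclass(frozen=True)
class PhysicochemicalTable:
    """16 dinucleotides x N properties, optionally standardized.

    ``values`` is indexed by dinucleotide (rows, lexicographic order)
    and property name (columns).  When ``standardized`` is set, every
    column has mean 0 and unit (population) standard deviation over the
    16 dinucleotides.
    """

    values: pd.DataFrame
    standardized: bool = False
    version: str = TABLE_VERSION

    def __post_init__(self) -> None:
        if list(self.values.index) != list(DINUCLEOTIDES):
            raise ValueError("table must have exactly the 16 dinucleotide rows in order")
        if self.standardized:
            mu = self.values.mean(axis=0).to_numpy()
            sd = self.values.std(axis=0, ddof=0).to_numpy()
            if not (np.all(np.abs(mu) < 1e-9) and np.all(np.abs(sd - 1) < 1e-9)):
                raise ValueError("standardized table must have mean 0 / sd 1 per property")

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def subset(self, properties: tuple[str, ...]) -> "PhysicochemicalTable":
        missing = [p for p in properties if p not in self.values.columns]
        if missing:
            raise KeyError(f"property column(s) missing from table: {missing}")
        return PhysicochemicalTable(
            self.values[list(properties)], self.standardized, self.version
        )

    def standardize(self) -> "PhysicochemicalTable":
        """Per-property z-score over the 16 dinucleotides (population sd)."""
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0, ddof=0)
        return PhysicochemicalTable((self.values - mu) / sd, True, self.version)

    def lookup(self, dinucleotide: str, prop: str) -> float:
        return float(self.values.at[dinucleotide, prop])

    def as_array(self) -> np.ndarray:
        """(16, n_properties) array in dinucleotide order."""
        return self.values.to_numpy(dtype=float)


def load_default_table() -> PhysicochemicalTable:
    """Load the bundled A-form RNA base-step parameter table (raw values)."""
    ref = resources.files("a2isite.data").joinpath("rna_dinucleotide_steps.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", index_col="dinucleotide")
    df.index = [d.upper().replace("T", "U") for d in df.index]
    df = df.loc[list(DINUCLEOTIDES), list(ALL_PROPERTIES)]
    return PhysicochemicalTable(df, standardized=False)
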