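"""Dinucleotide structural property tables and their standard conversion.

Six base-pair-step parameters describe the local geometry of two
stacked base pairs: three angular (twist, tilt, roll) and three
translational (shift, slide, rise). The values originate from long
atomistic molecular-dynamics simulations of DNA in water and are
tabulated per dinucleotide. Before use in correlation functions each
property is z-scored across the 16 dinucleotides so that every property
contributes on a common, unit-free scale:

    P(XY) = (P0(XY) - mean over 16 dinucleotides) / SD

with the sample (n-1) standard deviation. The standardized values have
zero mean and are a fixed point of the conversion.

Note: the published standardized *roll* column is not the z-score of
the published original roll column (its printed values are consistent
with a different, unpublished source column). The standardized table is
therefore embedded verbatim and is canonical for all encoding; the
original table is kept for the conversion itself and for user-supplied
property sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PROPERTY_NAMES = ("twist", "tilt", "roll", "shift", "slide", "rise")

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

# Original (unstandardized) values; columns in PROPERTY_NAMES order.
_ORIGINAL = {
    "AA": (0.026, 0.038, 0.020, 1.69, 2.26, 7.65),
    "AC": (0.036, 0.038, 0.023, 1.32, 3.03, 8.93),
    "AG": (0.031, 0.037, 0.019, 1.46, 2.03, 7.08),
    "AT": (0.033, 0.036, 0.022, 1.03, 3.83, 9.07),
    "CA": (0.016, 0.025, 0.017, 1.07, 1.78, 6.38),
    "CC": (0.026, 0.042, 0.019, 1.43, 1.65, 8.04),
    "CG": (0.014, 0.026, 0.016, 1.08, 2.00, 6.23),
    "CT": (0.031, 0.037, 0.019, 1.46, 2.03, 7.08),
    "GA": (0.025, 0.038, 0.020, 1.32, 1.93, 8.56),
    "GC": (0.025, 0.036, 0.026, 1.20, 2.61, 9.53),
    "GG": (0.026, 0.042, 0.019, 1.43, 1.65, 8.04),
    "GT": (0.036, 0.038, 0.023, 1.32, 3.03, 8.93),
    "TA": (0.017, 0.018, 0.016, 0.72, 1.20, 6.23),
    "TC": (0.025, 0.038, 0.020, 1.32, 1.93, 8.56),
    "TG": (0.016, 0.025, 0.017, 1.07, 1.78, 6.38),
    "TT": (0.026, 0.038, 0.020, 1.69, 2.26, 7.65),
}

# Published standardized values, canonical for all encoding.
_STANDARDIZED = {
    "AA": (0.06, 0.5, 0.27, 1.59, 0.11, -0.11),
    "AC": (1.50, 0.50, 0.80, 0.13, 1.29, 1.04),
    "AG": (0.78, 0.36, 0.09, 0.68, -0.24, -0.62),
    "AT": (1.07, 0.22, 0.62, -1.02, 2.51, 1.17),
    "CA": (-1.38, -1.36, -0.27, -0.86, -0.62, -1.25),
    "CC": (0.06, 1.08, 0.09, 0.56, -0.82, 0.24),
    "CG": (-1.66, -1.22, -0.44, -0.82, -0.29, -1.39),
    "CT": (0.78, 0.36, 0.09, 0.68, -0.24, -0.62),
    "GA": (-0.08, 0.5, 0.27, 0.13, -0.39, 0.71),
    "GC": (-0.08, 0.22, 1.33, -0.35, 0.65, 1.59),
    "GG": (0.06, 1.08, 0.09, 0.56, -0.82, 0.24),
    "GT": (1.50, 0.50, 0.80, 0.13, 1.29, 1.04),
    "TA": (-1.23, -2.37, -0.44, -2.24, -1.51, -1.39),
    "TC": (-0.08, 0.5, 0.27, 0.13, -0.39, 0.71),
    "TG": (-1.38, -1.36, -0.27, -0.86, -0.62, -1.25),
    "TT": (0.06, 0.5, 0.27, 1.59, 0.11, -0.11),
}


class DegeneratePropertyError(ValueError):
    """A property column is constant, so its z-score is undefined."""


@dataclass(frozen=True)
class PropertyTable:
    """16 dinucleotides x 6 structural properties.

    ``values`` is indexed by dinucleotide (AA..TT) with one named column
    per property; ``form`` is "original" or "standardized".
    """

    values: pd.DataFrame
    form: str

    def __post_init__(self) -> None:
        df = self.values.reindex(index=list(DINUCLEOTIDES), columns=list(PROPERTY_NAMES))
        if df.isna().any().any():
            missing = df.isna().stack()
            where = missing[missing].index.tolist()[:4]
            raise ValueError(f"property table has missing cells, e.g. {where}")
        object.__setattr__(self, "values", df.astype(float))

    def value(self, dinucleotide: str, prop: str) -> float:
        """P_nu(XY) for one dinucleotide and one property."""
        dinucleotide = dinucleotide.upper()
        if dinucleotide not in _ORIGINAL:
            raise KeyError(f"unknown dinucleotide {dinucleotide!r}")
        if prop not in PROPERTY_NAMES:
            raise KeyError(f"unknown property {prop!r}; expected one of {PROPERTY_NAMES}")
        return float(self.values.at[dinucleotide, prop])

    def row(self, dinucleotide: str) -> np.ndarray:
        """All six property values for one dinucleotide."""
        dinucleotide = dinucleotide.upper()
        if dinucleotide not in _ORIGINAL:
            raise KeyError(f"unknown dinucleotide {dinucleotide!r}")
        return self.values.loc[dinucleotide].to_numpy()

    def as_array(self) -> np.ndarray:
        """16 x 6 array in (AA..TT) x (twist..rise) order."""
        return self.values.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="dinucleotide")

    @classmethod
    def from_tsv(cls, path: str | Path, form: str = "original") -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", index_col="dinucleotide")
        return cls(df, form)


def builtin_table(form: str = "standardized") -> PropertyTable:
    """The built-in property table in its original or standardized form."""
    if form == "original":
        data = _ORIGINAL
    elif form == "standardized":
        data = _STANDARDIZED
    else:
        raise ValueError(f"form must be 'original' or 'standardized', got {form!r}")
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(PROPERTY_NAMES))
    return PropertyTable(df, form)


def standardize(table: PropertyTable) -> PropertyTable:
    """Z-score every property column across the 16 dinucleotides.

    Uses the sample (n-1) standard deviation; output columns have mean 0
    and unit sample variance, and the transform is idempotent to machine
    precision. A constant column raises :class:`DegeneratePropertyError`.
    """
    arr = table.as_array()
    sd = arr.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        names = [PROPERTY_NAMES[i] for i in degenerate]
        raise DegeneratePropertyError(f"constant property column(s): {names}")
    z = (arr - arr.mean(axis=0)) / sd
    df = pd.DataFrame(z, index=list(DINUCLEOTIDES), columns=list(PROPERTY_NAMES))
    return PropertyTable(df, "standardized")
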