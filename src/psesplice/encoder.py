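"""Sequence encoders: NAC, k-tuple composition, DNC and PseDNC.

The pseudo dinucleotide composition (PseDNC) represents a DNA sequence
of length L by 16 + lambda components:

    d_u = f_u / (1 + w * sum_j theta_j)            u = 1..16
    d_u = w * theta_{u-16} / (1 + w * sum_j theta_j)   u = 17..16+lambda

where f_u are the 16 normalized overlapping dinucleotide frequencies
(which sum to 1, so the denominator's composition term collapses to 1),
and theta_j is the j-th tier correlation factor

    theta_j = 1/(L-j-1) * sum_{i=1}^{L-j-1} Theta(R_i R_{i+1}; R_{i+j} R_{i+j+1})

with the correlation function Theta the mean squared difference of the
six standardized structural property values of two dinucleotides. The
tail components inject long-range sequence-order information that plain
composition discards; w weights it against composition and lambda sets
how many tiers are counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import Label, LabeledDataset, SpliceSequence
from .structural_props import DINUCLEOTIDES, PropertyTable, builtin_table

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

#: Largest k for which the 4**k k-tuple space is allowed without an override.
MAX_K = 7

DEFAULT_LAMBDA_RANGE = (1, 10)
DEFAULT_WEIGHT_RANGE = (0.0, 1.0)


@dataclass(frozen=True)
class EncoderParams:
    """PseDNC parameters: correlation tiers, weight factor and property set.

    ``lam`` (lambda) counts the correlation tiers, ``weight`` (w) scales
    their contribution against composition. Defaults bound them to the
    conventional search box 1 <= lambda <= 10, 0 <= w <= 1; pass
    ``enforce_bounds=False`` to explore outside it. The table must be in
    standardized form.
    """

    lam: int = 4
    weight: float = 0.3
    table: PropertyTable = field(default_factory=builtin_table)
    enforce_bounds: bool = True

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if self.enforce_bounds:
            lo, hi = DEFAULT_LAMBDA_RANGE
            if not lo <= self.lam <= hi:
                raise ValueError(
                    f"lambda={self.lam} outside [{lo}, {hi}]; "
                    "pass enforce_bounds=False to override"
                )
            wlo, whi = DEFAULT_WEIGHT_RANGE
            if not wlo <= self.weight <= whi:
                raise ValueError(
                    f"weight={self.weight} outside [{wlo}, {whi}]; "
                    "pass enforce_bounds=False to override"
                )
        if self.table.form != "standardized":
            raise ValueError("PseDNC requires a standardized property table")


@dataclass(frozen=True)
class FeatureVector:
    """One encoded sequence: ordered non-negative components summing to 1."""

    values: np.ndarray
    kind: str
    names: tuple[str, ...]
    params: EncoderParams | None = None

    def __len__(self) -> int:
        return len(self.values)


def _residues(seq: SpliceSequence | str) -> str:
    if isinstance(seq, SpliceSequence):
        return seq.residues
    s = str(seq).upper()
    if set(s) - set(_BASES):
        bad = sorted(set(s) - set(_BASES))
        raise ValueError(f"invalid bases {bad} in sequence")
    return s


def _kmer_names(k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(_BASES, repeat=k))


def nac(seq: SpliceSequence | str) -> FeatureVector:
    """Nucleic acid composition: (f(A), f(C), f(G), f(T))."""
    s = _residues(seq)
    if not s:
        raise ValueError("cannot encode an empty sequence")
    counts = np.array([s.count(b) for b in _BASES], dtype=float)
    return FeatureVector(counts / len(s), "nac", tuple(_BASES))


def ktuple_composition(
    seq: SpliceSequence | str, k: int, allow_large: bool = False
) -> FeatureVector:
    """Overlapping k-tuple composition: 4**k components in lexicographic order.

    Normalized by the number of overlapping windows, L - k + 1. k > 7 is
    refused unless ``allow_large=True`` (the feature space grows as 4**k
    and quickly becomes a liability rather than a representation).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > MAX_K and not allow_large:
        raise ValueError(f"k={k} > {MAX_K}; pass allow_large=True to override")
    s = _residues(seq)
    if len(s) < k:
        raise ValueError(f"sequence length {len(s)} < k={k}")
    idx = np.array([_BASE_INDEX[b] for b in s], dtype=np.int64)
    code = np.zeros(len(s) - k + 1, dtype=np.int64)
    for offset in range(k):
        code = code * 4 + idx[offset : offset + len(code)]
    counts = np.bincount(code, minlength=4**k).astype(float)
    return FeatureVector(counts / (len(s) - k + 1), "ktuple", _kmer_names(k))


def dnc(seq: SpliceSequence | str) -> FeatureVector:
    """Dinucleotide composition: the k-tuple composition at k = 2."""
    fv = ktuple_composition(seq, 2)
    return FeatureVector(fv.values, "dnc", fv.names)


@lru_cache(maxsize=8)
def _theta_matrix_cached(cells: tuple[float, ...]) -> np.ndarray:
    arr = np.asarray(cells, dtype=float).reshape(16, 6)
    diff = arr[:, None, :] - arr[None, :, :]
    return (diff**2).mean(axis=2)


def theta_matrix(table: PropertyTable | None = None) -> np.ndarray:
    """16 x 16 matrix of Theta over all ordered dinucleotide pairs."""
    if table is None:
        table = builtin_table()
    return _theta_matrix_cached(tuple(table.as_array().ravel()))


def theta_correlation(
    d1: str, d2: str, table: PropertyTable | None = None
) -> float:
    """Correlation function Theta: mean squared property difference.

    Symmetric, non-negative, and zero iff the two dinucleotides have
    identical standardized property rows (e.g. any strand-symmetric
    pair such as AA/TT).
    """
    d1, d2 = d1.upper(), d2.upper()
    for d in (d1, d2):
        if d not in _DI_INDEX:
            raise KeyError(f"unknown dinucleotide {d!r}")
    return float(theta_matrix(table)[_DI_INDEX[d1], _DI_INDEX[d2]])


def _dinucleotide_codes(s: str) -> np.ndarray:
    idx = np.array([_BASE_INDEX[b] for b in s], dtype=np.int64)
    return idx[:-1] * 4 + idx[1:]


def tier_factors(
    seq: SpliceSequence | str, lam: int, table: PropertyTable | None = None
) -> np.ndarray:
    """Tier correlation factors theta_1 .. theta_lambda.

    theta_j averages Theta between all dinucleotide pairs separated by j
    positions; the denominator is exactly L - j - 1, so lambda may be at
    most L - 2.
    """
    s = _residues(seq)
    L = len(s)
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if lam >= L - 1:
        raise ValueError(
            f"lambda={lam} too large for sequence of length {L} "
            f"(requires lambda <= L-2 = {L - 2})"
        )
    tm = theta_matrix(table)
    codes = _dinucleotide_codes(s)  # length L-1
    thetas = np.empty(lam, dtype=float)
    for j in range(1, lam + 1):
        thetas[j - 1] = tm[codes[: L - 1 - j], codes[j:]].mean()
    return thetas


def psednc(seq: SpliceSequence | str, params: EncoderParams) -> FeatureVector:
    """Pseudo dinucleotide composition: 16 + lambda components summing to 1.

    With w = 0 the vector is the plain DNC padded with lambda zeros.
    """
    comp = dnc(seq).values
    thetas = tier_factors(seq, params.lam, params.table)
    denom = 1.0 + params.weight * thetas.sum()
    values = np.concatenate([comp / denom, params.weight * thetas / denom])
    names = DINUCLEOTIDES + tuple(f"theta{j}" for j in range(1, params.lam + 1))
    return FeatureVector(values, "psednc", names, params)


_LABEL_SIGN = {Label.TRUE_SITE: 1, Label.FALSE_SITE: -1}


@dataclass(frozen=True)
class FeatureMatrix:
    """Encoded dataset: rows in dataset order, labels mapped to +/-1."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    ids: tuple[str, ...]
    kind: str
    params: EncoderParams | None = None

    def to_tsv(self, path: str | Path) -> None:
        """Tab-separated features with a header row and id/label columns."""
        import pandas as pd

        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "id", list(self.ids))
        df.insert(1, "label", self.y.astype(int))
        df.to_csv(path, sep="\t", index=False)

    def to_libsvm(self, path: str | Path) -> None:
        """Sparse libsvm format: ``label index:value ...`` per row."""
        with open(path, "w") as fh:
            for label, row in zip(self.y, self.X):
                feats = " ".join(
                    f"{i + 1}:{v:.10g}" for i, v in enumerate(row) if v != 0.0
                )
                fh.write(f"{int(label)} {feats}\n")


def encode_sequence(
    seq: SpliceSequence | str,
    params: EncoderParams | None = None,
    kind: str = "psednc",
) -> FeatureVector:
    """Encode one sequence with the requested encoder kind."""
    if kind == "psednc":
        return psednc(seq, params if params is not None else EncoderParams())
    if kind == "dnc":
        return dnc(seq)
    if kind == "nac":
        return nac(seq)
    raise ValueError(f"unknown encoder kind {kind!r}")


def encode_dataset(
    ds: LabeledDataset,
    params: EncoderParams | None = None,
    kind: str = "psednc",
) -> FeatureMatrix:
    """Encode every sequence of a labeled dataset into a feature matrix.

    Row order follows dataset order; labels map true_site -> +1,
    false_site -> -1. Any per-sequence failure aborts naming the record.
    """
    if len(ds) == 0:
        raise ValueError("cannot encode an empty dataset")
    rows, labels, names = [], [], None
    for s in ds:
        if s.label not in _LABEL_SIGN:
            raise ValueError(f"record {s.id!r} is unlabeled; encode_dataset needs labels")
        try:
            fv = encode_sequence(s, params, kind)
        except Exception as exc:
            raise type(exc)(f"record {s.id!r}: {exc}") from exc
        rows.append(fv.values)
        labels.append(_LABEL_SIGN[s.label])
        names = fv.names
    return FeatureMatrix(
        np.vstack(rows),
        np.array(labels, dtype=int),
        names,
        tuple(s.id for s in ds),
        kind,
        params,
    )
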