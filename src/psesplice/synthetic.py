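"""Synthetic splice-site benchmark generator with a controllable signal.

The generator emulates the architecture of real splice-site benchmark
windows without reproducing any real corpus:

* every window (positive or negative) carries the canonical signal —
  GT for donor, AG for acceptor — at the centre;
* a negative window is otherwise homogeneous: all remaining positions
  are drawn i.i.d. from a genic background composition;
* a positive window is a composite of two sequence classes, because a
  true site sits on an exon|intron boundary. One half keeps the
  background (exon-like) composition while the intron half drifts
  toward an intron-proximal composition (T-rich downstream of a donor;
  polypyrimidine-rich upstream of an acceptor). On top of that, the
  +/-6 bp flanking the site are drawn from a position-specific
  consensus profile built from the canonical mammalian motifs
  (MAG|GTRAGT for donors, polypyrimidine tract + YAG| for acceptors).

A single dial, ``consensus_strength`` in [0, 1], linearly mixes both
the flank profile and the intron-half composition with the background:
at strength 0 positives and negatives are distributionally identical;
at strength 1 the full signal is present. The exact profile weights are
a documented constant of this package, not a measured property of any
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import Label, LabeledDataset, SiteType, SpliceSequence, write_fasta

_BASES = "ACGT"

#: Genic background composition (A, C, G, T); negatives and the exon
#: half of positives are drawn from this.
BACKGROUND = (0.24, 0.26, 0.28, 0.22)

#: Donor-proximal intron composition (T-rich, as just downstream of a
#: 5' splice site).
INTRON_DONOR = (0.26, 0.14, 0.16, 0.44)

#: Acceptor-proximal intron composition (polypyrimidine tract, as just
#: upstream of a 3' splice site).
INTRON_ACCEPTOR = (0.10, 0.35, 0.10, 0.45)

# Flank consensus profiles at full strength: 6 positions upstream then 6
# downstream of the central dinucleotide. None means "use the local
# context composition" (no positional preference there).
_M = (0.5, 0.5, 0.0, 0.0)   # A or C
_R = (0.5, 0.0, 0.5, 0.0)   # A or G
_Y = (0.0, 0.65, 0.0, 0.35)
_PY = (0.07, 0.40, 0.08, 0.45)

DONOR_FLANK_PROFILE = (
    None, None, None, _M, (1, 0, 0, 0), (0, 0, 1, 0),       # ..MAG | GT
    _R, (1, 0, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1), None, None,  # GT | RAGT..
)

ACCEPTOR_FLANK_PROFILE = (
    _PY, _PY, _PY, _PY, _PY, _Y,                             # polypyrimidine + Y | AG
    (0.20, 0.10, 0.55, 0.15), None, None, None, None, None,  # AG | G..
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the donor benchmark scale."""

    n_pos: int = 2796
    n_neg: int = 2800
    length: int = 140
    site_type: SiteType = SiteType.DONOR
    center_offset: int = 70  # 1-based position of the first signal base
    consensus_strength: float = 1.0
    background: tuple[float, float, float, float] = BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.length < 20 or self.length % 2:
            raise ValueError(f"length must be even and >= 20, got {self.length}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        if not 0.0 <= self.consensus_strength <= 1.0:
            raise ValueError("consensus_strength must lie in [0, 1]")
        if not 7 <= self.center_offset <= self.length - 7:
            raise ValueError(
                f"center_offset={self.center_offset} leaves no room for the "
                f"+/-6 bp flank in a window of length {self.length}"
            )


def _mix(profile, context: np.ndarray, s: float) -> np.ndarray:
    if profile is None:
        return context
    return s * np.asarray(profile, dtype=float) + (1.0 - s) * context


def _position_distributions(config: SimConfig, positive: bool) -> list[np.ndarray | None]:
    """Per-position base distributions; None marks the fixed signal."""
    L = config.length
    c0 = config.center_offset - 1  # 0-based index of the first signal base
    s = config.consensus_strength
    bg = np.asarray(config.background, dtype=float)
    dists: list[np.ndarray | None] = [bg] * L
    dists[c0] = None
    dists[c0 + 1] = None
    if not positive:
        return dists
    if config.site_type is SiteType.DONOR:
        intron = np.asarray(INTRON_DONOR, dtype=float)
        flank = DONOR_FLANK_PROFILE
        upstream_ctx, downstream_ctx = bg, s * intron + (1 - s) * bg
    else:
        intron = np.asarray(INTRON_ACCEPTOR, dtype=float)
        flank = ACCEPTOR_FLANK_PROFILE
        upstream_ctx, downstream_ctx = s * intron + (1 - s) * bg, bg
    for i in range(c0):
        dists[i] = upstream_ctx
    for i in range(c0 + 2, L):
        dists[i] = downstream_ctx
    flank_positions = list(range(c0 - 6, c0)) + list(range(c0 + 2, c0 + 8))
    for k, i in enumerate(flank_positions):
        ctx = upstream_ctx if i < c0 else downstream_ctx
        dists[i] = _mix(flank[k], ctx, s)
    return dists


def _region_map(config: SimConfig, positive: bool) -> str:
    """Per-position generator-region codes for the truth manifest.

    S = fixed signal, F = consensus flank, U/D = upstream/downstream
    context of a positive, B = background of a negative.
    """
    L = config.length
    c0 = config.center_offset - 1
    codes = ["B"] * L if not positive else ["U"] * c0 + ["?", "?"] + ["D"] * (L - c0 - 2)
    codes[c0] = "S"
    codes[c0 + 1] = "S"
    if positive:
        for i in list(range(c0 - 6, c0)) + list(range(c0 + 2, c0 + 8)):
            codes[i] = "F"
    return "".join(codes)


def _draw_class(
    rng: np.random.Generator, config: SimConfig, positive: bool, n: int
) -> list[str]:
    L = config.length
    signal = config.site_type.signal
    dists = _position_distributions(config, positive)
    mat = np.empty((n, L), dtype="U1")
    for i, dist in enumerate(dists):
        if dist is None:
            continue
        mat[:, i] = rng.choice(list(_BASES), size=n, p=dist / dist.sum())
    c0 = config.center_offset - 1
    mat[:, c0] = signal[0]
    mat[:, c0 + 1] = signal[1]
    return ["".join(row) for row in mat]


def simulate(config: SimConfig) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate a labeled dataset plus a truth manifest.

    Fully reproducible from ``config.seed``; every record passes
    benchmark validation at the configured length and centre offset.
    The manifest records, per sequence, the region code of every
    position (see :func:`_region_map`) together with the generating
    distributions, so downstream analyses can condition on what was
    actually sampled.
    """
    rng = np.random.default_rng(config.seed)
    site = config.site_type.value
    pos_seqs = _draw_class(rng, config, True, config.n_pos)
    neg_seqs = _draw_class(rng, config, False, config.n_neg)
    sequences = [
        SpliceSequence(f"{site}_pos_{i + 1}", s, config.site_type, Label.TRUE_SITE)
        for i, s in enumerate(pos_seqs)
    ] + [
        SpliceSequence(f"{site}_neg_{i + 1}", s, config.site_type, Label.FALSE_SITE)
        for i, s in enumerate(neg_seqs)
    ]
    ds = LabeledDataset(sequences, config.site_type)
    pos_map = _region_map(config, True)
    neg_map = _region_map(config, False)
    manifest = pd.DataFrame(
        {
            "id": [s.id for s in sequences],
            "label": [s.label.value for s in sequences],
            "site_type": site,
            "consensus_strength": config.consensus_strength,
            "seed": config.seed,
            "region_map": [pos_map] * config.n_pos + [neg_map] * config.n_neg,
        }
    )
    return ds, manifest


def write_outputs(
    ds: LabeledDataset, manifest: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write one FASTA per class plus the tab-separated truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = LabeledDataset([s for s in ds if s.label is Label.TRUE_SITE], ds.site_type)
    neg = LabeledDataset([s for s in ds if s.label is Label.FALSE_SITE], ds.site_type)
    paths = {
        "positives": out_dir / "positives.fasta",
        "negatives": out_dir / "negatives.fasta",
        "manifest": out_dir / "manifest.tsv",
    }
    write_fasta(pos, paths["positives"])
    write_fasta(neg, paths["negatives"])
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths
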