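"""Windowed structural-property profiles along splice-site windows.

For one sequence, the per-position track of a property assigns to
position i (1-based, 1 <= i <= L-1) the table value of the dinucleotide
starting there. A dataset profile averages the tracks over sequences
and then smooths with a sliding window (default 10 bp, step 5 bp);
because all sequences share one length, averaging and windowing
commute. True-site and false-site profiles diverge near the window
centre when a site signal is present, which is the visual argument for
feeding these properties into the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import LabeledDataset, SpliceSequence
from .structural_props import PROPERTY_NAMES, PropertyTable, builtin_table


@dataclass(frozen=True)
class StructuralProfile:
    property_name: str
    centers: np.ndarray  # 1-based window centre positions, bp
    means: np.ndarray
    window: int
    step: int


def position_track(
    seq: SpliceSequence | str,
    prop: str,
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Per-position property values; length L - 1."""
    if table is None:
        table = builtin_table()
    if prop not in PROPERTY_NAMES:
        raise KeyError(f"unknown property {prop!r}; expected one of {PROPERTY_NAMES}")
    residues = seq.residues if isinstance(seq, SpliceSequence) else str(seq).upper()
    col = table.values[prop]
    return np.array(
        [col[residues[i : i + 2]] for i in range(len(residues) - 1)], dtype=float
    )


def windowed_means(track: np.ndarray, window: int = 10, step: int = 5):
    """Sliding-window means anchored at position 1; partial tail dropped.

    Returns (centers, means) where a window covering track positions
    s+1 .. s+window (1-based) is reported at centre s + (window+1)/2.
    """
    track = np.asarray(track, dtype=float)
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > track.size:
        raise ValueError(f"window {window} exceeds track length {track.size}")
    n_windows = (track.size - window) // step + 1
    starts = np.arange(n_windows) * step
    means = np.array([track[s : s + window].mean() for s in starts])
    centers = starts + (window + 1) / 2.0
    return centers, means


def dataset_profile(
    ds: LabeledDataset,
    prop: str,
    window: int = 10,
    step: int = 5,
    table: PropertyTable | None = None,
) -> StructuralProfile:
    """Windowed mean property track averaged over a dataset."""
    if len(ds) == 0:
        raise ValueError("cannot profile an empty dataset")
    mean_track = np.mean(
        [position_track(s, prop, table) for s in ds], axis=0
    )
    centers, means = windowed_means(mean_track, window, step)
    return StructuralProfile(prop, centers, means, window, step)


def all_profiles(
    ds: LabeledDataset,
    window: int = 10,
    step: int = 5,
    table: PropertyTable | None = None,
) -> pd.DataFrame:
    """All six properties in one table: window_center plus one column each."""
    out = {}
    centers = None
    for prop in PROPERTY_NAMES:
        profile = dataset_profile(ds, prop, window, step, table)
        centers = profile.centers
        out[prop] = profile.means
    df = pd.DataFrame(out)
    df.insert(0, "window_center", centers)
    return df


def write_profiles(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def plot_profiles(df: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render the profile table to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for prop in PROPERTY_NAMES:
        ax.plot(df["window_center"], df[prop], label=prop)
    ax.set_xlabel("window centre (bp)")
    ax.set_ylabel("standardized property value")
    if title:
        ax.set_title(title)
    ax.legend(ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
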