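"""Windowed structural-property profiles of true vs false windows.

Per-position structural property tracks are averaged over sequences
and smoothed (10 bp windows, 5 bp step). True-site windows diverge
from false-site windows around the centre, where the splice signal and
its consensus context sit — the visual motivation for building the
encoder on these six properties.
"""

from psesplice import Label, LabeledDataset, all_profiles
from psesplice.synthetic import SimConfig, simulate

ds, _ = simulate(SimConfig(n_pos=200, n_neg=200, site_type="donor",
                           consensus_strength=1.0, seed=9))
pos = LabeledDataset([s for s in ds if s.label is Label.TRUE_SITE], "donor")
neg = LabeledDataset([s for s in ds if s.label is Label.FALSE_SITE], "donor")

true_profiles = all_profiles(pos, window=10, step=5)
false_profiles = all_profiles(neg, window=10, step=5)

gap = (true_profiles.drop(columns="window_center")
       - false_profiles.drop(columns="window_center")).abs().mean(axis=1)

print("window_center   mean |true - false| across the six properties")
for center, g in zip(true_profiles.window_center, gap):
    marker = " <- splice signal" if abs(center - 70) <= 5 else ""
    print(f"{center:>13.1f}   {g:.4f} {'#' * int(g * 60)}{marker}")

print("\nThe divergence peaks at the central windows (the GT signal and its")
print("consensus flank) and stays elevated on the intron side, whose")
print("composition differs from background in true windows.")
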