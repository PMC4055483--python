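"""Generate a synthetic donor benchmark and cross-validate the pipeline.

The generator emulates splice-site windows: every record carries GT at
positions 70-71; positives additionally carry the donor consensus at
the +/-6 bp flank and an exon|intron compositional asymmetry, both
scaled by consensus_strength. At strength 0 the classes are identical
and accuracy sits at chance; at strength 1 the pipeline should exceed
90% — the dial demonstrates that the classifier tracks genuine signal
rather than an artifact.
"""

from psesplice import EncoderParams, TrainingConfig, kfold
from psesplice.synthetic import SimConfig, simulate

params = EncoderParams(lam=4, weight=0.3)
config = TrainingConfig(c_grid=(1.0, 8.0, 64.0), gamma_grid=(1.0, 8.0, 64.0),
                        cv_folds=10, seed=7)

print("consensus_strength   Sn      Sp      Acc     MCC")
for strength in (0.0, 0.5, 1.0):
    ds, _ = simulate(SimConfig(n_pos=300, n_neg=300, site_type="donor",
                               consensus_strength=strength, seed=7))
    report = kfold(ds, params, config)
    m = report.metrics
    mcc = f"{m.mcc:.3f}" if m.mcc_defined else "undef"
    print(f"{strength:>17.1f}   {m.sn:.3f}   {m.sp:.3f}   {m.acc:.3f}   {mcc}")

print("\nEach row is a stratified 10-fold cross-validation of 600 windows,")
print("with (C, gamma) grid-searched once on the full data first.")
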