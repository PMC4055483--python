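# Methods

This note records the modelling choices behind `psesplice`: what is
computed, which parameters matter, what the synthetic benchmark does
and does not emulate, and the numerical conventions.

## Encoding

A window `D = R1..RL` over `{A,C,G,T}` is represented by pseudo
dinucleotide composition. The 16 overlapping dinucleotide frequencies
`f_u` (lexicographic order AA..TT, normalized by `L−1`) are augmented
with `λ` tier correlation factors

    θ_j = 1/(L−j−1) · Σ_{i=1}^{L−j−1} Θ(R_i R_{i+1}; R_{i+j} R_{i+j+1}),

where `Θ(X; Y)` is the mean over six structural properties of the
squared difference of standardized property values. The final vector is

    d_u = f_u / (1 + w Σθ_j)        (u ≤ 16)
    d_u = w θ_{u−16} / (1 + w Σθ_j) (u > 16),

which always sums to exactly 1 because the `f_u` do. The implementation
uses the simplified denominator `1 + wΣθ` (`Σf = 1` analytically); the
tests verify both forms agree. `θ_j` requires `λ ≤ L − 2`; violating
lengths are rejected naming the offending record.

Parameters, defaults and meaning:

| parameter | default | meaning |
|---|---|---|
| `λ` (tiers) | 4 | how many correlation ranks of sequence order are counted; unit-free count, searched over 1–10 |
| `w` (weight) | 0.3 | relative weight of sequence-order vs composition; unit-free, searched over [0, 1] |
| window length | 140 nt | benchmark convention; signal at 1-based 70–71, configurable |

`w = 0` reduces PseDNC to DNC exactly (tests assert this), so the DNC
baseline is the same code path. NAC and general k-tuple composition are
provided as utilities; k is capped at 7 by default because the 4^k
feature space beyond that is a dimensionality liability, not a
representation.

## Structural property tables

The six base-pair-step parameters (twist, tilt, roll; shift, slide,
rise) are embedded in two forms: the original molecular-dynamics values
and the published standardized values. Standardization is the z-score
across the 16 dinucleotides with the **sample (n−1) SD** — the only
convention that reproduces the published standardized table at printed
precision for twist, tilt, shift, slide and rise. Two facts drive the
design:

1. The published standardized **roll** column is *not* the z-score of
   the published original roll column under any SD convention (e.g. GC:
   2.30 recomputed vs 1.33 published); it is consistent with an
   unpublished source column. We do not guess that source.
2. Both tables are strand-symmetric (AA=TT, AC=GT, AG=CT, CA=TG, GA=TC,
   CC=GG), which makes `Θ` invariant under complementing both
   arguments — asserted over all 256 pairs.

Consequently the published standardized table is embedded verbatim and
is **canonical for all encoding**; `standardize()` exists for
user-supplied property sets (TSV import/export) and is tested for zero
mean, unit sample variance, idempotence and affine invariance. Units of
the original columns are irrelevant after standardization.

## Classifier

An RBF-kernel SVM (scikit-learn's `SVC`, which wraps the libsvm
solver). `(C, γ)` are tuned by exhaustive grid search over the
conventional powers-of-two lattices `C ∈ 2^{−5..15}`, `γ ∈ 2^{−15..3}`
(step 2²) under seeded, stratified 10-fold cross-validation; the same
folds are reused for every cell, ties resolve to smallest `C` then
smallest `γ` (smoother models first). Stratification is the
low-variance choice for these near-balanced benchmarks; no class
weighting is applied. Model bundles persist the SVM together with the
encoder parameters so prediction re-encodes inputs identically;
feature-width mismatches are hard errors.

No feature scaling is applied before the SVM: PseDNC components already
live in [0, 1] on a common scale (an optional hook exists for
experimentation).

## Evaluation

Metrics are computed from miscall counts (FN out of N⁺ positives, FP
out of N⁻ negatives): `Sn = 1 − FN/N⁺`, `Sp = 1 − FP/N⁻`,
`Acc = 1 − (FN+FP)/(N⁺+N⁻)`, and the rewritten MCC

    MCC = (1 − (FN/N⁺ + FP/N⁻)) / sqrt((1 + (FP−FN)/N⁺)(1 + (FN−FP)/N⁻)).

This is algebraically identical to the confusion-matrix MCC; the tests
verify the identity exhaustively over all 169 count configurations at
N⁺ = N⁻ = 12. When every prediction falls in one class a factor under
the root is ≤ 0 and MCC is reported as NaN with an explanatory flag —
never silently clamped.

Protocols:

* **jackknife** — leave-one-out at fixed `(λ, w, C, γ)`; trains exactly
  n models (asserted by a counting test). `(C, γ)` are tuned **once on
  the full data** beforehand, not re-tuned per split; re-tuning inside
  each of ~5,600 splits would multiply cost by the grid size for no
  change in the protocol's verdict.
* **k-fold** — seeded stratified folds; with `k = n` it degenerates to
  leave-one-out and reproduces the jackknife exactly (tested).
* **(w, λ) optimization** — outer grid over the box `0 ≤ w ≤ 1`,
  `1 ≤ λ ≤ 10` (step 0.1 / all integers by default), `(C, γ)`
  re-tuned inside every cell; the full accuracy surface is returned so
  selection effects stay visible. No multiple-testing correction is
  applied across the surface — by design, it is a tuning surface, not
  a hypothesis test.

One caveat worth knowing: on **null** data (no class signal) with a
near-constant kernel (tiny `γ` relative to feature distances) the SVM
degenerates to a majority vote, and leave-one-out then scores far
*below* chance — removing the held-out sample tips the training
majority against its class. This is an artifact of LOO + majority
voting, not of the implementation; the null-calibration tests therefore
use a discriminative kernel width.

## Synthetic benchmark generator

The generator emulates the *architecture* of splice-site benchmark
windows, at the published scale by default (2,796 positives / 2,800
negatives, 140 nt, donor signal at 70–71):

* every window, either class, carries the canonical GT (donor) or AG
  (acceptor) at the centre;
* negatives are otherwise i.i.d. from a genic background composition
  (A 0.24, C 0.26, G 0.28, T 0.22 by default);
* positives model the exon|intron boundary that a true site sits on:
  the exon half keeps the background composition while the intron half
  drifts toward an intron-proximal composition — T-rich
  (0.26/0.14/0.16/0.44) downstream of a donor, polypyrimidine
  (0.10/0.35/0.10/0.45) upstream of an acceptor — and the ±6 bp flank
  follows position-specific consensus profiles built from the
  canonical mammalian motifs (MAG|GTRAGT donor, polypyrimidine + YAG|
  acceptor).

A single dial, `consensus_strength ∈ [0, 1]`, linearly mixes both the
flank profiles and the intron-half composition with the background; at
0 the classes are generated identically (the null), at 1 the full
signal is present. The half-window compositional component is part of
the design deliberately: a localized 12-bp motif alone is
information-theoretically invisible to *global* composition features —
its effect on 16 dinucleotide frequencies over 140 nt is far below
sampling noise at realistic sample sizes — whereas real true-site
windows differ from false ones across the whole window precisely
because one half is intron. Without that component a composition-based
pipeline could never separate the classes well, however strong the
motif.

All profile weights are documented constants of this package, chosen
once as a caricature of real splice-site context; they are not
estimates from any genome. What passing tests show: the pipeline's
accuracy tracks genuine, dialled signal monotonically (≈0.51 at
strength 0 to ≈0.95 at strength 1 for 300+300 donor windows, 5-seed
means) and is calibrated at the null. What they do not show: accuracy
on real genomic data, which has positional correlations, repeat
structure and compositional heterogeneity the i.i.d. generator does not
emulate. Reproducing published real-data accuracies requires the
original benchmark corpora, which cannot be redistributed here; the
`cv` command runs them unchanged when supplied.

## Problem sizes and numerics

The test suite and examples run the pipeline at 300+300 windows with a
compact `(C, γ)` grid (`{1, 8, 64}²`), sizes at which the full sweep of
5 strengths × 5 seeds completes in well under a minute while leaving
the conclusions (chance at null, >0.9 at full strength, monotone in
between) unambiguous. Tolerances: encoder equivalence with the
brute-force oracle at 1e−10 and component sums at 1e−12 (pure
floating-point identities); table reproduction at the published 2
decimals; grid-search ties at 1e−12. Windowed profiles anchor at
position 1 and drop the final partial window; window centres are
reported at `start + (window+1)/2` so a 10-bp window starting at 1 is
plotted at 5.5. Averaging over sequences and windowing commute for
equal-length inputs (asserted numerically), so the implementation
windows the dataset-mean track.

## Known limitations

* The generator draws positions independently; it cannot express
  branch-point spacing constraints or higher-order dependencies.
* The published roll column's provenance is unresolved upstream; all
  encodings inherit the published standardized values by design.
* Jackknife at benchmark scale (~5,600 windows) trains ~5,600 SVMs and
  is CPU-hours work; the stratified 10-fold protocol is the practical
  proxy and agrees closely at these sample sizes.
* Only the two-class, single-label formulation is supported; multilabel
  metric systems are out of scope.
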