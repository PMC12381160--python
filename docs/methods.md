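# Methods

`chirsep` predicts whether a diastereomeric salt resolution experiment —
a racemate, an enantiopure resolving agent and a solvent system — will
succeed. This note documents the model, its assumptions, the numerical
choices made where the design was genuinely open, and what the synthetic
test harness does and does not establish.

## Figures of merit and labels

An experiment is summarised by the solid mass fraction
`m_frac = m_solid / m_initial` and the enantiomeric excess
`ee = |chi_R - chi_S|` of the recovered solid, with the combined score
`z = m_frac * ee` (z = 0.5 is the ideal resolution of a racemic feed: half
the mass crystallises, enantiopure). Labels:

* **retrospective hit** — `m_frac > 0.20` and `ee > 0.25` (strict);
* **low-noise** — `m_frac >= 0.20`; below this, outcomes are dominated by
  kinetics and termination artefacts and the labels are not trusted;
* **prospective hit** — full dissolution before crystallisation and
  `z >= 0.25`.

Records whose `ee` exceeds the maximum attainable at their `m_frac`
(1 for `m_frac <= 0.5`, else `(1 - m_frac)/m_frac`, assuming a racemic
50:50 feed) by more than a 5% experimental-error band are discarded before
modelling. A record with `m_frac = 0` has no solid; its `ee` is stored as 0
by convention and flagged (`ee_imputed`).

## Atom-density representation

Each conformer snapshot of an acid–base complex is encoded per non-hydrogen
atom *i* as `A1 || A2 || A3`:

* `A1` (7 values): nuclear charge, group, period, partial charge, s/p/d
  orbital populations.
* `A2(i)^w(r) = sum_{j != i} w_ij G_ij(r)`: two-body weighted density.
* `A3(i)^{w,phi}(r) = sum_{j,k != i, j != k} w_ij w_ik w_jk G_ij(r)
  phi(theta_ijk)`: three-body profile; `phi` is cos or sin of the angle at
  the central atom.

`G_ij` is a normalised Gaussian of width `sigma = 0.0825` Å centred at the
interatomic distance, evaluated at 160 bin centres spanning 0.7–8 Å
(endpoints inclusive, point evaluation rather than bin integration — the
simplest reading of binning a smooth profile). Neighbours beyond 8 Å are
cut off hard; at this Gaussian width the truncated tail is below machine
precision for in-range bins, so no switching function is needed.

Seven weighting channels inject electronic structure: orbital overlaps
`eps_sigma/eps_pi/eps_delta` (short-ranged, decaying exponentially), the
charge product `q_i*q_j` and population products `p^sigma/p^pi/p^delta`
(distance-independent, long-ranged). Decisions taken where the combination
rule was open:

* the p-channel pair weight is the product `p*_i * p*_j`, mirroring the
  stated `q_ij = q_i * q_j` product;
* the three-body sum runs over ordered neighbour pairs `(j, k)` with
  `j != k` (the angle of an atom with itself is undefined); each unordered
  pair therefore contributes once through each Gaussian centre;
* the "principal angle" is taken at the central atom *i*;
* hydrogens are excluded as centres but included as neighbours (they carry
  charge in the q channel); a flag flips this;
* by default the long-range channels honour the same 8 Å cutoff; the
  `long_range_unbounded` flag removes it.

Per-atom snapshot length: 7 + 7·160 + 14·160 = 3367. A trajectory is
summarised by concatenating the per-frame mean and **population** standard
deviation (ddof = 0, fixed convention): 6734 values per atom. The whole
construction depends only on distances, angles and scalar atom properties,
so it is fully E(3)-invariant *including reflections* — a single complex
cannot leak chirality; chirality sensitivity arises only at the pair level.

## Electronic weight providers

The channels come from a pluggable provider. The default surrogate is a
deterministic, self-contained electronic model: electronegativity-
equalisation charges `q_i = (chi_bar - chi_i)/eta_i` (neutral molecules,
charges sum to zero exactly), neutral-valence orbital populations adjusted
by the charge, and overlaps
`eps*_ij = cap*_i cap*_j exp(-(d_ij - r_cov,i - r_cov,j)/lambda)` with
`lambda = 0.5` Å (covalent-overlap scale, configurable) and per-element
sigma/pi/delta capacities; delta capacities vanish for the supported
main-group set (H, C, N, O, F, P, S, Cl, Br, I). An adapter can instead
ingest a parsed semi-empirical output file (charges/populations block plus
three overlap blocks); the library never executes external codes.

## Pair construction

The two diastereomeric complexes (R and S substrate against the same agent)
are featurised independently, compressed per atom from 6734 to 20 dimensions,
and combined token-wise into a mean stream `(z_R + z_S)/2` and an absolute
difference stream `|z_R - z_S|`. The diff stream is identically zero iff the
two complexes are isometric (achiral agent) — the physically required
behaviour, since swapping R and S labels also leaves both streams unchanged.

The compressor is a symmetric two-hidden-layer autoencoder (tanh hidden
layers, linear latent, Adam on standardised inputs) with a PCA alternative
(`compressor.kind`). It is trained per cross-validation fold on that fold's
training atoms only, to keep test complexes out of the fit. The full 6734
vector is compressed (A1 features are not passed through raw). Solvent
mixtures are molar-fraction-weighted sums of pure-solvent descriptor rows.

## Model

Both streams are processed by independent stacks of pre-norm transformer
blocks (multi-head self-attention + ReLU feedforward, no positional
encoding — atom tokens form a set, and the output is token-permutation
invariant). The processed tokens of both streams are concatenated and pooled
by cross-attention in which the embedded solvent descriptor is the single
query (the alternative, solvent as an extra token, sits behind
`solvent_as_token`). A two-layer head maps the pooled vector to outputs.

Defaults: 2 blocks per stream, 4 heads, token width 64, feedforward 128,
dropout 0.1, seed in the config. The network runs on a small in-package
reverse-mode autodiff engine over numpy (gradient-checked against finite
differences), so forward passes and training are bit-reproducible for a
fixed seed on a single thread.

## Two-stage training

* **Stage 1 (regression):** all records, including the noisy low-`m_frac`
  ones, with squared error on `(m_frac, ee)` (config `stage1_target`; a
  single-target `z` variant is provided since the regression target is a
  free choice). Adam, minibatches, a ~10% racemate-grouped validation split
  for best-checkpoint selection.
* **Stage 2 (classification):** the head is replaced and every other
  parameter frozen (asserted bit-identical via SHA-256 fingerprints before
  and after). Training uses the low-noise subset only, with weighted
  sampling giving an expected 50/50 class mix per batch. Because the
  backbone is frozen, each record's pooled vector is fixed; it is computed
  once in evaluation mode and the head is fine-tuned on the cached features
  with binary cross-entropy.

Evaluation uses racemate-grouped k-fold splits (greedy size-balanced
assignment of shuffled racemates — the grouping requirement fixes only that
no racemate spans folds), pooled across folds by default. Metrics: the
enrichment factor `EF(n) = (hits in top n)/(n H / N)` (EF(N) = 1 by
construction) and standard step-integrated average precision; rankings sort
scores descending with ties broken by stable record order. Agent ranking for
a new racemate scores each agent by the maximum ensemble probability across
solvent systems.

## Attention–contact analysis

Crystal neighbours are heavy-atom pairs within 3.5 Å in the salt crystal
coordinates (single asymmetric unit; symmetry images out of scope).
Attention matrices are symmetrised as `(A + A^T)/2`; for every
(stream, block, head) the mean symmetrised attention over neighbour and
non-neighbour unordered pairs is compared with the uniform baseline `1/T`.
Both streams are analysed and reported separately. Trajectory-level
representations give a single attention matrix per pair, so no frame
averaging arises.

## Synthetic data: what it emulates and what it does not

The generator builds tetrahedral stereocentres with four distinct
substituent fragments; the S substrate is the exact `x -> -x` mirror of the
R substrate posed against a shared agent. Planar agents placed in the mirror
plane give exactly mirrored complexes (diff stream exactly zero); chiral
agents give genuine diastereomers. Conformer ensembles replace molecular
dynamics with seeded Gaussian jitter plus a rigid agent rattle inside a
1.6–4.5 Å contact band; the dynamics protocol being emulated (2 Å initial
contact, square-well restraint, 500 K warm-up at 0.25 fs, sampling every
5 ps at 0.5 fs, Langevin thermostat, 200 snapshots) is stored verbatim as
metadata, and the FrameSet interface lets a real MD backend slot in. For a
diastereomer pair one set of random operations is drawn and the S member
receives the mirrored operations, so achiral-agent pairs stay exactly
mirrored frame by frame.

Screening grids plant a logistic hit model in compressed diff space:
`p = sigmoid(slope * (s_pair + c_solv * s_solvent) + b)` where `s_pair` is a
fixed random direction applied to the token-mean of the PCA-compressed diff
stream, standardised over the grid. The intercept is calibrated by bisection
so the expected post-label-noise hit rate matches the target (default 3%,
the historical rate; label-flip noise 1%). Hit outcomes draw
`m_frac ~ U(0.22, 0.5), ee ~ U(0.30, 0.95)`; non-hits are either low-noise
failures (`m_frac ~ U(0.20, 0.55), ee ~ U(0, 0.22)`, 45% of non-hits) or
slurry/no-solid outcomes (`m_frac < 0.2`). With ~4% overall hits this puts
roughly 8% hits in the low-noise subset, mirroring the class balance the
method is designed for.

Because the signal lives in compressed-diff space, recovering it exercises
featurisation, compression, pair assembly and the model jointly. What
passing does **not** show: the toy complexes sit at the small end of
realistic sizes (~12–15 heavy atoms), jitter ensembles have none of the
conformational structure of real trajectories, the surrogate electronic
model is not a quantum-chemistry method, and a planted linear signal says
nothing about how learnable real crystallisation outcomes are.

## Problem sizes and defaults in the test harness

The end-to-end recovery checks run on a 30 racemate x 20 agent x 2 solvent
grid with 16 frames per complex and a 3-member ensemble, a scale chosen so
the full suite runs comfortably on a single CPU while leaving ~45 hits in
the grid; the learning-curve check reuses the same grid with nested training
subsets at fractions 0.25/0.5/1. The pipeline in these checks uses the PCA
compressor (deterministic, faster); the autoencoder path is unit-tested
separately.

## Known limitations

* The surrogate charges are geometry-independent, so the q/p channel
  *weights* do not fluctuate across frames (the profiles still do through
  the Gaussians).
* The autoencoder is trained whole-batch per epoch with a fixed epoch count;
  no early stopping.
* `EF`/`AP` require at least one hit; callers must filter degenerate folds.
* Crystal contact analysis ignores periodic images and symmetry mates.
* Training-time hyperparameters (steps, learning rates, batch sizes) are
  fixed defaults in `TrainConfig`; no hyperparameter search is included.
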