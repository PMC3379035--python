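# Methods

## Model

A kinase's phosphosite specificity is modelled position-wise over the
15-residue window centered on the phospho-acceptor (offsets −7..+7, center
restricted to S/T/Y).  The substrate alphabet has 21 symbols — the 20 amino
acids plus `x`, which stands both for unknown residues and for positions
falling outside the protein when a site lies near a chain terminus; padding
with `x` keeps all training windows the same length.  The window length 15
follows the observation that offsets beyond ±4 still carry usable signal for
some kinases while longer windows mostly add noise.

### Profiles, background, PSSM

The profile `P_k` is the maximum-likelihood column-stochastic 21×15
frequency matrix of kinase *k*'s confirmed substrate windows (pseudocount 0
by default: raw profiles legitimately contain many zeros; Laplace smoothing
is available but changes none of the package's defaults).  The background
`B` pools all windows over the offsets not in {−3, −2, 0, +1}; those four
are excluded because they are the most strongly biased by kinase recognition
(lowest entropy), so the remaining offsets approximate the amino-acid
composition of phosphorylatable protein surface.

The scoring matrix is the power-smoothed contrast

    M_k(i, j) = sign(P_k(i,j) − B(i)) · |P_k(i,j) − B(i)|^e ,  e = 1.2.

Unlike the classical log-odds `log(P/B)`, this is finite on zero profile
entries, vanishes exactly where profile equals background, and keeps the
positive/negative-determinant sign logic.  The exponent (default 1.2, the
value found empirically to give the best predictions in this family of
methods) mildly de-emphasizes small fluctuations while preserving order;
both the exponent and the functional form are configurable, and the raw
log-odds matrix is available as a documented reference
(`matrices.log_odds_matrix`).  A candidate window is scored by the additive
sum of its 15 looked-up entries; the acceptance threshold is 0 (a score of
exactly 0 is accepted).

### Consensus calling

Per profile column the most probable amino acid is emitted uppercase when
its probability is ≥ 0.15, lowercase in [0.08, 0.15), and as the don't-care
symbol `x` below 0.08.  The two boundaries are closed from below so the
bands partition [0, 1]; argmax ties break by fixed alphabet order; the `x`
row never wins the argmax (the consensus `x` means "no preference", not the
padding symbol).

### SDR detection

For domain column *i* and substrate offset *j* two detectors are combined:

* **Mutual information** `I(i, j)` (base 2; the base only rescales all
  scores by a constant, so SDR ranking is base-invariant — tested).  The
  domain variable ranges over 20 residues + gap, the substrate variable over
  20 residues + `x`.
* **Charge dependency** `C(i, j)`: the expectation of the residue
  interaction matrix `R(substrate, domain)` under the joint distribution of
  the two positions.  For the consensus variant this is exactly the mean
  `(1/n) Σ_k R(y_k, x_k)` over training kinases; the expectation form is the
  unique consistent extension to the profile variant's fractional joints.

`R` encodes side-chain physics: D/E and K/R repel within a charge class
(−2) and attract across (+2); histidine is weakly positive (+1 with acidic,
−1 with basic residues and itself); F/I/L/V attract each other (+2) and
repel charged residues (−1); S/T/Y weakly bind each other (+0.5).
Substrate-side glycine gets +0.5 against every domain residue (a small
residue opens a pocket for the domain; domain-side glycine carries no bonus
because domain 3-D context is unknown), substrate-side proline defaults to
0.  The `x` row and gap column are identically zero.  The G and P rows and
the hydrophobic/charged pairings are the places where the published prose
underdetermines the numbers; the chosen defaults are documented
approximations and the whole matrix can be replaced via TSV.

The combination is the product `C_c = I · C`.  The product (rather than a
weighted sum, which is selectable) is the minimal form that reproduces the
intended behavior: strongly conserved charged columns have `I = 0` and are
vetoed regardless of `C`, while charge-neutral correlations (`C = 0`) are
equally vetoed.  Per substrate offset the top *m* = 7 columns with strictly
positive `C_c` are kept — co-crystal structures of kinase–peptide complexes
show at most about seven domain residues contacting one substrate position,
and larger *m* only blurs the matrices toward a family average.  The kept
`C_c` values, normalized to sum 1, are the interaction weights.  No
additional noise threshold is applied before the top-*m* cut (`min_combined`
exposes one); with a few hundred training kinases the weight normalization
already keeps spurious selections harmless, because their conditionals are
close to the training marginal.

### Prediction

For each offset the predicted column is the weight-mixture of the
conditional distributions `P(Y_j | X_i = a)` at the selected SDR columns,
evaluated at the query's residues.  Conditionals are conditional frequencies
(consensus variant) or the Bayes ratio `p(x, y)/p₁(x)` of the
maximum-likelihood joint (profile variant).  A query residue never seen at
an SDR column in training — or a gap — backs off to the training marginal
`p₂(y)` rather than to a uniform distribution, so rare residues degrade
toward the observed substrate composition; offsets with no informative SDR
return the background column.  Mixtures of stochastic vectors are stochastic
by construction; columns are nevertheless renormalized (guard tolerance
1e−9) to absorb floating-point drift.  Predictions are therefore always
convex combinations of stored conditionals, backoff and background — a
tested invariant.

### Evaluation

Matrices are compared by the sum of squared entry-wise differences (SSE).
The classifier accepts a window when its PSSM score is ≥ 0; negatives are
seeded uniform 15-mers.  Their flanks draw uniformly over the 20 amino acids
(no `x`: physical peptides have residues) and their center uniformly over
S/T/Y, because a non-acceptor center would not be a valid phosphosite window
— both choices are config-exposed.  Kinase ranking per site sorts by
descending score with lexicographic tie-breaks, so all outputs are
deterministic.  A train/test helper reserves the top-*n* (default 5) kinases
by pair count as the test set, the ones whose empirical profiles are most
trustworthy.

## Synthetic families

`simulate.PlantedModel.default()` defines the study conditions used
throughout the tests and the acceptance script: K = 200 kinases, n = 30
peptides each, alignment length L = 100 — large enough for stable
mutual-information estimates, small enough for seconds-scale runs.  One
coupling is planted at offset −3 (the canonical basophilic/acidophilic
example position): a column whose residues draw uniformly from the
six-residue pool E/D/K/R/L/F with a deterministic, charge-consistent
substrate map (E→R, D→K, K→E, R→D, L→I, F→V), so both detectors carry
signal; a charge-inconsistent mode maps to neutral residues instead,
silencing the charge detector at unchanged mutual information, which lets
tests separate the two detectors.  Coupling strength γ mixes the conditional
with the flank background (γ = 0: independence; γ = 1: deterministic
coupling).  Flanks follow smoothed human-proteome amino-acid frequencies;
the acceptor draws S/T/Y at 0.60/0.25/0.15.  Non-planted columns are
conserved at level 0.9 over a neutral pool (A/G/N/Q/M/W/C/P).

What the generator does *not* emulate: real kinome phylogeny (kinases are
i.i.d. given the planted columns, with no shared ancestry), real motif
content, multi-column epistasis, and hydroxyl or charged residues at
non-planted domain columns — the neutral pool deliberately excludes them so
that interaction-matrix signal is confined to the planted couplings, whereas
real catalytic domains of course contain serines and glutamates everywhere.
Passing recovery tests therefore show that the estimators find couplings of
the assumed form at realistic sample sizes, not that real kinase specificity
is predicted correctly; performance numbers on these families (e.g. the
~93 % classifier specificity, or mean prediction SSE ≈ 0.38 vs a background
baseline of ≈ 1.32) characterize the pipeline under the planted model only.

## Numerical choices

* Column-stochasticity enforced to 1e−9; mutual information clamps tiny
  negative round-off to 0.
* SDR ranking ties break by ascending column index; consensus argmax ties by
  alphabet order; ranking ties by kinase id — every output path is
  deterministic given inputs and seed, and the full pipeline is
  byte-reproducible (tested).
* Gap aliases `-` → `~` on input; `~` written on output.  Ambiguity codes
  (B, Z, U, O, X, J) map to `x` in substrate windows and are rejected in
  domain alignments, where sequences must be fully specified or gapped.
* Pair de-duplication is off by default (`read_pairs(dedupe=True)` enables
  it); duplicate handling in the original curated corpora is unknown, so the
  reader makes no claim either way.

## Known limitations

* The consensus variant discards within-kinase uncertainty (argmax
  summarization) and is measurably less accurate than the profile variant on
  graded couplings — reproduced as a test invariant.
* Atypical kinases without an alignable catalytic domain are outside the
  prediction path; they can still enter as ordinary empirical profiles.
* The interaction matrix is a coarse, distance-free average; no inter-SDR
  spatial proximity preference is modelled (sequence-adjacent columns are
  not favored, since 3-D neighbors can be sequence-distant).
* With S/T/Y-restricted negatives, any kinase whose *acceptor* column is
  informative hands about a third of random negatives a large positive
  center term, which bounds achievable specificity well below what
  unconstrained-center negatives would show; the synthetic families keep the
  acceptor offset uninformative, so the reported specificity reflects flank
  discrimination.
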