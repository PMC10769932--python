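# Methods

`indriflex` quantifies how flexibly individual indris (*Indri indri*, the
only singing lemur) concatenate phrase types in their long territorial
songs, and how that flexibility covaries within the breeding pair and
differs across sex and social status. This note documents the models, the
parameter choices that matter, the synthetic-data generator, and the
numerical decisions, in the package's own terms.

## Sequence encoding

A *contribution* is the portion of one song emitted by one singer, encoded
as an ordered string over a closed six-symbol alphabet: the single unit
`SU` and descending phrases `DP2`–`DP6` (2–6 adjacent notes of descending
frequency). Any other annotation label (e.g. long notes, `LN`) is removed
before analysis; a contribution left empty by filtering is flagged and
excluded rather than silently dropped. Each singer carries a sex
(female / male / unrecorded), a status (dominant = member of the
reproductive pair / non-dominant = everyone else regardless of age) and a
group. Non-dominants are pooled across sexes into a single category, so the
three analysis categories are dominant female, dominant male, non-dominant.

## Statistic 1 — Jaro similarity of phrase strings

For token sequences `a`, `b`, with `m` matches inside the standard window
`w = ⌊max(|a|,|b|)/2⌋ − 1` and `t` transpositions (half the number of
matched tokens out of order),

    sim(a, b) = (m/|a| + m/|b| + (m − t)/m) / 3,    sim = 0 when m = 0.

The value is stored with the orientation 1 = complete match; *lower* values
mean greater concatenation flexibility. Matching is **token-level** (each
phrase type is one symbol). A character-level mode over the pipe-delimited
text is available for compatibility with generic string tooling, but it
overweights shared label prefixes (`DP3` vs `DP5` share "DP") and is not
the canonical statistic. Plain Jaro is used; the Winkler common-prefix
boost exists behind a flag (weight 0 by default).

All `n(n−1)/2` unordered pairs of contributions (upper triangle of the
pairwise matrix; within-singer pairs pooled across songs) become records of
a dyadic dataset. Each record holds the unordered singer pair (the *dyad*),
the distance type (within one individual / between individuals) and a
nine-level factor crossing distance type with the categories of the two
singers: `WDF, WDM, WND, BDF, BDM, BND, B-DF-DM, B-DF-ND, B-DM-ND`.

### Distance mixed model

The response is `√JD` (square root for residual normality). The fixed
effect is the nine-level factor; the omnibus test is a likelihood-ratio
test (ML fits) against a null with the same random structure and only an
intercept, df = 9 − 1 = 8. The random structure is:

* a random intercept per dyad, and
* by default, a **multiple-membership variance component over
  contributions**: each record loads on both of its contributions.

The second component is this package's own addition. Every contribution
appears in `n − 1` records, so records sharing a contribution are
correlated *across* dyads; a dyad-only structure leaves that sharing
unmodelled, and in matched-generator null simulations its likelihood-ratio
test is grossly anticonservative (empirical type-I error 0.3–0.5 at desk
scale, growing with the number of records per dyad). With the contribution
component the test is close to nominal. A `contribution_re=False` flag
restores the dyad-only model for comparison with the original analysis
style.

Post-hoc all-pairs contrasts use the fitted fixed-effect covariance with
Tukey adjustment through the studentized-range distribution. The fitting
backend (statsmodels `MixedLM`) provides no Kenward–Roger denominator
degrees of freedom; contrasts use a dyad-level residual df as a documented
fallback, and every report names the method actually used. ML fits use a
Powell-first optimizer cascade (the gradient evaluations dominate runtime);
any unconverged or failed attempt falls through to the default optimizer
and the best log-likelihood wins, because an under-converged null fit would
silently inflate the likelihood-ratio statistic.

### SVM classification

To ask whether concatenation style is category-diagnostic, an RBF-kernel
SVM classifies contributions from their Jaro profiles. The feature vector
of contribution *i* is its row of similarities to the training reference
set (kernel-matrix-as-features; a precomputed-kernel mode is the
alternative). Data are split 70/30 stratified; `(C, σ)` are tuned by
10-fold stratified cross-validated accuracy over powers-of-four grids
(`C ∈ 2⁻⁵…2¹⁵`, `σ ∈ 2⁻¹⁵…2³`), then the tuned model is scored on the
held-out 30%. All randomness is seeded; reports carry the seed, the tuned
parameters, per-class recall and the confusion matrix.

## Statistic 2 — normalized diversity

`ND = richness / length`: the number of distinct phrase types divided by
the token count (for `DP2|DP3|DP3|DP5|DP4`: 4/5 = 0.8). ND is order-free —
permuting a contribution leaves it unchanged — so it captures repertoire
use within a contribution, complementary to the order-sensitive Jaro
statistic. With six phrase types richness saturates at 6, so ND ≤ 6/length
for long contributions: a combinatorial ceiling that compresses
between-category differences. The modeled response is `log ND` (natural
log; the base only shifts the scale).

The category comparison is a mixed model with crossed random intercepts for
singer and song (both realized as variance components over a single
population group), tested by ML likelihood ratio with df = 2.

Duet covariation: within each group, per-song NDs of the dominant female
and dominant male are paired over songs in which both sang (songs with
non-dominant participation still count — duets may sit inside choruses) and
correlated by Spearman's rank test, midranks for ties. Groups with fewer
than 3 shared songs are reported untested rather than dropped.

## Statistic 3 — Markov entropy rate

Each singer's pooled contributions are treated as realizations of one
first-order, time-homogeneous Markov chain. Transitions never cross
contribution boundaries. With empirical transition matrix `P` and
stationary distribution `π` (`πP = π`),

    H = − Σ_i π_i Σ_j P_ij log P_ij        (0·log 0 ≡ 0),

in nats by default (base configurable; category comparisons are
base-invariant). `H` is bounded by `log k` for a `k`-state chain, attained
iff `P` is uniform; `H = 0` for deterministic cycles. Higher `H` = less
predictable = more flexible.

Small samples routinely give non-ergodic empirical chains. States observed
only as targets (a contribution's last token has no continuation) are
trimmed iteratively and the remaining sub-chain is row-renormalized; `π` is
then computed on the largest closed communicating class, via the dominant
left eigenvector with a Cesàro-averaged power-iteration fallback (tolerance
1e−12, max 10⁵ iterations — the averaging handles periodic chains). An
ambiguous structure (two equally large closed classes, as in a two-state
identity matrix) raises a diagnostic instead of guessing; per-singer tables
record such singers as NaN with the reason. Optional add-α smoothing
(default off) restores irreducibility over the observed states instead.

The analytic evaluation is canonical. A simulation mode mirrors the
simulation-based procedure of the original tooling: simulate long chains
from the empirical matrix, re-estimate, average the plug-in entropy; it
converges to the analytic value and serves as a cross-check.

Entropy rates are compared across the three categories by Kruskal–Wallis
(df = 2) and between duetting dominants by per-group Spearman correlation,
untested below 3 complete female–male pairs.

## Synthetic corpora

The generator exists so that every downstream stage is testable end to end
with known ground truth. Defaults mirror the field study's scale: 10
groups, one dominant pair plus 2 non-dominants per group, 60 songs per
group (≈600 songs, ≈1500 contributions). The dominant female sings in
every song; the male joins with probability 0.95, each non-dominant with
probability 0.3. Contributions are first-order Markov chains over the
six-token alphabet; per-category transition matrices have rows drawn from a
symmetric Dirichlet whose concentration controls predictability (low →
peaked, stereotyped rows; high → near-uniform). Initial tokens are drawn
from the matrix's stationary distribution to avoid start-up transients.
Lengths are geometric with mean 12 by default (the real length distribution
is unreported; a low-dispersion negative-binomial option exists). The same
configuration and seed always produce a byte-identical corpus.

Duet coupling: with coupling ρ, each song draws a bivariate-normal latent
pair (correlation ρ) for the two dominants; each latent level `z` rescales
that singer's effective Dirichlet concentration for the song,
`c_eff = 0.5·exp(2.5 z)`, and the song's contribution is emitted from a
matrix re-drawn around the category base with that concentration. This
induces rank covariation of the pair's per-song diversities — exactly the
structure the Spearman analysis tests. Limitation: under heavy-tailed
geometric lengths, ND variation is dominated by length noise and the
induced rank signal is heavily diluted; the coupling is clearly visible
with low-dispersion lengths.

What the generator does *not* emulate: timing and overlap of contributions,
acoustic gradation within phrase types, song-context differences
(territorial vs cohesion), or ontogenetic change in non-dominants. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not fidelity of that model to wild indri
songs.

## Validation simulations and problem sizes

The test suite validates the inference pipelines by simulation, at sizes
chosen to keep the default run practical on one CPU:

* **Distance LMM**: corpora of 3 groups × 4 songs, every singer in every
  song, mean length 15 (36 contributions → 630 dyadic records per
  replicate). Matched-generator nulls (all categories share one matrix,
  concentration 3.0) check type-I error; effect corpora give the
  non-dominant category a concentration-0.01 (strongly stereotyped) matrix.
* **Diversity LMM**: 5 groups × 10 songs, negative-binomial lengths
  (dispersion 20); the shifted category draws its matrix from a Dirichlet
  concentrated on a two-symbol repertoire (diversity responds to repertoire
  narrowing; a symmetric low concentration lowers conditional entropy but
  can leave visited-state diversity unchanged).
* 200 seeded replicates per arm; empirical power and type-I error are
  compared against the 0.90 / 0.05 ± 0.04 targets.
* **Structural checks** run at the field scale (1528 strings → a
  1528 × 1528 matrix; ~1.17 M dyadic records are enumerated but not fitted).

## Known limitations

* Denominator df for post-hoc contrasts are large-sample fallbacks, not
  Kenward–Roger; adjusted p-values for small corpora are approximate.
* The entropy rate of a singer whose observed chain has no closed
  communicating class among source states is undefined and reported NaN.
* ND's duration-based variant (dividing by contribution duration rather
  than token count) is not implementable from token strings and is out of
  scope.
* The SVM feature construction (similarity-to-reference-set) is one
  defensible reading of "classification from distance values"; the
  precomputed-kernel alternative is provided but not the default.
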