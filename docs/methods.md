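# Methods

`odorpop` implements, end to end, the population-coding analysis used to
contrast how two stations of the mouse olfactory reward circuit represent
odors during appetitive conditioning: a ventral-pallidum-like population
that encodes *reward contingency* (valence) in a low-dimensional, odor-
generalizing format, and olfactory-tubercle-like populations that encode
*odor identity* in a high-dimensional format. Because the imaging data the
analyses were designed for are not bundled with the package, every stage is
exercised against a synthetic-session generator whose encoding structure is
known exactly; the generator is first-class, tested code, and the recovery
of its ground truth is the package's main form of validation.

## Conditioning paradigms

**Six-odor paradigm.** Six odors (three 2-ketones: hexanone, heptanone,
octanone; three terpenes: terpinene, pinene, limonene) are presented for
2 s each, 30 blocks per session, each block containing every odor once in
random order; inter-trial intervals are uniform on 12–18 s. Each
contingency group — sucrose (S), nothing (X), airpuff (P) — contains one
ketone and one terpene, giving the role labels S_K, S_T, X_K, X_T, P_K,
P_T. The US is delivered 0.1–0.3 s after odor offset. On days 1–3 the
original contingency map applies (heptanone/pinene → sucrose); on days 4–6
the map is switched (octanone/terpinene → sucrose, heptanone/limonene →
nothing). A block order in which an odor would repeat more than twice in a
row across a block boundary is redrawn.

**Lick/no-lick paradigm.** Reward probability (0 / 50 / 100 % sucrose,
delivered 1.1–1.3 s after odor offset) is crossed with lick-spout
availability: for the L odors the spout stays in place; for the N odors it
is retracted 0.2 s before odor onset and returns 0.1 s before the earliest
possible reward time. This decouples the opportunity to lick from reward
contingency, which is what the disentangling regressions exploit. The
source protocol text assigns probabilities to chemicals in a way that
contradicts the crossed design (two 50% odors with the spout present, two
100% odors without); we keep the retracted trio (terpinene, octanone,
limonene) and assign probabilities so that each probability occurs exactly
once per spout state.

## Synthetic sessions

Per neuron, fluorescence is

    F(t) = F0 · (1 + drift(t) + r(t)) + ε(t),  truncated at 0,

with `drift` an Ornstein–Uhlenbeck process (default timescale 100 s,
stationary SD 5 % of F0 — slow enough to exercise the moving-window
baseline stage, fast enough to matter), `ε` white Gaussian noise (SD 5 % of
F0), and `r` the event drive convolved with a peak-normalized difference of
exponentials (rise 0.2 s, decay 1.7 s — kinetics in the range reported for
the slow jGCaMP7s indicator). Sampling is 5 Hz throughout.

Encoding classes and their drives:

- `valence_pos` / `valence_neg` — a shared contingency template: the drive
  scales with the *current* sucrose contingency of the presented odor
  (reward probability in the lick/no-lick paradigm), with a per-odor
  multiplicative jitter (SD 0.1) so the two same-contingency odors evoke
  *near*-equal responses. This makes the valence signal low-rank across
  odors by construction.
- `identity` — tuning weights drawn independently per chemical
  (exponential, normalized to unit preferred-odor weight): full-rank
  population tuning.
- `lick` — impulses at lick-bout onsets; `us_sucrose` — impulses at sucrose
  delivery; `salience` — equal drive for all odors plus the airpuff;
  `silent` — no drive.

Response amplitudes are lognormal (median 0.8 ΔF/F, σ=0.4), and every
odor/US response is additionally scaled by a per-trial gain
`max(0, 1 + 0.35·N(0,1))`. This trial-to-trial variability is essential:
without it the per-odor jitter alone would make even same-contingency odor
pairs perfectly discriminable at 30 trials, which real calcium data are
not.

Licking is an inhomogeneous Poisson process: 0.2 Hz baseline; an
anticipatory component that ramps over the final odor second and persists
through the delay, with peak 7 Hz scaled by a learning factor (0.15, 0.6,
0.95 on days 1–3, restarting after the contingency switch) and by reward
probability; and a 7 Hz consummatory bout for 2.5 s after sucrose. The
capacitive sensor only registers licks while the spout is present; face
features (tongue-tip and mouth-corner tracking confidences, upper/lower lip
coordinates) are noisy deterministic functions of the true lick state, so
licking remains decodable on spout-retracted trials. Lick-bout statistics
are not constrained by any published value; the defaults were chosen for a
qualitatively realistic raster and are configurable.

What the generator does **not** emulate: correlated (shared) noise across
neurons, non-Poisson lick-bout microstructure, sensory-motor artifacts,
slow representational drift across days beyond the programmed class
changes, or neuropil contamination. Passing recovery tests therefore shows
the analyses are correct and well-calibrated under the assumed encoding
model — not that they would be unconfounded on arbitrary real data.

## ΔF/F baseline

The baseline of each neuron is the mean of the *baseline component* of a
two-component Gaussian mixture fit to the fluorescence inside a moving
window of 2,500 frames (500 s), evaluated at window centers placed every
500 frames (windows clipped at the recording edges) and linearly
interpolated between centers. The mixture statistic is the lowest-mean
component **holding at least 25 % of the window samples**: for excited
neurons the upper component absorbs transient-contaminated samples, while
for inhibited neurons the activity *dips* form a sparse low mode that must
not be mistaken for baseline. Near-constant windows fall back to the
window mean. The fit is a vectorized two-component 1-D EM (percentile
initialization, ≤50 iterations, tolerance 1e-3 on the means, every 4th
frame of the window) that is checked against
`sklearn.mixture.GaussianMixture` in the test suite; a 20th-percentile
estimator is available as a robustness fallback. ΔF/F is
`(F − baseline)/baseline`, with a hard error if any baseline is
non-positive.

## Frame conventions

Frames are 0-based; frame `i` covers `[i/fs, (i+1)/fs)`. A window contains
every frame whose *start* falls inside it. At 5 Hz: odor period = relative
frames 0–9, last odor second = 5–9, pre-odor 2 s = −10…−1, first post-odor
second = 10–14, and the lick/no-lick anticipatory window (last 0.5 s of
odor + first 0.5 s of delay) = frames 8–12. One utility module owns these
definitions; behavior and decoding consume the same frames.

## Statistics

**Responsiveness.** Each of the 10 odor frames is compared against the
pooled pre-odor distribution of the same odor's trials (10 frames ×
trials) with a two-sided Wilcoxon rank-sum test; the 10 p-values form one
Holm–Bonferroni family per (neuron, odor) at FWER 0.05. A neuron is
responsive to an odor when ≥4 corrected-significant frames share one sign;
mixed-sign families are labeled by the majority sign and flagged. The
rank-sum is the normal approximation with continuity correction, computed
vectorized across neurons; slices containing ties fall back to scipy's
implementation (which the vectorized path reproduces exactly on tie-free
data). The US-responsiveness variant tests the 2 s after sucrose delivery
against the same pre-odor pool; the cross-day transition fraction counts
tracked neurons that are US-responsive on day 1 and S-odor responsive with
the same sign on day 3.

**ΔΔF/F.** Trial-averaged mean over the last odor second minus the
trial-averaged pre-odor mean, per neuron per odor; the scaled variant
divides by the neuron's largest positive ΔΔF/F (undefined, and flagged,
when no positive value exists). Identity-line similarity for an odor pair
(i, j) is R² = 1 − Σ(ΔΔ_j − ΔΔ_i)² / Σ(ΔΔ_j − mean)² — the fit of the
null model "every neuron responds identically to both odors"; it is
negative when that model is worse than the mean.

**Single-neuron decoding.** The per-trial feature is the last-odor-second
mean, Z-scored over the pooled trials of the two odors. A logistic model
on a 1-D feature produces scores monotone in the feature, so its auROC
equals the feature's rank (Mann–Whitney, midrank ties) auROC up to
orientation; the fitted coefficient's sign fixes the orientation, and the
rank computation is the implementation. Permutation nulls shuffle labels
(default 10,000; <100 refused) and use add-one p-values
`(1 + #{null ≥ obs})/(1 + n)`. Quadrant categorization thresholds the
{S_K vs X_K} (intervalence) and {S_K vs S_T} (intravalence) auROCs at
θ = 0.75: valence = intervalence only above θ; identity = both;
identity_S_only = intravalence only; uninformative = neither. Note the
valence *count* is not monotone in θ — raising θ can reassign
identity-quadrant neurons into valence — but the intervalence-above-θ count
is.

**Population decoding.** Features are per-trial window means from
simultaneously recorded neurons; Z-scoring uses training-fold statistics
only (a scaler inside the CV pipeline). Classifiers are logistic
regression or RBF-SVM (C=1, scale gamma), stratified 5-fold CV. The 15×15
generalization matrix trains on the full data of one pair and tests on all
trials of every other pair; labels transfer by sucrose contingency (the
higher-contingency class maps to the higher-contingency class). Pairs with
no contingency difference make the mapping orientation-ambiguous: the
maximum over both mappings is reported and the entry flagged. "Generalized
valence decoding" is the off-diagonal mean over the block of pairs with
exactly one sucrose-predicting odor. PC-restricted decoding subsamples 15
neurons, fits PCA on the full 6-odor design (so the leading components are
the population's dominant response axes, not automatically the pair's
discriminative axis), and trains on the top-m components.

**Geometry.** Distance trajectories subtract each trial's pre-odor mean,
average across trials, and report per-frame Euclidean distances for all
odor pairs normalized by the per-animal maximum over pairs and frames.
Pooled clustering Z-scores each neuron's concatenated 6-odor trial-averaged
trace, averages three bins per odor (first/last odor second, first
post-odor second) into an 18-vector, and cuts a Ward tree (clusters
relabeled by descending mean S-odor response for stable output). The
participation ratio PR = (Σλ)²/Σλ² of the neuron-covariance eigenvalues is
computed on the full-session ΔF/F series by default (epoch-restricted
optional) and bootstrapped by drawing k = 15 neurons 1,000 times without
replacement.

**Behavior.** Anticipatory licking per trial is the lick rate in frames
8–12 (shared utility). The sucrose-cue lick fraction is S-odor licks over
all odor-period licks; odor-lick series are smoothed with a 10-trial
moving average whose edge windows shrink (preserving the mean). The face
lick detector is a logistic model on three features (tongue confidence,
mouth-corner confidence, upper–lower lip distance), trained on
spout-present frames against the sensor and applied to spout-absent
frames. Distributed-lag models regress a target series on lags −L…+L
(default ±10 frames = ±2 s) of the predictors, fit by OLS on the first 80 %
of the session and scored by out-of-sample R² on the final 20 %.
Variance partitioning fits, per neuron, trial-level responses to (1)
reward contingency, (2) anticipatory lick rate, (3) both + interaction;
ΔR²_-valence = R²_full − R²_lick-only and ΔR²_-licking = R²_full −
R²_contingency-only (non-negative in-sample). Accuracy-versus-behavior
fits pairwise decoding accuracies to Δlick (range-normalized by the
per-animal maximum), ΔP(sucrose), and both + interaction; because the
combined model nests both single-variable models, its in-sample R² is
never smaller.

## Numerical and design choices

- Mixture size 2 and the lowest-qualifying-mean statistic are exposed as
  configuration (the protocol source specifies neither); `method="sklearn"`
  supports other component counts.
- Per-(neuron, odor) Holm families (10 frames); larger family definitions
  can be composed from the returned p-values.
- Pre-odor pools are per-odor (that odor's trials only).
- Fold seeds are fixed and every stochastic step takes a seed; pipeline
  runs are byte-reproducible and the manifest records the config hash and
  derived seeds.
- Degenerate inputs: zero-variance decoding features → auROC 0.5, flagged;
  zero-variance cluster features → neuron dropped, logged; truncated trial
  windows → dropped with a warning count; all-tied rank-sum data → p = 1
  with a warning.
- Problem sizes in the test and acceptance suites (e.g. 130/250-neuron
  cohorts, 30 trials per odor, 20 paired seeds for the dimensionality
  contrast, 1,000-shuffle nulls in places where 10,000 is the analysis
  default) are chosen to keep a full desk-scale run in minutes while
  leaving the Monte-Carlo error well inside the asserted margins.

## Known limitations

- The acceptance-scale contrasts are *qualitative* reproductions of the
  published effect directions on synthetic cohorts; the published
  magnitudes come from imaging datasets that are not redistributable and
  are not reproduced here.
- The GMM baseline underestimates true baseline slightly on unimodal data
  (the lower component of a split Gaussian); the bias is ~1 noise SD and
  cancels in the trial-relative (ΔΔ) statistics.
- Generalization-matrix entries for identity-coding populations are
  high-variance (trained hyperplanes score near-binary transfer accuracy on
  single sessions); cross-animal averaging, as in the pipeline runner, is
  the intended use.
- The lick/no-lick generator couples anticipatory licking to reward
  probability, so contingency and vigor regressors are correlated at the
  odor level; the variance partitioning relies on trial-level lick
  variability, exactly as the analysis does on real data.
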