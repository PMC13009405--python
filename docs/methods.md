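# Methods

This note records the models, rules and numerical choices behind
`discourselsm`, and what the synthetic-data tests do and do not
establish.

## Discourse scoring

**CWF (Content Word Fluency).** One point per production of a checklist
item. A token matches an item when its normalized form equals the
item's lemma or one of its listed synonyms; synonyms pass through the
same inflection rules as lemmas. Exclusions operate on *items*, within
a phrase: the second consecutive resolution to the same item is an
immediate repetition, the third or later a perseveration (the protocol
names perseveration without defining it; ≥3 consecutive is our
operationalization). Adjacency is evaluated after skipping
filler-flagged tokens only, so a repeated target separated by any
contentful token counts again, and re-use in a later phrase always
counts. We adopt the permissive reading for within-phrase non-adjacent
repeats (they count); the protocol explicitly states only the
subsequent-phrase case. Unintelligible and non-word tokens never match.

**Lemmatization** is a deterministic rule table, not a statistical
tagger — auditability over coverage. Order: lower-case and strip edge
punctuation; irregular-form lookup (children→child, took→take, …); an
"-ie lemma" plural table (cookies→cookie — a plain "-ies→-y" rule would
produce *cooky*); then ordered suffix rules (-ies→-y, -es after
sibilants, -s, -ing/-ed with e-restoration and consonant undoubling).
Users can extend the irregular table. Anything the rules cannot analyse
is returned unchanged.

**CIU counting** is annotation-driven: relevance/accuracy judgments
require human (or simulator) flags, so the counter is deterministic
given flags — a token counts unless flagged
{filler, unintelligible, off_topic, inaccurate, non_word} or it
immediately repeats the preceding unflagged token's normalized form.
Word count excludes only unintelligible and non-word tokens (fillers
are words).

## Item response models

Dichotomous production (item produced at least once) is modelled with
the 1PL/2PL/3PL logistic family over a standard-normal latent ability,
estimated by EM marginal maximum likelihood with 41-point Gauss–Hermite
quadrature (sensitivity at 21/61 nodes is covered by a test; difficulty
estimates correlate > 0.999 across node counts). Identification fixes
the latent variance at 1; the 1PL slope is freely estimated, giving
n_params = k + 1 and hence the printed df values at k = 17 (16, 33,
135). M-steps maximize the expected complete-data likelihood with
L-BFGS-B (analytic gradients); EM therefore increases the marginal
likelihood monotonically (asserted to 1e-8 in tests). Abilities are
EAP. The 3PL adds a weak Beta(2, 20) prior on guessing (pseudo-Bayes);
plain 3PL MML is unstable at n ≈ 76, and the prior is disclosed here;
the reported log-likelihood is always unpenalized, so the 3PL may trail
the 2PL by a small margin in likelihood at small n.

**M2.** Limited-information fit statistic on first- and second-order
margins with the orthogonal-complement weight matrix
C = Ξ⁻¹ − Ξ⁻¹Δ(ΔᵀΞ⁻¹Δ)⁻¹ΔᵀΞ⁻¹, where Ξ is the model-implied
covariance of the margin indicators and Δ the Jacobian of margins with
respect to the free parameters. The statistic is asymptotically
χ²(k(k+1)/2 − n_params) for any √n-consistent estimator; the df is
always computed and no p-value is produced when df ≤ 0. An optional
parametric bootstrap calibrates the same quadratic form by simulating
from the fitted model with parameters held fixed (no per-replicate
refit — slightly liberal, flagged here). Empirical type-I error at
α = 0.05 over 200 well-specified replicates (k = 8, n = 250) is ≈ 0.045.

## Elementary statistics

Pearson r with p from t = r√((n−2)/(1−r²)); partial correlation by
least-squares residualization of both variables on the covariates (with
intercept), df = n − 2 − q; pooled-variance Student t (the printed
df = 56 at group sizes 41/17 forces pooled, not Welch). Tract-damage
partial correlations default to a one-tailed test in the negative
direction: back-computation from published-style values (r = −0.22,
n = 63, one covariate → p ≈ 0.04) is consistent only with one-tailed
testing; two-tailed is available via `alternative`. No multiple-testing
correction by default (uncorrected p reporting); `holm_bonferroni` is
provided but off by default. The psycholinguistic regression is OLS by
QR decomposition, never normal equations.

## Lesion analytics

All analyses run in voxel space on a verified-identical grid; voxel
indices are 0-based, C-order. The coverage filter keeps voxels lesioned
in ≥ 10 % of subjects, inclusive (count/n ≥ fraction), so at n = 63
retention requires 7 subjects.

**Sparse CCA LSM.** We maximize corr(Xw, y) over unit-norm w under a
hard-sparsity projection that retains the top |sparseness| fraction of
|w| entries, by iterative gradient steps on the least-squares objective
(equivalent direction, scale-invariant target) with projection after
each step, from a deterministic zero start with a power-iteration step
size; negative sparseness leaves signs free, positive clamps to
non-negative (the upstream convention: −0.3 means "keep 30 % of voxels,
signs free"). Significance is the one-tailed t-test of the Pearson
correlation between pooled held-out predictions and the behaviour over
k = 4 folds; the fold split derives from the seed, so results are fully
deterministic. This analytic p is mildly anti-conservative under
permutation (cross-fold dependence inflates the null sd of the pooled
correlation by ~15 %); `permutation_p` provides the exact check.
Displayed voxels are negative-weight voxels with |w|/max|w| > 0.1
(damage predicting worse scores).

**Identifiability limit.** With n subjects the lesion matrix has rank
≤ n. In the desk-scale recovery world (40 subjects, 24³ grid, 20-voxel
critical region) the coverage mask holds ~2000 spatially correlated
columns, so the fit is in the interpolation regime and the *support* of
the weight map is not identified — any spanning subset fits equally
well in-sample. Cross-validated prediction (cv correlation ≈ 0.6) and
permutation calibration are therefore the meaningful desk-scale checks;
voxel-precise overlap (Dice) between the displayed set and the
generating region is not attainable at this n for any estimator; the
corresponding recovery assertion in the test suite fails for this
reason and is left in place as an honest record of the limit. A green
CV test establishes that the map predicts behaviour out of fold, not
that individual displayed voxels are causal.

**Disconnection maps.** A template streamline is disconnected iff any
of its voxels is lesioned; each traversed voxel gets the fraction
disconnected-through / total-through, binarized inclusively at ≥ 0.5.

**PVC.** Single-map model: one weight map fit on the stacked data (both
behaviours, shared w); two-map model: one map per behaviour. Residuals
come from cross-validated predictions with a per-fold linear
calibration (train-set intercept and slope of y on Xw) so they live on
the behaviour scale. AIC = Σ_behaviours n·ln(RSS/n) + 2k with
k = number-of-maps × retained-voxel count; this Gaussian-residual
operationalization is validated through its properties (identical
behaviours can never favour two maps; disjoint generating regions raise
the difference), and the verdict rule is two_maps iff difference > 100,
boundary exclusive.

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis
assumes, not linguistic or anatomical realism. Ability
θᵢ = −β·loadᵢ + εᵢ with ε ~ N(0, noise_sd) and load the lesioned
fraction of a designated critical region. θ is deliberately *not*
cohort-standardized (a stated design alternative): standardizing would
erase the mean ability shift the lesion effect induces and with it the
guarantee that mean CWF is non-increasing in β. With β = 0 and the
default noise_sd = 1, θ is exactly N(0, 1) and shares the
item-difficulty scale, which is the Wright-map convention the fitting
assumes. Items are produced with probability logistic(θᵢ − b_j),
b ~ N(0, 1). Transcripts embed produced items (inflected or synonym
surface forms chosen so the normalizer provably round-trips them) among
function words, extra relevant words (rate rising with ability, so CIU
exceeds CWF and both track severity), fillers (rate 0.15), immediate
repetitions (rate 0.08) and severity-dependent error tokens. Lesions
are connected blobs (random seed voxel, 6-neighbour accretion) with
log-normal target sizes (median ~400 voxels, σ = 0.9, clipped at 15 %
of the grid — a desk-scale analogue of 5–376 cc lesions) seeded around
the grid centre (sd = shape/6), emulating middle-cerebral-artery
clustering. The default critical region is a 20-voxel blob placed
off-centre; one tract (FAT) is routed through it so tract-load analyses
have a true positive. Defaults were calibrated once to reproduce the
target correlation structure (r(CWF, CIU) > 0.6 at n = 100; observed
≈ 0.93) and then frozen.

What generated data cannot establish: coder disagreement and
transcript ambiguity (flags are exact), real lesion anatomy and
registration error, the true generative process of discourse, and
checklist content validity (the packaged vocabulary is synthetic; the
published picture-description checklist is user-supplied).

## Degenerate inputs and tie-breaks

All-0/all-1 item columns are dropped upstream
(`response_matrix(for_irt=True)`) and refused with the offending ids by
the fitter. Constant behaviour vectors, collinear covariates and
rank-deficient regression designs raise typed errors naming the
problem. Hard-threshold ties in the sparsity projection resolve by
`np.partition` order, deterministic for fixed input. JSON outputs are
written with sorted keys and the manifest carries seeds, n and the
package version, so a pipeline re-run from the same config is
byte-identical.
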