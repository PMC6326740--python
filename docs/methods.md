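# Methods

## The analysis

`netbgc` implements a resting-state functional-connectivity analysis that
asks whether a functional network's *between-network global connectivity*
(BGC) covaries with depression-symptom severity across subjects.

For subject-level inputs the pipeline expects parcellated BOLD time series
(one mean series per cortical region), six rigid-body motion estimates per
frame, and nuisance signals (ventricle, white matter, global). Per subject:

1. **Framewise displacement (FD).** For each frame, the L2 norm of the six
   frame-to-frame motion deltas, with rotations converted to arc length on
   a 50 mm sphere (the conventional head radius). The first frame is 0 by
   convention. The Euclidean norm is used deliberately; it differs from the
   more common L1 ("Power") FD.
2. **FD low-pass.** The FD trace (not the BOLD data) is filtered with an
   order-2 Butterworth applied forward and backward (zero phase, unit DC
   gain), cutoff 0.3 Hz, to suppress respiration-band oscillations. The
   filter order is a package choice; only the cutoff is part of the
   analysis definition. Cutoffs at or above Nyquist raise an error rather
   than silently passing the trace through.
3. **Scrubbing.** Frames whose filtered FD exceeds 0.3 mm are censored
   together with 1 frame before and 2 after, windows clipped at the series
   boundaries. The threshold is strict (`fd > threshold`).
4. **Nuisance regression.** Design: intercept, 6 motion estimates plus
   their first differences (the "12 motion parameters"), ventricle and
   white-matter signals plus their first differences, and the global
   signal (17 regressors + intercept). "12 motion parameters" is read as
   estimates + derivatives, the standard convention. The global signal's
   derivative is *not* included. First differences are backward
   differences computed on the full series before censoring (so gaps do
   not corrupt derivatives); the least-squares fit and the residuals are
   computed on retained frames only (censor-then-regress). The order is a
   documented package decision — fitting before censoring is equally
   defensible — and is logged via the provenance block so users can audit
   it.
5. **FC and BGC.** Pearson correlation between every region pair over the
   retained frames gives the FC matrix W. For region i in network C,

       BGC_i = Σ_{j∉C} W_ij / (N_total − N_C),

   and a network's BGC is the unweighted mean of its regions' values.
   Weights are averaged as raw r (no Fisher transform): the statistic is
   defined on the FC weights directly, and after global-signal regression
   the values sit near zero where atanh is essentially the identity.

On the phenotype side, the 20 CES-D items (0–3 each) are scored with four
reverse items (default 4, 8, 12, 16, 1-based; configurable — the scale
itself fixes the reverse-worded items but data files vary in coding), total
0–60, plus three factor subscores (somatic, negative affect, anhedonia).
The item→factor map is a configurable input with a documented default
(anhedonia = the four reverse items; the remaining items split between
somatic and negative-affect sets following the three-factor literature);
it is a default, not ground truth, and studies with a preferred assignment
should supply their own. Handedness answers, if present, yield a laterality
quotient LQ = 100·(score sum)/22 ∈ [−100, 100].

Because community CES-D totals are right-skewed, totals (and factor scores,
for diagnostics) are Box-Cox transformed, y → (y^λ−1)/λ (log at λ = 0),
with shift +1 since the minimum score is 0. λ is chosen by profile
log-likelihood on the grid [−5, 5] step 0.01. Normality is assessed before
and after with a one-sample KS test on standardized values against N(0,1)
(asymptotic p, no Lilliefors correction — the common default of the era,
anti-conservative because parameters are estimated from the sample; the
p-values are reported as diagnostics, and the transform is applied
unconditionally).

Association tables correlate each network's (or region's) per-subject
summary with the transformed total. p-values use t = r·√((n−2)/(1−r²)) with
n−2 df (Spearman via average ranks then the same t approximation — chosen
over exact permutation for consistency with the n≈100 regime the package
targets). Benjamini–Hochberg FDR is applied within each table: the networks
form one family, the regions another, never pooled. Control analyses:

* **Spearman robustness** on raw totals (rank-invariant to the transform).
* **Age/gender residualization**: the transformed total is replaced by its
  least-squares residual on intercept + age + a binary gender indicator.
* **Connection-exclusion BGC**: for a set of focus networks (default: the
  a-priori network plus the two companions with the most negative primary
  correlations; configurable), each focus network's BGC is recomputed with
  the other focus networks' regions removed from its target set.
* **Between-network mean FC** between the a-priori network and each other
  focus network, correlated with symptoms.
* **Factor partial correlations**: rank-based partial correlation of each
  factor with focus-network BGC, holding the other two factors fixed
  (t-based p with n−2−k df). Rank-based is the default because the factor
  scores are skewed sums; `stats.partial_rank_correlation` documents the
  construction.
* **Within- vs between-network comparison**: within-network mean FC is
  correlated with symptoms and compared to the BGC correlation with the
  independent-samples Fisher z formula. The two correlations share
  subjects; the dependent-samples tests need the inter-measure correlation,
  which published reports rarely include, so the package deliberately uses
  the independent form and labels it as such.
* **Alternate partition rerun**: the full network-level table recomputed
  under a second region→network table, exercising sensitivity to the
  partition choice.

Subjects are never excluded for motion beyond frame censoring, but a
minimum-retained-frames floor (default 200) drops subjects whose FC would
be estimated from too few frames; drops are warned about and recorded in
the scrubbing summary.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes: by
default 96 subjects, 360 regions in 12 networks, 1,070 frames at
TR = 0.785 s. Per subject j with standardized latent severity s_j:

* **Covariance.** Unit-diagonal block correlation matrix: within-network
  off-diagonal w_k (default 0.3), between-network b (default 0.05), and
  the effect network's between-network rows set to the subject's realized
  coupling b_j = b + β·s_j + σ_b·ε_j (σ_b default 0.01). Eigenvalues are
  clipped at 1e−6 and the matrix rescaled to unit diagonal if needed; the
  repair errors out if any entry moves by more than 0.05, so infeasible
  targets fail loudly instead of silently distorting the design.
* **Frames** are i.i.d. multivariate normal (optional AR(1) flag). The
  analysis operates on correlations, which are unbiased under temporal
  autocorrelation in expectation, and i.i.d. frames keep the oracle
  calculations exact.
* **Global component.** A common unit-variance signal scaled by 0.3 is
  added to every region and mixed (0.7 g + 0.5 noise) into the ventricle
  and white-matter signals; the "global" nuisance series is the mean over
  regions of the final data. This gives global-signal regression real work
  to do.
* **Motion** is a low-amplitude random-walk drift (step SD 0.001 mm;
  rotations scaled to equivalent arc length) plus isolated translation
  steps at rate 0.01/frame with amplitude 1.2–2.0 mm, large enough that FD
  exceeds the 0.3 mm threshold even after the 0.3 Hz low-pass. The
  designed spike frames are returned for verification.
* **CES-D items** follow a graded-threshold model: propensity
  0.9·s_j + N(0,1), cut at (−0.35, 0.9, 2.0) into levels 0–3; reverse
  items store the flipped response. The cutpoints were chosen so that the
  expected total at s = 0 is ≈ 17 with SD ≈ 9 (matching published
  community samples), the floor (s = −3) scores near 0 and the ceiling
  (s = +3) in the upper third of 0–60.
* **Demographics**: balanced binary gender, age uniform on 18–35,
  handedness answers drawn mostly right-preferent (population LQ ≈ 75).

All outputs derive from one integer seed through spawned `SeedSequence`
streams: a configuration determines every array bit-for-bit.

**Planted effect size.** The default slope β = −0.0043 was calibrated once,
by running the full pipeline on 3,000-subject cohorts under the scaled-down
geometry, so that the population correlation between effect-network BGC and
the transformed CES-D total is ≈ −0.25 — the effect size the analysis is
designed to detect at n ≈ 100. The observed correlation reflects β through
three attenuation stages (coupling noise σ_b, FC estimation noise at 600
frames, and the item-sampling noise between s and the scored total), so the
slope is much smaller than the target correlation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic autocorrelation and low-frequency
drifts, spatially structured (non-block) covariance, heavy-tailed motion,
respiratory pseudo-motion in the realistic frequency band, distance-
dependent artifacts, site/scanner effects, and any non-Gaussian marginal
structure of BOLD. Tests on this generator validate the *estimators and
their calibration*, not the neuroscience.

**Scaled-down test geometry.** Tests and the acceptance studies use 4
networks × 15 regions and 600 frames — small enough that the full suite
runs in minutes while exercising every code path, and large enough that
block means and BGC estimates are stable. Calibration studies that need
thousands of cohorts (type-I error, monotonicity) use
`synthetic.quick_bgc_cohort`, which draws identical couplings and item
responses but computes FC directly on the clean block samples, skipping
the motion/nuisance path; end-to-end claims always go through the full
pipeline.

## Numerical choices and degenerate inputs

* FC requires ≥ 3 retained frames and errors on zero-variance regions,
  naming them.
* Rank-deficient nuisance designs are rejected with the offending columns
  identified via pivoted QR; regression requires ≥ (regressors + 2)
  retained frames.
* `bgc_excluding` with an empty exclusion set shares its kernel with
  `bgc_profile`, so the two agree bitwise; excluding all possible targets
  errors.
* BH adjustment is the standard step-up with capping at 1, order-
  preserving under input permutation.
* Report tables serialize with a fixed `%.10g` float format and no
  timestamps, so repeated runs are byte-identical.
* Partitions require ≥ 2 networks at construction; every matrix operation
  validates region order against the partition, which is the single source
  of truth.

## Known limitations

* The censor-then-regress order and the exclusion of the global-signal
  derivative are conventions, not uniquely correct choices; both are
  configurable only by editing the design construction.
* The KS diagnostic is anti-conservative (see above).
* The independent-samples Fisher z comparison understates the dependency
  between two correlations measured on the same subjects.
* The default CES-D factor map is a literature-informed default; factor
  results should be interpreted against the map actually supplied.
* The generator's i.i.d. frames make effective sample sizes optimistic
  relative to autocorrelated BOLD; planted-effect recovery tolerances
  would widen on real data.
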