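# Methods

## Signal model and the single-shell free-water fit

A voxel's diffusion-weighted signal is modeled as a two-compartment
(bi-tensor) mixture: an anisotropic tissue tensor $D_t$ and an isotropic
free-water compartment with fixed diffusivity
$d_w = 3.0\times10^{-3}$ mm²/s (the diffusivity of water at body
temperature; the shared constant between the simulator and the fit):

$$S_i = S_0\left[(1-f)\,e^{-b_i \mathbf g_i^\top D_t \mathbf g_i}
       + f\,e^{-b_i d_w}\right].$$

$S_0$ is taken as known from the mean b0 signal. Tissue eigenvalues are
constrained to $[0.1, 2.5]\times10^{-3}$ mm²/s.

**Variable projection.** For a fixed candidate $f$, the corrected
attenuations $A_t = (A - f e_w)/(1-f)$ make the tissue tensor a closed-form
weighted-least-squares problem in the log domain (weights: squared observed
attenuations, which are constant across candidates so one normal-matrix
inverse serves the whole search). The fit therefore reduces to a global 1-D
search over $f$: a coarse grid (step 0.01 over $[0, 0.99]$ plus an explicit
pure-water candidate $f=1$) followed by local refinement to a resolution of
$2.5\times10^{-4}$, selecting on the signal-domain residual with
eigenvalue-clamped tensors. This replaces a per-voxel nonlinear optimizer:
it is globally optimal in $f$, has no convergence failures, and vectorizes
over all mask voxels. A per-voxel NLLS fit is retained in the test suite as
an independent oracle.

**The degeneracy, and the tissue-MD prior.** With a single shell the
likelihood is nearly flat along the trade-off between $f$ and tissue mean
diffusivity: raising $f$ while lowering MD$_t$ by roughly
$0.9\times10^{-3}\,(1-f)^{-1}$ mm²/s per unit of $f$ leaves the mean
attenuation almost unchanged. A raw maximum-likelihood fit at SNR 30
therefore wanders along this valley (biases in $f$ up to +0.4 in our
phantoms). The fit resolves this as a MAP criterion: the selection objective
is the residual sum of squares plus
$\hat\sigma^2_v\,(\mathrm{MD}_t - \mu)^2/\tau^2$, a Gaussian prior on
tissue MD with mean $\mu = 0.7\times10^{-3}$ mm²/s (the canonical healthy
white-matter mean diffusivity after free-water removal) and width
$\tau = 0.1\times10^{-3}$ mm²/s (a realistic population spread; halving it
changes phantom bias/RMSE by less than 0.001). The prior is scaled by the
per-voxel noise variance $\hat\sigma^2_v$ estimated from the best
unpenalized fit, so it vanishes exactly on noiseless data (recovery of $f$
and FA$_\mathrm{T}$ to the grid resolution) and grows with noise precisely
where the likelihood stops being informative. `md_prior_sd=None` exposes the
raw maximum-likelihood fit.

**Spatial regularization.** One smoothing pass on the $f$ map
($f \leftarrow (1-w)f + w\cdot$ 6-neighborhood mean within the mask,
default $w=0.1$) stands in for the gradient-flow regularizer of the original
free-water literature, whose parameters are not published; tensors are refit
at the smoothed $f$. `regularization_weight=0` gives the raw voxelwise fit —
the mode used by all parameter-recovery tests and the acceptance phantom,
whose interleaved strata have deliberately no spatial structure (smoothing
across strata would mix ground truths and test the smoother, not the
inversion).

**Degenerate voxels.** $f \ge 0.99$ (pure CSF) flags the tissue tensor as
undefined (FA$_\mathrm{T}$ = NaN). Negative eigenvalues in the plain DTI fit
are clamped to zero and flagged; non-positive signals exclude a voxel from
fitting and are tallied.

**Known bias at the water line.** At $b\,d_w = 3$ the pure-water signal sits
only ~2.5σ above the Rician floor at SNR 50, which biases single-tensor MD
on CSF voxels low by ~8% there; 5% agreement with $d_w$ is reached from
SNR ≈ 100. This is a property of magnitude noise, not of the estimator.

## Motion quality control

Per-volume motion is summarized relative to the b0 frame: for every brain
voxel with world coordinate $x$, the displacement under the volume's affine
$T$ is $\lVert Tx - x\rVert$, and the volume's score is the root mean square
over all intracerebral voxels (a stride option subsamples for speed but
defaults to every voxel). Both exclusion thresholds are strict inequalities,
read literally from their "> 2 mm" / "more than 25%" phrasing: a volume is
flagged iff RMS > 2 mm, a subject excluded iff the flagged fraction > 0.25.
The subject-level mean RMS averages diffusion-weighted volumes only (the b0
is the reference and contributes zero by construction). Flagged-but-retained
volumes stay in the tensor fit (participant-level exclusion only); this is
the documented default. Directions are rotated by the polar-decomposition
rotation of each volume's upper-left 3×3 — eddy-style corrections contain
scale and shear which must not act on unit directions — and a reflection
(negative determinant) is an error.

## Group statistics

The group model is a linear model with intercept, diagnosis, sex, their
interaction, and covariates (age in months; scanner as a two-level
categorical), under sum-to-zero coding. With two-level factors every effect
is a single column, so the Type-III partial F equals the squared t of that
coefficient in the full model; this closed form is computed from one shared
design matrix for arbitrarily many outcome columns at once, which makes the
null-calibration simulations (48 outcomes × 1000 replicates) run in seconds.
Residual df is $N - p$ with $p$ the column count — 6 for the standard model,
so 172 diffusion-passing subjects give F(1, 166) and the 187-subject
demographic ANOVA (no covariates, $p=4$) gives F(1, 183). Type III with
sum-to-zero contrasts is the convention that keeps main effects
interpretable under an interaction; the statsmodels Type-III ANOVA serves as
the cross-check oracle in the tests.

BH-FDR is the step-up adjustment $q_{(i)} = \min_{j\ge i} m p_{(j)}/j$
capped at 1, applied within declared families: across ROIs per effect for
volumetry, across the 10 tracts per effect separately for FA$_\mathrm{T}$
and FW, across (metric, behavior) pairs separately per measure family for
the correlation battery, and across slices within a tract for the profile
tests. (The adjustment is *not* idempotent — re-adjusting adjusted values
inflates them — so the invariants asserted are $q \ge p$ and monotonicity in
rank order.) Missing behavior scores are explicit NaNs dropped per analysis
(listwise within each test), reproducing designs where behavior is scored on
fewer subjects than imaging; correlations with ASD-only instruments (ADI-R
section C, ADOS-2) are computed on ASD rows only. Slice-level tests use no
covariates — a deliberate asymmetry with the tract-level ANCOVA, matching
the source design — and slice profiling is gated by default on whole-tract
FDR significance.

## The synthetic cohort generator

The generator's defaults are the study conditions: cell counts 42/49/52/44
(ASD-M/ASD-F/TD-M/TD-F) for the enrolled cohort of 187 and 36/43/50/43 for
the 172 motion-passing diffusion subjects (the published exclusions are
12 ASD and 3 TD; their sexes are not printed, so the cells are reduced
proportionally). Age, IQ, RBS-R total, ADI-R-C and SCQ means/SDs per cell,
and the per-tract FA$_\mathrm{T}$/FW group means/SDs, are the published
table values verbatim. Sex shifts on the four tracts with reported sex
effects are back-computed from the printed F statistics
($d \approx 2\sqrt{F/N}$). RBS-R subscale marginals are not published;
plausible per-cell values were fixed once, with the restricted-interests
subscale carrying the reported diagnosis-by-sex interaction (males >
females, more pronounced in ASD).

Metrics are cell-appropriate normals; age and scanner slopes default to
zero so the marginal group SDs equal the printed SDs exactly (no covariate
slopes are published; covariates then only consume degrees of freedom,
which is the conservative configuration), with knobs to plant both.
Behavior scores are tied to metrics by a Gaussian copula (latent Pearson
$r = 2\sin(\pi\rho_s/6)$ for a target Spearman $\rho_s$), then pushed
through integer/floor marginal transforms to mimic the non-normal,
zero-inflated clinical distributions. The planted rank correlations are
within-cell; the pooled-sample Spearman also picks up the diagnosis shift
acting on both variables, so a planted −0.28 link reads about −0.35 in the
pooled cohort — within the generator's Monte-Carlo acceptance band. Links
into one behavior must satisfy $\sum r_m^2 \le 1$; infeasible structures
raise an error naming the offending pair. Tract metrics are independent
across tracts by default with an exchangeable-correlation knob, since
within-subject between-tract covariance is not published.

What the generator does **not** emulate: real anatomy and partial-volume
geometry, crossing fibers, susceptibility/eddy artifacts, scanner-specific
signal differences, or site effects. Passing tests therefore demonstrate
that the pipeline's inferences are correct for data obeying its model at
the published effect sizes — not that the published biology would replicate.

## Problem sizes and numerical choices

The parameter-recovery phantom uses 21 strata (f ∈ {0,…,0.6} × tissue FA ∈
{0.2, 0.5, 0.7}) of 480 voxels each (~10⁴ voxels) with the 64-direction
b = 1000 scheme; detection-rate checks use 100 seeded cohort replicates at
the study ns; null FDR calibration uses 1000 replicates of 48 outcomes; the
end-to-end pipeline test runs 12–20 subjects on 12³–16³ grids. The f search
resolution (2.5e-4) is an order below the 1e-3 recovery tolerance. Voxel
grids are single-subject-space by design: masks, labels and templates must
share the image grid (registration is out of scope), affines map 0-based
voxel indices to RAS mm, and only the FSL gradient dialect (3×N, with a
declared transposed variant) is read. Significance stars in reports follow
the conventional p < 0.05/0.01/0.001 at FDR-corrected values.

## Known limitations

- Single-shell free-water estimates are prior-dependent by construction;
  tissue-MD deviations from 0.7×10⁻³ mm²/s in real pathology will bleed
  into f at low SNR. The prior mean/width are exposed parameters.
- The smoothing pass is a stand-in for the original gradient-flow
  regularizer, not a reproduction of it.
- The ANCOVA engine covers two-level factors with single-df effects (the
  study's design); multi-level factors would need a partial-SS extension.
- ADOS-2 scores are simulated as a simple truncated normal; the generator's
  clinical marginals are calibration targets, not instrument models.
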