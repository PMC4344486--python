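# Methods

This note documents the models, defaults and limitations of the `sgdyn`
toolkit: what each analysis computes, what the synthetic-data generators
emulate, and the numerical and design choices that were genuinely open.

## Exchange kinetics (FRAP and photo-conversion)

### Model

Protein traffic between a stress granule and the cytoplasmic pool is treated
as balanced first-order exchange: at steady state the in- and out-fluxes are
equal, a single rate constant `k` (s⁻¹) describes both, and the inbound and
outbound half-lives coincide at `ln2/k`. With a cytoplasmic pool much larger
than the granule's content, the fluorescence of a bleached or photo-converted
region then relaxes mono-exponentially. We deliberately fit only this single
exponential with a plateau:

* FRAP: `F(t) = F_inf − (F_inf − F_bleach)·e^{−kt}` on the post-bleach frames
  of the normalized trace; mobile fraction
  `(F_inf − F_bleach)/(F_pre − F_bleach)`, immobile fraction its complement.
* Photo-conversion (red channel): `R(t) = R_plat + (R0 − R_plat)·e^{−kt}`;
  immobile fraction `R_plat/R0`; 30-s retained fraction `R(30)/R0` from the
  fitted curve.

Diffusion-limited recovery, bleach-spot geometry and multi-exponential decays
are out of scope; for granule-scale regions and second-scale exchange the
reaction-dominant single exponential is the standard reduced model.

### Acquisition and normalization

Traces follow the standard confocal protocol: 300 ms frame interval, 5 frames
before the event, 100 after a bleach and 300 after a conversion. Acquisition
bleaching dims ROI and reference alike; FRAP traces are double-normalized,
`F_n(t) = [roi(t)/ref(t)] / [mean_pre(roi)/mean_pre(ref)]`, which cancels
common-mode bleaching exactly and fixes the pre-event mean at 1. The red
conversion channel has essentially zero pre-event signal, so its pre-event
mean is not a usable scale; red traces are corrected by the reference ratio
only — all conversion read-outs (`R_plat/R0`, `R(30)/R0`) are scale-free
ratios, so the absolute scale is irrelevant. Without a reference trace, FRAP
falls back to pre-event-mean normalization with a warning.

### Fitting

Nonlinear least squares (`scipy.optimize.least_squares`) on the post-event
frames, parameters `(k, plateau, amplitude)`. Initialization: plateau from
the last 10% of frames, start level from the first post-event frame, `k₀`
from the time to half-amplitude; five multistarts at `k₀ × {¼, ½, 1, 2, 4}`,
best residual sum of squares wins. Tolerances 1e−14, so noiseless synthetic
traces are recovered to better than 1e−6 relative. Degenerate traces (no
recovery amplitude — e.g. a fully immobile pool — or `r² < 0.2`) return a
flagged result with `k = NaN` instead of raising.

Two immobile-fraction conventions exist in the literature: relative to the
recovery amplitude (`1 − mobile`, reported as `immobile_fraction`) and
relative to the pre-bleach level (`1 − F_inf`, reported as
`unrecovered_fraction`). The amplitude convention is the default because it
is what the generative model parameterizes; both are always reported.

### The short-window caveat

A 100-frame (30 s) recovery window covers only ~1.8 half-lives of the stable
class (17 s). The fit then flags `plateau_not_reached`, and on some noise
draws the *global* least-squares optimum sits at a slow-rate/low-plateau
solution — an identifiability limit of the window, not a numerical failure.
Two consequences:

* Classification (below) uses the immobile fraction *observed at the end of
  the window* (`immobile_fraction_end`) whenever the plateau was not reached,
  the standard practice for incomplete recoveries.
* Single-trace half-life estimates of slow exchangers scatter widely
  (median absolute error ~20%); aggregates (medians over ≥50 traces, or fits
  of averaged traces) are accurate to a few percent. Comparisons between the
  FRAP and conversion estimators for slow exchangers are therefore made on
  medians, while fast exchangers can be compared trace by trace.

The same caveat applies scientifically to granules early after stress
induction, where exchange has not reached steady state; the flag marks those
fits.

### Classification

Fits are assigned to the *transient* class when `t_half ≤ 5 s` and immobile
fraction `≤ 0.2`, to the *stable* class when `t_half ≥ 10 s` and immobile
`≥ 0.4`, otherwise *ambiguous*. The gaps (5–10 s, 0.2–0.4) lie between the
two observed regimes (~2–3 s with negligible immobile pool vs ~15–20 s with
60–70% immobile) and are configuration keys, not constants of nature.

### Generator presets

`transient`: half-life 2.5 s, immobile fraction 0 — the midpoint of the
observed 2–3 s range, with no immobile pool because none is observed (and
because converted transient-class protein clears almost completely within
30 s, which a nonzero plateau would contradict). `stable`: half-life 17 s,
immobile fraction 0.65 — midpoints of the observed 15–20 s and 60–70%
ranges. Default bleach depth 0.8, Gaussian trace noise as a fraction of the
pre-event intensity (0.02 in the standard simulations).

## Granule quantification

### Detection

Spots are detected on one channel with scale-normalized Laplacian-of-Gaussian
blob detection (`skimage.feature.blob_log`, σ 1–6 px, 11 scales), followed
by: peak refinement to the local maximum; a sub-pixel amplitude correction
(the peak pixel undersamples a spot centred between pixels by up to
`e^{−d²/2σ²}`); region growing at half of the estimated amplitude above the
per-field background (median intensity inside cells); and minimum-peak and
minimum-area filters. Each granule is assigned to exactly one cell by its
intensity-weighted centroid; centroids on background are discarded. Raising
the intensity threshold can only remove detections (monotonicity).

Cell masks are *inputs* (label images, 0 = background); no cell segmentation
is performed. Cells touching the image border are excluded from per-cell
statistics by default, since their visible area is partial.

### Per-cell statistics

`area_fraction` = granule pixels / cell pixels. A cell is *SG-positive* when
it has ≥ 2 granules covering ≥ 0.1% of its area — an operational rule (both
thresholds are config keys), since "SG-containing cell" has no standard
quantitative definition. Population summaries report % SG-positive and both
the per-cell mean area fraction (default read-out) and the pooled
granule-pixels/cell-pixels variant, with SDs across fields; groups under 100
cells warn but do not fail.

### Synthetic fields

Cells are non-overlapping ellipses (axes 16–34 px) fully inside a 256×256
image; granules are isotropic 2D Gaussians truncated at 3σ, parameterized by
their half-maximum radius (default 2.0–3.5 px, matching ~0.5–1.5 µm granules
at high magnification), planted with pairwise separation ≥ 2(r₁+r₂) so spots
never merge at the half-max level. The planted "area" ground truth is the
pixel count at or above half of the spot's amplitude — an unambiguous,
discretization-aware definition; for the smallest default spots the ±1 px
discretization bounds the achievable area agreement at roughly 10%.

Stress time courses draw each cell's SG positivity from a per-condition
logistic curve over time and, for positive cells, realize a target area
fraction (log-normal per-cell scatter, CV 25%) by planting the appropriate
number of granules. Defaults emulate the observed assembly kinetics:
controls reach ~80% SG-positive cells by 30 min of arsenate stress, the
triple TIA1/TIAR/G3BP1 knockdown is delayed and plateaus near 20% of the
control level at 2 h, with a proportionally reduced area fraction. What the
generator does **not** emulate: real point-spread functions and optical
aberrations, intensity heterogeneity within granules, cell shape irregularity,
granule fusion/fission, or imperfect manual cell masks — so passing tests
demonstrate correctness of the measurement chain on idealized images, not
robustness to all real-world imaging artifacts.

## qPCR decay analysis

`2^−ΔCt` against an untreated baseline gives relative abundance; ΔΔCt
additionally cross-normalizes to a reference gene measured in every sample
(amplification efficiency fixed at the classical 2.0). Replicates are
averaged in Ct (log) space before exponentiation — the convention chosen
where the order of operations was open — and SDs are propagated to the fold
scale by the first-order delta method (`sd = ln2 · value · sd_Ct`). The ΔΔCt
result is mathematically invariant to any per-sample Ct offset (plate
effects). Condition contrasts use Welch's two-sample t-test on log2
abundances per gene and time point, annotated `*` for p < 0.05 and `**` for
p < 0.005; single-replicate groups yield p = NA with a warning.

The Ct generator writes `Ct(t) = Ct(0) + log2(e)·λ·t` plus Gaussian cycle
noise (default SD 0.15 cycles), so abundance recovery is exact by
construction at zero noise; the reference gene does not decay.

## Array decay analysis

* **Reliability filter**: keep transcripts with detection p < 0.001 in *all*
  untreated samples (present/absent-call mode available). Lowering the
  threshold can only shrink the kept set.
* **Background correction**: subtract the per-sample 5th percentile, floored
  at a small positive epsilon. With a realistic fraction of absent probes the
  5th percentile estimates the additive background to within ~10%.
* **Quantile normalization**: every sample is mapped onto the cross-sample
  mean of sorted vectors; ties receive the mean of their would-be quantiles
  (average-rank interpolation, the same convention as limma). For tie-free
  data, sorted columns become identical and column means equal to 1e−10; a
  constant column is the degenerate case where the tie convention necessarily
  relaxes the identity.
* **Decay slopes**: ordinary least squares of *non-log* intensity against
  time (minutes), per transcript and condition, on replicate means by default
  (per-replicate fitting behind a flag). Non-log regression is the stated
  read-out of the emulated assay; a log-space fit would be statistically
  nicer for exponential decay but answers a different question.
* **Slope correlation**: Pearson r over the shared transcript set, with the
  paired table emitted for plotting.

One scale subtlety: quantile normalization forces all samples onto a common
distribution, which *removes the global decay component* of an ActD time
course and reorders the heavy upper tail even at zero noise. Slope recovery
against generative truth is therefore evaluated on the background-corrected
(scale-preserving) matrix; quantile normalization is available for real data,
whose per-sample technical distribution shifts — the thing it exists to fix —
the generator deliberately does not simulate.

### Fold-change scatter classes

For a steady-state {control, knockdown} × {no-stress, stress} design,
`(x, y) = (log2 knockdown/control without stress, with stress)` per
transcript on replicate-mean intensities. Classes, mutually exclusive with
red/blue taking precedence: **red** `y ≤ −1` and `|x| < 1` (down during
stress only), **blue** `y ≥ +1` and `|x| < 1` (up during stress only),
**green** ≥ 2-fold from the origin in any direction, **none** otherwise.
"Any direction" defaults to the Chebyshev reading (`max(|x|,|y|) ≥ 1`), which
keeps the per-axis red/blue definitions internally consistent; the Euclidean
reading is selectable. Quadrant counts of ≥2-fold transcripts are also
reported.

### Decay generator

Per-transcript half-lives are log-normal with median 60 min (log-sd 0.5) —
the regime a 0–120 min chase can actually resolve; transcriptome-wide real
half-lives are longer on average, so real short-chase slope estimates are
noisier than this benchmark (a known limitation, not emulated). Baselines are
log-normal (median 500, log-sd 1); 15% of probes are "absent" (no signal,
high detection p). Noise is multiplicative log-normal (sd 0.10) plus an
additive per-sample background (default 30 intensity units with 2% jitter).
Ground-truth slopes are the OLS slopes of the noiseless, background-free
curves on the sampled grid, so at zero noise the fitted slopes match truth to
machine precision. The steady-state generator plants ~4.5% of transcripts
with ≥2-fold effects in both states and ~1.2% each with stress-only
down/up effects, against a null scatter of log2-SD 0.15.

## Pipeline and reproducibility

All stages run from a single validated configuration (unknown keys are
rejected) with one global seed; each stage derives a named substream, so
changing one stage's parameters leaves the others' randomness untouched.
Outputs are plain CSV/JSON written at fixed float precision, making reruns
byte-identical; `provenance.json` records the seed, the full configuration
and its hash. The demo configuration uses deliberately small problem sizes
(10 traces per class, a 2-condition × 2-time-point image course of 256×256
fields, 5 qPCR genes, 600 transcripts) and completes in well under a minute
on one CPU; the standard property checks use 50 traces per class, 500 cells
and 2000 transcripts.

## Known limitations

* The exchange model assumes steady state; early-granule fits are flagged,
  not corrected.
* Single-trace rate estimates for slow exchangers are window-limited (above).
* The image generator's idealizations mean detection performance on real
  micrographs will be lower than on synthetic fields.
* Amplification-efficiency correction, multi-reference-gene normalization,
  probe-to-gene collapsing and empirical-Bayes differential expression are
  out of scope by design.
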