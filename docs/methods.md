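# Methods

`stimrel` quantifies how reliably neural recordings track a repeated
naturalistic stimulus, and how strongly different recording modalities
track each other, using correlation maps standardized against
surrogate-based null distributions. This note documents the statistical
model, the synthetic cohort that the tests run on, the numerical
choices, and the limitations of both.

## Signal model and comparison levels

All comparisons operate on band-limited log-amplitude envelopes on a
common temporal grid: 297 s of stimulus-locked data sampled at 20 Hz
(5,940 samples). Eight bands are analysed by default — δ 0.5–4, θ 4–8,
α 8–12, β 12–28, γ1 28–46, γ2 55–70 Hz, a high-frequency band (HF)
64–116 Hz, and a broadband signal 0.5–116 Hz. Band extraction is a
zero-phase 4th-order Butterworth bandpass followed by the natural log of
the analytic-signal modulus (Hilbert transform). A hemodynamic modality
contributes its raw slow signal (one band-agnostic series per subject
and viewing) sampled at the repetition interval and linearly
interpolated onto the 20 Hz grid.

Three comparison levels are computed per band and channel:

* **within-subject** — r(viewing 1, viewing 2) per subject;
* **between-subject** — each subject's viewings against the alternate
  viewings of every other subject (2(S−1) bidirectional pairs),
  averaged to one value per subject;
* **between-method** — every (subject, viewing) of one cohort against
  the alternate viewing of every subject of another cohort. An
  electrode montage pooled across patients enters as one composite
  subject, and Spearman rank correlations replace Pearson whenever a
  montage participates (robustness to amplitude outliers).

Correlations are Fisher z-transformed (atanh) before any averaging; a
grand average (GA) is the mean Fisher-z per channel. |r| = 1, which only
occurs in degenerate fixtures, is clamped to 1 − 1e−12 rather than
allowed to produce infinities.

## Surrogate inference

Significance is never parametric. For each time series entering a
comparison, iAAFT surrogates preserve the value distribution exactly and
the amplitude spectrum approximately while destroying stimulus-locked
phase structure. For every comparison entry the second-listed side (the
hemodynamic/counterpart side for cross-modal comparisons) is replaced by
each of its `n_surr = 100` surrogates and the correlation recomputed.
GA null draws are then bootstrapped `n_boot = 10,000` times by sampling
one surrogate correlation per entry and averaging exactly as the
empirical GA does. The per-channel SNR is

    z = (r_GA − μ_surr) / σ_surr

with μ_surr, σ_surr the mean and SD of the channel's null draws.
p-values are add-one permutation proportions ((b + 1)/(n + 1); the plain
proportion is available), one-sided positive for within/between-subject
comparisons and two-sided on |GA| for cross-modal comparisons, where
genuinely inverse coupling is expected at low frequencies.
Benjamini–Hochberg FDR is applied across channels at q = .05. A pooled
montage analysed as a single subject cannot be bootstrapped at the
subject level; it uses 1,000 surrogate correlations per channel directly
as the null.

RNG streams fan out from one root seed keyed by (modality, subject,
viewing, band), so surrogate sets are generated once per series, reused
across every comparison sharing that series, and reproducible under
partial re-runs.

### iAAFT numerics

Initialization is a random permutation; each iteration imposes the
target amplitude spectrum and then rank-remaps onto the sorted original
values, so `sorted(surrogate) == sorted(original)` holds exactly at
every iterate. Iteration stops when the rank ordering is unchanged or at
`max_iter` (default 100 for the standalone operation). The iteration
runs in single precision — only the value ordering matters — and the
final surrogate is assembled from the double-precision sorted originals.
The pipeline caps bulk surrogate generation at
`surrogate_max_iter = 10`: on AR(1)-like envelope series the relative L2
spectrum error plateaus below 0.1% within a few iterations, far inside
the 5% tolerance that matters for null validity, and null calibration is
indistinguishable from full convergence.

## SNR contrasts and cluster statistics

Two significance maps are contrasted channel-wise on the z scale,
dz = z_B − z_A, with |z_B| substituted when side B is a cross-modal map
(its sign carries physiology, not strength). Candidate clusters are
connected components of channels above the 97.5th or below the 2.5th
percentile of the map's own dz values, with adjacency defined by an
edge-if-within-distance graph (default threshold 1.5× the median
nearest-neighbour distance; on an 8 mm grid this yields
18-connectivity). Each of `n_maps = 10,000` surrogate SNR maps draws one
stored GA null value per channel per side, standardizes it against its
own null, and goes through *the same* thresholding and clustering code
path; the p-value of an empirical maximum cluster is the add-one
proportion of surrogate maximum absolute cluster sums at least as large.
BH correction is applied to the per-band collection of max-cluster
p-values at q = .025. Surrogate-map thresholds are recomputed from each
map's own distribution (keeping the null statistic exchangeable with the
empirical one); applying the observed thresholds instead is exposed as
an option. Surrogate maps draw channels independently; spatially
correlated surrogate maps are out of scope.

## Spatial and temporal alignment

A volumetric support maps onto a source grid by nearest-coordinate
assignment (each grid point averages the voxels for which it is the
nearest grid point; ties go to the lowest channel index) and onto an
electrode montage by 6 mm-radius pooling with per-electrode voxel counts
retained; unassigned channels are flagged missing and excluded from
every comparison they would have entered, never silently zeroed.

The stimulus lag of the hemodynamic modality is the argmax over
±15 s of the lag-wise Pearson correlation between the stimulus audio
envelope and the mean series of the 20 channels nearest the centroid of
the auditory-tagged region. The default maximizes |correlation| because
the synthetic BOLD mixture of signed band couplings may anticorrelate
with the envelope; maximizing the signed correlation is an option. The
estimated shift absorbs the hemodynamic response delay itself, exactly
as in the real procedure; an *injected* extra delay is recovered by
differencing against a zero-delay reference, which cancels the kernel
shape bias. With realistic viewing noise the argmax additionally jitters
by a fraction of the repetition interval (noise interpolated from a
1.5 s grid is smooth below that scale) — a property of the data, not the
estimator — so the shift-recovery check runs on the deterministic
forward chain.

## The synthetic cohort

The generator provides ground truth; it is a testing device, not a claim
about real data. Per band b and channel c, a stimulus-locked latent
g_{b,c} (unit variance) is shared by all subjects and viewings. The
band-limited log-amplitude of subject s, viewing v is

    x_{s,v} = √a·g + √b·u_s + √(1−a−b)·ε_{s,v}

with u_s stable across the two viewings and ε viewing-specific, all
components empirically standardized. Hence E[r(within)] = a + b and
E[r(between)] = a. Defaults: a = b = 0.1, 10 electrophysiology
subjects, 11 hemodynamic subjects, a 656-electrode montage pooled from 5
pseudo-patients (uniform points on a 70 mm-radius shell), and a
5×5×2-point 8 mm grid as the desk-scale stand-in for a full source
grid. Two viewings per subject, always.

Component spectra: the shared latents are Gaussian noise low-passed at
0.2 Hz — stimulus-locked envelope fluctuations are slow, and a
hemodynamic modality must retain coupling to them through the response
kernel — while u and ε are AR(1) with ρ = 0.5, making surrogate testing
non-trivial. A scalar stimulus drive underlies the audio envelope
(shifted to be non-negative) and loads with weight √0.5 on the HF-band
latents of auditory-tagged channels only: high-frequency amplitude is
the canonical signature of temporally precise auditory tracking, and
confining the drive to one positively-coupled band keeps the
hemodynamic coupling signs of the other bands clean.

The hemodynamic forward model mixes the band latents with
band-dependent signs (δ, θ, α, β negative; γ1, γ2, HF positive — the
known inverse low-frequency-power/BOLD relationship), convolves with a
unit-sum double-gamma kernel (peak 5 s, undershoot 15 s), applies the
stimulus delay (default 4.5 s), samples at TR = 1.5 s, and adds white
noise so the shared fraction is again `a`. Convolution and delay are
circular: the stationary latent stands in for a stimulus with continuous
context outside the analysis window, avoiding a startup transient.

In `envelope` mode the generator emits log-amplitude series directly on
the 20 Hz grid (analytically tractable); in `raw` mode it synthesizes
amplitude-modulated sinusoidal carriers at each band centre sampled at
256 Hz, with slow modulators (low-passed at 1 Hz) so the carriers stay
band-limited, and the full filter chain (notch → bandpass → Hilbert →
resample) must recover the same decomposition. Broadband is an analysis
construct and is not synthesized as a separate carrier.

What the generator does *not* emulate: 1/f background spectra,
artifacts, head movement, spatial leakage of source reconstruction,
anatomically realistic geometry, or spatially correlated noise. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under a known model — not that real recordings
satisfy that model.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at desk scale, as the package's own choice of
test instrument: null calibration uses 20 replicate cohorts of 10
subjects × 50 channels × 5,940 samples with n_surr = 20 and
n_boot = 1,000; the cluster-test calibration/power check uses a
144-channel grid (a compact 10-channel injected cluster is then 7% of
the support — real clusters are far smaller fractions of their maps), 75 s
series, 200 replicates at n_maps = 500; sign recovery uses the full
seven coupled bands at the default cohort sizes. The shipped default
configuration reproduces the canonical analysis settings exactly (100
surrogates, 10,000 bootstrap GAs, 10,000 surrogate SNR maps, 1,000
surrogates for the single-subject montage variant, q = .05 / .025,
20 Hz, 297 s, 6 mm, 20 nearest channels).

## Known limitations

* Channel-independent surrogate SNR maps understate spatial correlation
  of real map noise; cluster p-values on real data should be read with
  that in mind.
* The between-method GA averages all pairs flatly; a two-stage
  (per-subject first) average is available and can differ when cohort
  sizes are unbalanced.
* The montage null (no bootstrap) and the bootstrap null agree in
  distribution only under exchangeability of entries; both are exposed.
* `raw` mode recovers the generative decomposition only approximately at
  band edges (filter roll-off), and its broadband envelope mixes all
  carriers by construction.
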