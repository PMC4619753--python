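# Methods

This note documents the models, conventions and numerical choices behind
`nirsfc`, and what the synthetic-data tests do and do not demonstrate.

## Signal model

A continuous-wave fNIRS channel measures light intensity `I(t)` between one
source and one detector at two wavelengths (defaults 690 and 830 nm).
Intensity is normalized to optical density against its own temporal mean,

    OD(t) = -ln( I(t) / mean_t I ),

using the natural logarithm. The log base only rescales the extinction
coefficients, so this choice is a convention; it is absorbed consistently
because the same units are used in the inversion. By construction OD is
invariant to rescaling a channel by a positive constant and is zero wherever
the intensity equals its mean — which also means absolute concentration
levels are not recoverable: everything downstream works with *changes*
around an arbitrary per-channel baseline.

The modified Beer-Lambert law relates OD changes to chromophore
concentration changes:

    dOD(lambda) = [ eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR ] * L * DPF(lambda)

with `eps` in cm^-1 (mol/L)^-1, the source-detector separation `L` in cm and
the dimensionless differential pathlength factor `DPF` (default 6.0 at both
wavelengths, the conventional adult-head value; configurable). With two
wavelengths this is a 2x2 linear system per channel pair and time point,
solved directly; concentrations are reported in µmol/L and
HbT = HbO + HbR. The embedded extinction table covers 690 and 830 nm from
the compiled hemoglobin spectra commonly used in CW-NIRS tooling; other
wavelengths require explicit `MBLLParameters` (matching tolerance 15 nm).
The matrix's condition number is exposed so ill-separated wavelength pairs
are visible.

## Band-pass filtering

The default band is 0.01–0.1 Hz, the band in which spontaneous hemodynamic
fluctuations used for resting-state connectivity live. The filter is a
cascade of a 5th-order Butterworth high-pass at 0.01 Hz and a 3rd-order
Butterworth low-pass at 0.1 Hz, each applied forward-backward
(`sosfiltfilt`), which doubles the effective order, squares the magnitude
response and cancels group delay exactly. Cascade order is high-pass first.

Numerical note: at 25 Hz sampling the high-pass corner sits at a normalized
frequency of 8e-4 and its poles lie very close to the unit circle, giving
edge transients with a time constant of roughly `1/low_cut` seconds.
Filtering therefore uses odd-reflection padding of about three high-pass
time constants (clamped to the signal length) instead of scipy's short
default; without this, low-frequency transients leak through the low-pass
stage and can dominate short recordings. Even so, amplitude-response
measurements in the tests use the central half of a 600 s probe signal so
that residual edge effects have decayed; recordings much shorter than ~100 s
should not be trusted near the 0.01 Hz edge.

## Detrending

Per channel, the ordinary-least-squares straight line is subtracted
(`scipy.signal.detrend`). The output has zero mean and zero fitted slope and
the operation is idempotent.

## Motion correction

**Moving-standard-deviation detection.** The MSD is the sample standard
deviation inside a centered sliding window (default 2 s); edge windows are
truncated to at least 2 samples so the mask aligns with the time axis.
Samples with `MSD > mean(MSD) + T * sd(MSD)` (default T = 5) are flagged and
merged into segments, bridging gaps up to one window. An absolute-threshold
mode is also provided. A structural limitation of the relative rule: an
artifact occupying a large fraction of the recording inflates `sd(MSD)`
itself, and by Chebyshev's inequality at most ~1/T² of samples can ever
exceed a mean + T·sd cut — pervasive artifacts need the absolute mode or a
lower T.

**Spline subtraction.** Within each flagged segment a cubic smoothing spline
(`make_smoothing_spline`, with the smoothing parameter p in (0, 1] mapped to
the penalty `lam = (1-p)/p`; default p = 0.99, close to interpolation) is
fitted and subtracted, removing the artifact along with the slow signal
inside the segment. The corrected segment is then re-anchored to the linear
trend of the preceding clean window extrapolated across the segment, and all
following samples are shifted so the post-segment signal continues that
trend. Trend extrapolation, rather than matching raw window means, keeps the
re-leveling unbiased when the underlying signal has slope across the
artifact; it is what makes persistent baseline jumps (step artifacts)
correctable, not just transients. Segments shorter than 4 samples fall back
to mean subtraction. Flagging the entire series is an error ("signal
unusable"); a zero-variance series is returned unchanged.

**CBSI.** Correlation-based signal improvement assumes functional HbO and
HbR are anticorrelated while motion moves both the same way. With
`alpha = sd(HbO)/sd(HbR)` per channel:

    HbO' = (HbO - alpha * HbR) / 2,    HbR' = -HbO' / alpha.

The corrected pair is exactly anticorrelated (`corr = -1` by construction)
and any component appearing in HbO and in HbR scaled by `1/alpha` cancels
exactly. A constant HbO or HbR channel makes `alpha` undefined and raises.

## Quality control

SNR is computed on raw intensity as `mean / sd` over time (sample sd);
poor optode-scalp contact shows up as low SNR. A zero-variance channel is
reported as +inf with a warning rather than silently passing. The
cross-check is each channel's mean absolute Pearson correlation with all
other channels, computed on the concentration signal: a noise-dominated
channel correlates with nothing. Subject-level verdicts combine three
cutoffs that the underlying acquisition literature does not fix numerically,
so they are package defaults, all configurable: SNR floor 20, mean-|r| floor
0.05, maximum flagged-channel fraction 0.2 and maximum motion-time fraction
0.2. SNR flags are keyed by intensity-channel (per wavelength); correlation
and motion flags by measurement pair.

## Connectivity and group statistics

Pairwise connectivity is Pearson's r, Spearman's rank correlation (Pearson
on average ranks), or normalized cross-correlation: the signed r at the lag
in ±10 s (default) maximizing |r|, ties broken toward the smallest |lag| and
then the negative lag; positive lag means the second series is delayed. At
`max_lag = 0` cross-correlation reduces exactly to Pearson. Zero-variance
inputs yield an explicit NaN marker, never a silent zero.

Group maps across n subjects are elementwise: the R map (mean r), the Z map
(mean `z = atanh r`), the Z-to-R map (`tanh` of the Z map — not equal to the
R map in general; both are reported) and the T map (one-sample t of the
subject z values against zero, df = n-1, two-sided uncorrected p). No
multiple-comparison correction is applied; p values are emitted so users can
correct downstream. NaN entries propagate pairwise-complete with the
contributing count per entry; unit correlations (the whole-brain diagonal)
give infinite z, hence Z-to-R of 1 and an explicitly undefined t.

## Network analysis

The whole-brain r matrix (diagonal forced to 0) is thresholded either at an
r cutoff or at a sparsity s, keeping the `ceil(s N(N-1)/2)` strongest
positive connections. Negative correlations are excluded by default (an
absolute-value mode exists), following common practice in fNIRS network
construction. Metrics:

- clustering `c_i = 2 tri(i) / (k_i (k_i - 1))` (binary) or the
  Onnela geometric-mean triangle form (weighted); Cp is the mean over all
  nodes, counting `c_i = 0` for degree < 2;
- characteristic path length Lp: mean shortest-path length over *connected*
  ordered pairs, with the disconnected fraction reported separately;
  weighted graphs use 1/w edge lengths;
- efficiencies use `1/d` with `1/inf = 0`, so disconnection penalizes rather
  than undefines them; local efficiency is the global efficiency of each
  node's neighborhood subgraph;
- betweenness is unnormalized shortest-path betweenness with fractional
  counting over multiple shortest paths;
- modularity Q (Newman) is maximized exactly by enumerating all set
  partitions for graphs up to 10 nodes, and by greedy agglomeration
  (Clauset–Newman–Moore) plus seeded single-node-move refinement above that;
- the hierarchy exponent beta is the negative slope of the least-squares fit
  of `log c_i` on `log k_i` over nodes with degree >= 2 and positive
  clustering; at least three eligible nodes spanning two distinct degrees
  are required, otherwise beta is an explicit NaN.

Small-world indices normalize against degree-preserving null networks
(Maslov–Sneppen edge swaps, default 10 attempted swaps per edge, 100 nulls,
all seeds derived from one base seed): `gamma = Cp / mean(Cp_rand)`,
`lambda = Lp / mean(Lp_rand)`, `sigma = gamma / lambda`. Note that some of
the surrounding literature occasionally swaps the gamma/lambda labels; here
gamma is always the clustering ratio and lambda the path-length ratio.

Sparsity sweeps parallelize over (subject, threshold) tasks with
`joblib`; every task derives its own seed from the base seed and threshold,
so tables are bit-identical for any worker count, and per-task failures are
recorded in an `error` column instead of aborting the sweep.

## Synthetic data

The generator emulates the acquisition geometry the pipeline targets — 46
measurement channels at 25 Hz by default, 3.2 cm separations, 690/830 nm —
with a planted truth at every stage. Channel HbO mixes a block-shared latent
source (weight `sqrt(within_r)`) with independent noise
(weight `sqrt(1 - within_r)`), both unit-variance and exactly band-limited
to 0.01–0.1 Hz; the expected within-block Pearson r is therefore `within_r`
and between-block r is 0. Band-limited noise is synthesized in the frequency
domain (white spectrum restricted to the band) — filtering white noise
causally would leak shared edge-transient modes into every series and
corrupt the planted independence. HbO fluctuations default to 0.05 µmol/L
sd, a typical resting-state magnitude; HbR is `-HbO/3` plus independent
noise, matching the physiological anticorrelation and amplitude ratio CBSI
assumes; per-channel linear drifts (default slope within ±0.001 µmol/L/s)
exercise detrending. The planted correlation targets apply to the
band-limited component, i.e. after drift removal.

Raw intensity comes from the exact forward model
`I = I0 exp(-eps · dC · L · DPF)`, so OD + MBLL inversion recovers the
planted concentrations to numerical precision *up to one additive constant
per channel* (the mean-normalization of the OD step); round-trip checks
therefore compare after demeaning. Injected "dead" channels are white noise
at a target SNR, clipped at a 1%-of-mean detector floor so the log transform
stays defined; motion artifacts are steps or boxcar spikes with a returned
sample mask.

What passing tests show — and do not show: the synthetic sources are
Gaussian, stationary, linearly mixed and free of cardiac/respiratory
oscillations, superficial-physiology contamination and optode-coupling
drifts other than linear; recovery of the planted structure validates the
computational chain, not the physiological validity of any particular real
recording.

## Problem sizes

Simulation-based checks use 10 subjects x 20 channels x 300 s at 25 Hz for
group-map recovery, 600 s single-channel series for filter and motion
checks, 200 random graphs with up to 8 nodes for the enumeration oracles,
and a 100-node, degree-10 lattice with 100 nulls for the small-world regime.
These sizes put every Monte-Carlo quantity well inside its assertion band
while keeping the suite quick to run.

## Known limitations

- Two-wavelength MBLL only; no water/lipid chromophores, no partial-volume
  correction.
- No wavelet or PCA motion correction, no short-separation regression.
- The Hitachi-style CSV dialect is a documented minimal stand-in (header
  `key,value` lines plus a numeric block); vendor exports vary and optode
  coordinates are synthesized, not read.
- Cross-correlation matrices report the upper-triangle lag with its sign
  flipped below the diagonal; the matrix of r values is symmetric by
  construction only up to the |r|-maximizing lag being unique.
- The greedy modularity optimizer above 10 nodes is a heuristic; only the
  exact small-graph regime carries an optimality guarantee.
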