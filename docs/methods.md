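# Methods

`csirr` estimates respiratory rate (RR) from the magnitudes of Wi-Fi OFDM
channel state information (CSI). Chest and abdominal displacement during
breathing perturbs the propagation paths between a transmitter and receiver,
modulating the per-subcarrier magnitude of the channel estimate. The package
implements the full estimation chain on a T×K magnitude matrix (K = 256
subcarriers at 80 MHz bandwidth, nominally 50 packets/s), along with the
synthetic session generator and airflow reference used to validate it.

## Pipeline

Every 30 s sliding window (1 s step, trailing-edge timestamps: an estimate
at time *t* summarises (*t* − 30 s, *t*]) is processed as follows.

**1. PCA and component selection.** The window's subcarrier columns are
mean-centred and decomposed via the eigendecomposition of the K×K
covariance; components are ordered by explained variance and their sign is
fixed so each projection has non-negative skewness (eigenvector sign is
arbitrary; a deterministic convention keeps both estimators' inputs stable
across runs). Each component *i* is scored with a component quality index

CQI_i = Γσ_i · ΓSNR_i · Γpeak_i,

where Γσ_i is a binary variance index (1 for ranks up to the adaptive elbow
m\*, the smallest rank whose next component adds < 1% explained variance; at
least one component is always retained), ΓSNR_i ∈ [0, 1] is the fraction of
the one-sided spectral magnitude (mean-removed, untapered FFT) inside the
physiological band 5–35 brpm (0.083–0.583 Hz), and Γpeak_i is 1 when the
dominant non-DC spectral peak is at or above f_min = 5 brpm (inclusive),
guarding against high-variance 1/f drift components. The five components
with the highest CQI are selected (ties broken by variance rank; if every
CQI is zero the highest-variance components are used and the window flagged
low-quality). Because CQI vanishes identically beyond the elbow, projections
are only materialised for the first max(m\*, 5) ranks — a performance
choice with no effect on the result.

**2. Filtering.** Each selected component passes through a 4th-order
Butterworth high-pass at 5 brpm then a 4th-order low-pass at 35 brpm, both
applied forward-backward (zero phase) so breath timing is not skewed. The
filter family and order for this stage are this package's choice; the band
is configurable, with a 6–33 brpm preset matching the paced-protocol
extremes.

**3. Dual RR estimation.** *Breath counting*: the box slope sum function
(BSSF) — a trailing 1.0 s sum of positive first differences — is
peak-picked with a refractory period of 60/35 ≈ 1.71 s and an adaptive
threshold of 0.5 × the median slope-sum peak height per window; each
accepted peak is searched back to the start of its rise to timestamp the
breath onset, and RR_breath = (N − 1)/(t_N − t_1) · 60 over the window's
onsets. The box width, threshold factor and refractory scale a pulse-wave
onset detector to breathing timescales. *Spectral peak*: RR_FFT is 60 ×
the frequency of the largest Hann-windowed FFT magnitude inside the band;
at T = 30 s the resolution is 1/30 Hz = 2 brpm, a floor on achievable
accuracy. The combined estimate is the arithmetic mean; when exactly one
estimator is defined its value is used alone and the agreement factor below
is forced to 0.

**4. Signal quality.** SQI_i = ΓSNR_i · ΓAgree_i · ΓSPI_i, with ΓSNR_i taken
from the pre-filter spectrum of step 1, ΓAgree_i = 1 iff |RR_FFT −
RR_breath| ≤ 4 brpm (inclusive), and ΓSPI_i the spectral purity index
m₂²/(m₀·m₄) built from moments m_n = Σ ωⁿ S(ω) of the one-sided power
spectrum over normalized angular frequency ω ∈ [0, π] rad/sample. SPI is 1
for a single spectral line and 5/9 for a perfectly flat spectrum (the
closed-form value of the moment ratio; the index penalises spectral spread
rather than literally approaching 0 for white noise). A Hann taper is
applied before the SPI periodogram: the ω⁴ weight makes the fourth moment
hypersensitive to the slowly decaying (f⁻²-power) sidelobes of the implicit
rectangular window, which otherwise collapse the index to ~10⁻³ even for a
clean breathing tone; the Hann sidelobes (f⁻⁶ power) make the moment
integrals well behaved while leaving the tone value ≈ 0.98 and the
flat-spectrum value at 5/9.

**5. Fusion.** Each component rank keeps a scalar random-walk Kalman filter
on RR across windows (rank after CQI sorting identifies the source — a
label-switching approximation, since components are not tracked between
windows). Defaults: process variance 0.1 brpm²/step, chosen against the
protocol dynamics of ≤ 3 brpm change per 120 s; initial error variance
(band width/4)²; measurement variance base/SQI² with base = 1 brpm², so an
unreliable window barely moves the state. Sources with SQI = 0 or no
estimate run predict-only and are excluded from the window's fusion. The
fused RR is the product-form weighted mean of the filtered states with
per-source variance σ_i² = r_i/SQI_i² (r_i defaults to the posterior error
variance of the source's filter; a squared-innovation residual is available
behind a config switch, since "residual error" admits both readings), which is
algebraically the inverse-variance weighted mean. Windows with no usable
source, or a fused value outside the band, are flagged invalid; forward
filtering only, matching real-time use.

## Reference RR from airflow

The 32 Hz nasal-pressure trace is band-passed with an 8th-order Butterworth
IIR (5–35 brpm) applied forward-backward; zero-phase application doubles
the effective attenuation but keeps peak timestamps unbiased, which matters
because RR is computed from peak times. Per 30 s window, alternating local
extrema are found, Q3 of the absolute adjacent-extrema differences is
computed over that window only, and peaks whose smaller vertical separation
from an adjacent trough falls below 0.3·Q3 are discarded recursively (worst
offender first, merging its neighbouring troughs by keeping the deeper)
until stable — termination is guaranteed because the peak count strictly
decreases. RR = (N − 1)/(t_last − t_first) · 60 (the N − 1 interval
convention is used consistently for both this and breath counting; counting
N peaks over the same span would overestimate by one cycle). Windows whose
RR deviates from the metronome rate by strictly more than 4 brpm are
invalidated (a deviation of exactly 4 is kept), mirroring the protocol
compliance exclusion; the operation is idempotent.

## Synthetic data generator

The generator emulates the paced protocol: a metronome schedule stepping
6 → 33 brpm by 3 brpm every 120 s (10 levels, 20 min). The respiratory
waveform is a phase-continuous raised-cosine cycle with inhale fraction 0.4
(mild asymmetry gives realistic harmonic content that exercises the peak
detectors), whose instantaneous rate follows the schedule plus a bounded
random-walk compliance jitter (clipped at ± jitter brpm, updated at 1 Hz).
Each of a random subset (default 20% — only a minority of components carry
breathing in practice) of the 256 subcarriers adds the waveform to a static
baseline drawn in [10, 30] with a log-normal gain (modulation depth 5% of
baseline) and a phase lag uniform in one mean breath period; all
subcarriers receive 1/f-like drift (integrated white noise low-passed below
0.05 Hz) and white noise, plus optional 3 s broadband motion bursts (std
3.0) across every subcarrier. Magnitudes are clipped at zero. The matched
airflow trace resamples the waveform to 32 Hz with additive noise and slow
wander. All randomness flows through one seeded generator; sub-seeds for
the waveform, CSI and airflow stages derive deterministically from the
session seed.

Profiles: `clean` (no drift/motion/jitter, noise 0.1), `moderate` (noise
0.3, drift 0.5, 2 motion bursts, jitter 0.5 brpm — the validation
condition), `noisy` (noise 1.0, drift 1.5, 4 bursts, jitter 1 brpm). The
clean profile keeps a small sensor-noise floor rather than zero noise: an
exactly noise-free ensemble is singular, because PCA of noise-free
phase-lagged copies of a periodic waveform separates the breath harmonics
into distinct components that score as high-quality in-band tones (the
2nd harmonic of every level up to ~17 brpm is still inside 5–35 brpm) and
bias the fusion — a geometry no real capture exhibits, since CSI magnitudes
always carry a quantisation/thermal floor. The exact zero-noise limit
remains reachable through `synth_csi` parameters for per-subcarrier tests.

What the generator does *not* model: RF propagation physics, complex-valued
CSI or phase, packet loss, multi-person scenes, posture changes, or the
nonlinear standing-wave dependence of magnitude on displacement. Passing
the synthetic benchmarks therefore demonstrates correctness and noise
robustness of the algorithmic chain under the stated statistical structure,
not performance on real Wi-Fi recordings.

## Numerical choices and degenerate inputs

Zero-variance windows yield a single degenerate component with CQI forced
to 0. Constant signals give empty peak/onset trains, not exceptions; RR
from fewer than two peaks/onsets is NaN and the window invalid. Band edges
are treated inclusively (a spectral peak exactly at f_min passes; an
estimator disagreement of exactly 4 brpm agrees). RR-band reports use
intervals inclusive on the lower edge ([12, 21), etc.), membership by the
mean of estimate and reference; r² is the squared Pearson correlation, and
limits of agreement are bias ± 1.96 SD of the differences. Session
timestamps are regularised by per-subcarrier linear interpolation onto a
uniform 50 Hz grid, with gaps > 1 s flagged.

## Problem sizes

The end-to-end benchmark runs three full-protocol sessions (20 min each,
60 000 × 256 samples, 1171 windows per session) in ≈ 2.5 min on one CPU;
unit and property tests use 1–3 minute sessions and small subcarrier counts
chosen to keep the suite fast while preserving the spectral geometry
(≥ 30 s windows, 50 Hz sampling).

## Known limitations

Component identity across windows is positional (label switching under
noise); the Kalman process noise is tuned to slow paced protocols and will
lag abrupt RR changes; at 6 brpm a 30 s window holds only three breath
cycles, so breath-count estimates are fragile exactly where the study
design predicts reduced accuracy; the 2 brpm FFT resolution floors the
spectral estimator; and the generator's linear coupling model cannot produce
the harmonic distortion a strongly displaced reflection path would create.

One consequence of the generator's regularity is worth stating plainly: its
breath onsets are cleaner than real CSI breathing, so on synthetic sessions
the breath-counting estimator alone can outperform the breath/FFT average
(measured on a full-protocol moderate session: breath-only-fused MAE 0.67
vs combined-fused 0.76 vs FFT-only-fused 0.89 brpm). Averaging with the
2 brpm-quantised FFT estimate is retained because it hedges against the
false and missed onsets that irregular real waveforms produce; passing the
synthetic benchmark does not demonstrate that benefit, only the correctness
of the combination and fusion machinery.
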