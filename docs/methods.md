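# Methods

## The question the pipeline answers

Animal vocalizations carry structure in how their loudness evolves over
seconds to minutes. `fractalvoc` asks, recording by recording, whether the
low-frequency power spectrum of the squared amplitude (the envelope power) is
better described by

* a **fractal law** `S(f) = A f^-beta + gamma^2` — scale-free, long-range
  temporal correlations, with spectral index `beta` measuring how much
  long-timescale structure the signal has (`beta = 0` is white noise), and a
  white offset `gamma^2` standing in for background noise; or
* a **short-memory ARMA(1,1) spectrum**
  `S(f) = A (1 + 2 theta cos(2 pi f tau) + theta^2) / (1 - 2 phi cos(2 pi f tau) + phi^2)`
  — the rational spectrum of an autoregressive moving-average process with
  memory parameter `phi`, oscillatory strength `theta`, and timescale `tau`;
  correlations decay exponentially beyond `tau / ln(1/phi)`.

The two hypotheses are compared by Bayesian evidence: each model is fit by
nested sampling and `ln Z_ARMA - ln Z_fractal` is reported per recording
(negative favours the fractal law). Per-recording indices are then pooled
into species-level statistics.

As printed in some sources the ARMA denominator carries `theta` in the cosine
term, which goes negative for `|theta| > 1`; the standard ARMA(1,1) form with
`phi` is the default here and the literal variant is available via
`arma_denominator="as_printed"` for sensitivity checks.

## Preprocessing chain

1. Drop the first 5 s (the source library's spoken announcement).
2. Require at least 100 s of remaining signal (two decades of frequency
   information above the 0.01 Hz band edge).
3. Square the waveform: instantaneous power.
4. Decimate 44 kHz -> 220 Hz in three stages (10, 10, 2). Each stage is an
   eighth-order type-I Chebyshev low-pass (0.05 dB ripple, cutoff 0.8x the
   stage output Nyquist) applied zero-phase, then subsampled. Two deliberate
   choices: stages are normalized to exactly unit DC gain (the raw
   even-order Chebyshev sits 0.05 dB below unity at DC, which would scale a
   constant signal by 3.4% across three double-pass stages), and the squared
   magnitude response is applied circularly in the Fourier domain — the same
   transfer function forward-backward filtering realizes, but without edge
   transients, which on a 100 s window otherwise contaminate the spectrum at
   the percent level.
5. Remove the mean and take the one-sided periodogram (no window, no segment
   averaging; Parseval-normalized). The fitted quantity is the magnitude
   squared; a `quantity="magnitude"` switch exists for sensitivity checks.
6. Keep 0.01 Hz <= f <= 10 Hz (closed interval). The upper edge excludes
   tonal/pitch structure; the lower edge reflects available recording
   lengths. Non-44 kHz inputs are resampled to 44 kHz first so the stated
   factors always land on 220 Hz; stereo is averaged to mono.

## Likelihood and priors

The measured spectrum is modelled as the chosen `S(f)` plus independent
Gaussian scatter of variance `kappa * A` per bin; `kappa` is a fitted
nuisance absorbing periodogram noise, fit independently per model. Priors:
`A` log-uniform over 12 decades geometrically centred on the median observed
power (so the bracket always contains the maximum-likelihood point);
`kappa` log-uniform over the same data-scaled bracket — the required variance
tracks the square of the data's amplitude scale, so `kappa`, like `A`,
carries one factor of scale; `beta` uniform on [0, 4]; `gamma` uniform on
[0, 10]; `theta` uniform on [-2, 2]; `phi` uniform on [0, 1]; `tau` uniform
on [0, 100] s (the generating process acts at least as fast as the lowest
analysed frequency). Reported values are weighted posterior medians with
central 68% intervals (inverse-CDF quantiles of the weighted samples); the
"mode" is the maximum-likelihood sample.

## Nested sampler

`fractalvoc.nested` is a compact static nested sampler: `nlive` live points,
geometric volume shrinkage `ln X_i = -i/nlive`, new points drawn by rejection
inside the enlarged bounding ellipsoid of the live set, with an adaptive
switch to constrained random walks when the ellipsoid becomes inefficient
(ridged or multimodal constraint regions, e.g. the ARMA `tau` direction).
The run stops when the remaining live-point contribution to `ln Z` falls
below `dlogz = 0.1` nats; the final live points are swept in. The error
estimate is `sqrt(H / nlive)` with `H` the information. Identical seeds give
identical results. Defaults: 400 live points for one-off fits; the bundled
study-scale scripts use 100 (spectral fits, where evidence gaps are hundreds
to tens of thousands of nats) and 200 (mixture fits); the analytic-toy
cross-check against quadrature uses 400.

## Population statistics

With per-recording index estimates `x_i` (posterior medians) and
uncertainties `sigma_i` (half the 68% interval width):

* inverse-variance weighted mean `mu`, its standard deviation `sigma_mu`,
  and the population scatter
  `sigma_pop = sum((x_i - mu)^2 sigma_i^-2) / sum(sigma_i^-2)`. As defined,
  `sigma_pop` is a squared-scatter quantity; `sqrt(sigma_pop)` is used
  wherever a standard deviation is required (KS reference, group curves).
* the consistency statistic
  `(1/(M-1)) sum((x_i - mu)^2 / (sigma_i^2 + sigma_mu^2))`, ~1 when scatter
  matches the stated uncertainties, >> 1 when there is intrinsic
  between-recording variation.
* a one-sample KS test of the `x_i` against `Normal(mu, sqrt(sigma_pop))`
  (plain test; no Lilliefors correction for sample-estimated parameters).
* a normal-mixture analysis `P(beta) = sum_i A_i N(mu_i, s_i) / sum_i A_i`
  with `N in {1..5}` components: means uniform on [0, 4] restricted to
  ascending order, standard deviations uniform on (0, 1], weights
  log-uniform on [1e-5, 1e5]; the component count is chosen by evidence.

The ordering restriction admits two conventions and they differ materially.
Renormalizing the ordered region to unit mass is exactly equivalent to
unrestricted exchangeable components, and then extra components are nearly
free under the 10-decade weight prior: measured at high precision
(2000 live points, `ln Z` errors ~0.08), evidences for N >= 2 on cleanly
bimodal data agree within ~0.7 nats and the maximum often sits at N > 2, so
mode counting by argmax is not meaningful. Keeping the independent uniform
densities and simply truncating to the ordered region — what imposing the
ordering as a constraint on top of independent priors yields — leaves an
N-mode model with prior mass 1/N!, i.e. an extra ~ln N penalty per added
mode. Under that convention (the default, `order_prior="truncated"`) mode
counting is decisive and single-mode preferences on unimodal data show the
familiar "moderate evidence" gaps of a few tenths of a nat to ~1 nat.
`order_prior="renormalized"` is available; the two differ only by the
`ln N!` constant in `ln Z`.

Species are grouped "musical" (any recording tagged song or call by the
recordist) vs "non-musical" (tags are input metadata, never inferred); the
group comparison reports per-species `Normal(mu, sqrt(sigma_pop))` curves
and the difference of group mean indices.

## Synthetic data: what it emulates and what it does not

All calibration rests on generators with known ground truth:

* **Fractal envelope signals** (220 Hz): one-sided Fourier coefficients with
  deterministic magnitudes set by `A f^-beta + gamma^2` plus additive
  per-bin measurement noise `Normal(0, sqrt(kappa A))` (clipped at zero
  power), independent uniform phases, inverse-transformed and shifted to
  nonnegativity (the shift only moves the discarded DC bin). The resulting
  periodogram is exactly the law the likelihood assumes, so posterior
  intervals from the matching fit are calibrated and the generating `kappa`
  is recoverable. Fixture default `kappa = 1e-5`: small enough that the
  additive noise stays an order of magnitude below the weakest in-band
  target power for `beta` up to 1.5, so the zero-power clip never engages
  and the stated noise model holds exactly.
* **Short-memory series**: the discrete ARMA(1,1) recursion
  `x_t = phi_d x_{t-1} + e_t + theta e_{t-1}` with `phi_d = phi^(dt/tau)`
  (autocorrelation decays by a factor `phi` per timescale `tau`; `phi = 0`
  or `tau = 0` is white noise), unit Gaussian innovations, 10 tau burn-in,
  shifted to nonnegativity. Its periodogram carries natural chi-squared
  scatter — deliberately not matched to the Gaussian likelihood, as with
  real data.
* **WAV fixtures** (44 kHz PCM16): a unit-modulus random-sign carrier
  modulated by the square root of a generated envelope, so squaring returns
  the envelope exactly; the envelope is band-limited-interpolated from
  220 Hz (a zero-order hold would leave Dirichlet images that alias back at
  the 1e-3 level); the first 5 s is a constant-power stand-in for the spoken
  announcement so that lead removal isolates exactly the generated envelope
  window; and the envelope target is pre-divided by the decimation chain's
  known in-band response. Each choice exists to keep the end-to-end chain
  consistent with the generator's stated law.
* **Index populations**: true indices from a normal mixture, plus
  per-recording noise with sigmas drawn within +-20% of a scale parameter
  (default 0.05, a typical posterior half-width).

What passing tests on these fixtures shows: the pipeline's bookkeeping is
exact, the sampler's evidences and intervals are correct and calibrated when
the model matches the data, discrimination between scale-free and
short-memory spectra is reliable at study-like sizes, and the population
machinery behaves as designed. What it does not show: real recordings do not
satisfy the Gaussian constant-variance noise model (their periodogram
scatter is multiplicative and heteroscedastic), so on real data the per-fit
intervals are expected to undercover — which is precisely what the
consistency statistic and KS test are there to detect at the population
level.

## Problem sizes and scale choices

The bundled statistical checks use: 1000 s envelope fixtures at 220 Hz
(9,991 spectrum bins in band), 20 replicates per model-selection direction,
10 seeds per index value for recovery/coverage (beta in {0.5, 1.0, 1.5}),
populations of M = 30 for mode counting with 20 replicates per shape, and
M = 1000 for the consistency-statistic calibration. These sizes give binomial
/ Monte-Carlo resolution comfortably inside the stated bands while keeping a
full run at desk scale. Model-selection and recovery fits use 100 live
points; mixture fits use 200; the expected `sqrt(H/nlive)` evidence errors
(a few tenths of a nat) are negligible against the evidence gaps being
measured in the spectral fits and small against the >= 1 nat mode-count gaps.

## Known limitations

* Single-ellipsoid bounding (with random-walk fallback) is cruder than full
  multi-ellipsoid decomposition; strongly multimodal posteriors cost extra
  likelihood calls rather than failing, but evidence errors there carry the
  random-walk approximation.
* The ARMA generator matches the model's low-frequency Lorentzian behaviour
  through `(phi, tau)` jointly rather than reproducing the printed spectrum
  bin-for-bin at arbitrary `tau`; its closed-form autocorrelation is the
  tested oracle.
* Coverage of the razor-thin posteriors produced by high signal-to-noise
  fixtures sits near the lower edge of the nominal band: at those widths the
  sampler's quantile noise is the dominant interval error.
* 24-bit WAV support follows scipy's reader; exotic encodings raise a format
  error rather than being converted.
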