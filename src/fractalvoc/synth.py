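"""Ground-truth synthetic inputs for the pipeline.

Real corpus recordings carry no known spectral index, so every calibration
claim in this package rests on these generators:

* power-level envelope signals at 220 Hz whose periodogram is exactly the
  fractal law A f^-beta + gamma^2 plus additive measurement noise of
  variance kappa*A — the data-generating process the fitted likelihood
  assumes, so intervals and the fitted kappa calibrate against truth;
* short-memory ARMA(1,1) series with a chosen correlation timescale tau
  (natural chi-squared periodogram scatter, deliberately unmatched);
* full 44 kHz WAV fixtures in which a white unit-modulus carrier is
  modulated by the square root of a generated envelope, so that
  square -> decimate recovers a signal with the target low-frequency
  spectrum;
* per-species populations of spectral-index measurements drawn from a normal
  mixture with per-recording noise.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import lfilter

from .errors import DomainError, InputError
from .models import ARMAParams, FractalParams
from .preprocess import PowerSignal, RecordingMeta

POWER_RATE = 220.0
WAV_RATE = 44_000.0

#: Default measurement-noise scale for generated fixtures. Small enough that
#: the additive per-bin noise sqrt(kappa A) stays an order of magnitude below
#: the weakest in-band target power (A 10^-beta at 10 Hz for beta up to 1.5),
#: so clipping at zero power never distorts the stated noise model.
DEFAULT_FIXTURE_KAPPA = 1e-5


@dataclass
class SynthSpec:
    """Recipe for one synthetic signal."""

    generator: str  # "fractal" | "arma"
    params: FractalParams | ARMAParams
    duration: float  # seconds
    rate: float  # Hz: 220 for power-level, 44000 for WAV fixtures
    seed: int

    def validate(self) -> None:
        if self.generator not in ("fractal", "arma"):
            raise DomainError(f"unknown generator {self.generator!r}")
        if self.duration <= 0:
            raise DomainError("duration must be positive")
        self.params.validate()


def _decimation_chain_gain(freqs: np.ndarray, factors=(10, 10, 2), in_rate: float = WAV_RATE) -> np.ndarray:
    """In-band gain of the zero-phase Chebyshev decimation chain.

    Each stage contributes the squared magnitude (forward-backward
    application) of its eighth-order 0.05 dB Chebyshev low-pass. The product
    deviates from unity by ~1% across 0.01-10 Hz — far above the small
    matched measurement noise — so fixture synthesis divides it out of the
    envelope target. Band-limited upsampling in :func:`gen_wav_fixture` is
    transparent (gain one, no images), so this is the whole response.
    """
    from scipy.signal import cheby1, freqz

    gain = np.ones_like(freqs)
    rate = in_rate
    for q in factors:
        b, a = cheby1(8, 0.05, 0.8 / q)
        _, h = freqz(b, a, worN=2 * np.pi * freqs / rate, fs=2 * np.pi)
        _, h0 = freqz(b, a, worN=[0.0])
        # zero-phase application squares the magnitude; stages are
        # normalized to unit DC gain
        gain *= np.abs(h) ** 2 / np.abs(h0[0]) ** 2
        rate /= q
    return gain


def _upsample_bandlimited(x: np.ndarray, factor: int) -> np.ndarray:
    """Exact band-limited interpolation by Fourier zero-padding."""
    n = x.size
    spec = np.fft.rfft(x)
    out = np.fft.irfft(spec, n * factor) * factor
    return out


def _fractal_envelope(
    params: FractalParams,
    n: int,
    rate: float,
    rng: np.random.Generator,
    compensation: np.ndarray | None = None,
) -> np.ndarray:
    """Spectral synthesis of a signal whose periodogram is the noisy target.

    One-sided Fourier coefficients get deterministic magnitudes from the
    target law plus additive measurement noise of variance kappa*A per bin
    (clipped at zero power), and independent uniform phases. The resulting
    periodogram, in the normalization of
    :func:`fractalvoc.preprocess.compute_spectrum`, is exactly
    A f^-beta + gamma^2 + Normal(0, sqrt(kappa A)) — the data-generating
    process the fitted likelihood assumes, so posterior intervals from the
    matching fit are calibrated and the generating kappa is recoverable.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    target = np.zeros_like(freqs)
    target[1:] = params.A * freqs[1:] ** (-params.beta) + params.gamma**2
    noisy = target + np.sqrt(params.kappa * params.A) * rng.standard_normal(freqs.size)
    noisy = np.maximum(noisy, 0.0)
    if compensation is not None:
        noisy = noisy / compensation
    phases = rng.uniform(0.0, 2 * np.pi, freqs.size)
    # |X_k|^2 = n P_k / 2 makes the one-sided periodogram equal P_k
    coeffs = np.sqrt(n * noisy / 2.0) * np.exp(1j * phases)
    coeffs[0] = 0.0
    if n % 2 == 0:
        # Nyquist coefficient must be real; its bin is not doubled
        coeffs[-1] = np.sqrt(n * noisy[-1]) * np.sign(np.cos(phases[-1]))
    return np.fft.irfft(coeffs, n)


def gen_fractal_power_signal(spec: SynthSpec) -> PowerSignal:
    """A 220 Hz envelope power signal following A f^-beta + gamma^2."""
    spec.validate()
    if spec.generator != "fractal":
        raise DomainError("spec.generator must be 'fractal'")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    x = _fractal_envelope(spec.params, n, spec.rate, rng)
    # constant shift only moves the (discarded) DC bin
    x -= min(x.min(), 0.0)
    return PowerSignal(x, spec.rate)


def arma_coefficients(params: ARMAParams, rate: float) -> tuple[float, float]:
    """Discrete ARMA(1,1) coefficients at sample interval 1/rate.

    The autoregressive coefficient is phi^(dt/tau): its autocorrelation decays
    by a factor phi over one model timescale tau, so the correlation time is
    tau / ln(1/phi). phi = 0 or tau = 0 degenerates to white noise. The
    moving-average coefficient is theta itself.
    """
    dt = 1.0 / rate
    if params.tau <= 0 or params.phi <= 0:
        phi_d = 0.0
    else:
        phi_d = float(params.phi ** (dt / params.tau))
    return phi_d, params.theta


def gen_arma_series(spec: SynthSpec, burn_in: float | None = None) -> PowerSignal:
    """Simulate x_t = phi_d x_{t-1} + e_t + theta_d e_{t-1} at 220 Hz.

    ``phi_d = phi^(dt/tau)`` (zero when phi = 0 or tau = 0) makes the
    autocorrelation decay by a factor phi per timescale tau — an
    exponentially short memory, the alternative to the scale-free fractal
    law. The series is shifted to nonnegativity so it can stand for a
    squared envelope.
    """
    spec.validate()
    if spec.generator != "arma":
        raise DomainError("spec.generator must be 'arma'")
    params: ARMAParams = spec.params
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    phi_d, theta_d = arma_coefficients(params, spec.rate)
    if burn_in is None:
        burn_in = 10 * params.tau
    n_burn = int(round(burn_in * spec.rate))
    eps = rng.standard_normal(n + n_burn)
    # ARMA(1,1) as an IIR filter: b = [1, theta_d], a = [1, -phi_d]
    x = lfilter([1.0, theta_d], [1.0, -phi_d], eps)[n_burn:]
    x = np.sqrt(params.A) * x
    x -= min(x.min(), 0.0)
    return PowerSignal(x, spec.rate)


def arma_acf(params: ARMAParams, rate: float, lag: int) -> float:
    """Closed-form autocorrelation of the simulated ARMA(1,1) at integer lag."""
    phi, theta = arma_coefficients(params, rate)
    if lag == 0:
        return 1.0
    denom = 1 + 2 * phi * theta + theta**2
    rho1 = (1 + phi * theta) * (phi + theta) / denom
    return float(rho1 * phi ** (lag - 1))


def gen_wav_fixture(
    spec: SynthSpec,
    out_path: str,
    species: str = "synthetic",
    tag: str = "untagged",
    recording_id: str | None = None,
) -> RecordingMeta:
    """Write a 44 kHz PCM WAV whose envelope follows the target spectrum.

    A white random-sign (+-1) carrier is modulated by the square root of a
    generated envelope, computed at 220 Hz and band-limited-interpolated up
    to 44 kHz. The unit-modulus carrier makes the squared waveform equal the
    envelope exactly, and the fractal envelope target is pre-divided by the
    decimation chain's known in-band response, so the square -> decimate
    chain recovers a power signal following the target spectrum over
    0.01-10 Hz to within the matched measurement noise.

    The first ``lead`` seconds hold a constant-power stand-in for the source
    library's spoken announcement, and the target-law envelope spans exactly
    the remaining duration - lead seconds, so that after the standard lead
    removal the analysis window coincides with the generated envelope's full
    window (segmenting a longer envelope would reintroduce periodogram
    scatter the noise model does not describe). Fixtures must be at least
    105 s long to survive lead removal plus the 100 s minimum-length rule.
    """
    spec.validate()
    if spec.rate != WAV_RATE:
        raise DomainError(f"WAV fixtures are generated at {WAV_RATE:g} Hz")
    if spec.duration < 105.0:
        raise DomainError("WAV fixtures need duration >= 105 s to stay eligible")
    lead = 5.0
    rng = np.random.default_rng(spec.seed)
    env_rate = POWER_RATE
    factor = int(WAV_RATE / env_rate)
    env_spec = SynthSpec(
        spec.generator, spec.params, spec.duration - lead, env_rate, spec.seed
    )
    if spec.generator == "fractal":
        n_env = int(round(env_spec.duration * env_rate))
        env_freqs = np.fft.rfftfreq(n_env, d=1.0 / env_rate)
        comp = _decimation_chain_gain(env_freqs) ** 2  # power-spectrum gain
        env = _fractal_envelope(
            spec.params, n_env, env_rate, np.random.default_rng(spec.seed), comp
        )
    else:
        env = gen_arma_series(env_spec).samples
    lead_env = np.full(int(round(lead * env_rate)), max(abs(env.mean()), 1e-12))
    # band-limited interpolation is transparent to the decimation chain (no
    # spectral images); shifting to nonnegativity after interpolation keeps
    # every sample exact and moves only the discarded DC bin
    env = _upsample_bandlimited(env, factor)
    env -= min(env.min(), 0.0)
    lead_up = np.repeat(lead_env, factor)
    env = np.concatenate([lead_up, env])
    carrier = rng.integers(0, 2, env.size) * 2.0 - 1.0
    wave = np.sqrt(env) * carrier
    peak = np.max(np.abs(wave)) or 1.0
    pcm = np.round(wave / peak * 0.9 * 32767).astype(np.int16)
    try:
        wavfile.write(out_path, int(WAV_RATE), pcm)
    except OSError as exc:
        raise InputError(f"cannot write WAV to {out_path}: {exc}") from exc
    return RecordingMeta(
        recording_id=recording_id or os.path.splitext(os.path.basename(out_path))[0],
        species=species,
        tag=tag,
        duration=pcm.size / WAV_RATE,
        sample_rate=WAV_RATE,
        source_path=out_path,
    )


def gen_beta_population(model, M: int, sigma_scale: float, seed: int):
    """Draw a per-species population of spectral-index measurements.

    True indices come from the normal mixture ``model``; each measurement adds
    noise Normal(0, sigma_i) with sigma_i drawn uniformly within +-20% of
    ``sigma_scale`` (mimicking recording-to-recording variation in posterior
    widths).
    """
    from .population import MeasurementSet

    if M < 1:
        raise DomainError("M must be >= 1")
    if sigma_scale <= 0:
        raise DomainError("sigma_scale must be positive")
    means = np.asarray(model.means, dtype=float)
    sds = np.asarray(model.sds, dtype=float)
    weights = np.asarray(model.weights, dtype=float)
    if means.size == 0 or np.any(sds <= 0) or np.any(weights <= 0):
        raise DomainError("invalid mixture model")
    rng = np.random.default_rng(seed)
    comp = rng.choice(means.size, size=M, p=weights / weights.sum())
    truth = rng.normal(means[comp], sds[comp])
    sigmas = sigma_scale * rng.uniform(0.8, 1.2, size=M)
    values = truth + rng.normal(0.0, sigmas)
    return MeasurementSet(values=values, sigmas=sigmas)
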