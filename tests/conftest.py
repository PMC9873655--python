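import numpy as np
import pytest

import fractalvoc as fv


@pytest.fixture(scope="session")
def small_fractal_spectrum():
    """200 s power-level fractal fixture (beta=1, gamma=0) and its spectrum."""
    spec = fv.SynthSpec(
        "fractal",
        fv.FractalParams(A=1.0, beta=1.0, gamma=0.0, kappa=fv.synth.DEFAULT_FIXTURE_KAPPA),
        200.0,
        220.0,
        seed=11,
    )
    sig = fv.gen_fractal_power_signal(spec)
    return fv.band_select(fv.compute_spectrum(sig), 0.01, 10.0)


@pytest.fixture(scope="session")
def small_fractal_fit(small_fractal_spectrum):
    return fv.fit_model(
        small_fractal_spectrum,
        "fractal",
        fv.SamplerSettings(nlive=100, seed=7),
        recording_id="fix-200s",
    )


def write_wav(path, data, rate=44000):
    from scipy.io import wavfile

    wavfile.write(str(path), rate, data)
    return str(path)


@pytest.fixture
def silence_wav(tmp_path):
    return write_wav(tmp_path / "silence.wav", np.zeros(44000, dtype=np.int16))


@pytest.fixture
def stereo_wav(tmp_path):
    rng = np.random.default_rng(0)
    c1 = rng.integers(-1000, 1000, 44000).astype(np.int16)
    c2 = rng.integers(-1000, 1000, 44000).astype(np.int16)
    path = write_wav(tmp_path / "stereo.wav", np.column_stack([c1, c2]))
    return path, c1, c2
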