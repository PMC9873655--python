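"""Build a synthetic recording and run the audio-to-spectrum chain.

Generates a 110 s WAV whose envelope follows a 1/f law (beta = 1), then
applies the standard chain: strip the 5 s lead, square, decimate
44 kHz -> 220 Hz, Fourier transform, keep 0.01-10 Hz. Prints the band and a
log-log slope, which should sit near -beta.
"""
import tempfile

import numpy as np

import fractalvoc as fv

with tempfile.TemporaryDirectory() as tmp:
    path = f"{tmp}/fixture.wav"
    spec = fv.SynthSpec(
        generator="fractal",
        params=fv.FractalParams(A=1.0, beta=1.0, gamma=0.0, kappa=1e-5),
        duration=110.0,
        rate=44_000.0,
        seed=1,
    )
    meta = fv.gen_wav_fixture(spec, path, species="synthetic", tag="song")
    print(f"wrote {meta.duration:.0f} s fixture at {meta.sample_rate:.0f} Hz")

    signal, _ = fv.load_recording(path)
    spectrum = fv.preprocess_recording(signal)

print(f"spectrum bins: {len(spectrum)}")
print(f"band: {spectrum.frequencies.min():.3f} - {spectrum.frequencies.max():.1f} Hz")
slope = np.polyfit(np.log(spectrum.frequencies), np.log(spectrum.powers), 1)[0]
print(f"log-log slope: {slope:.3f}  (generating index beta = 1, so expect ~ -1)")
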