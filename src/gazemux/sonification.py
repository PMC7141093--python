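"""EEG alpha-rhythm sonification.

Turns the alpha-band (8–13 Hz) power envelope of a raw single-channel EEG
trace into audio, two ways, both on a 220 Hz carrier (the note a):

* frequency modulation — the carrier pitch rises with alpha power
  (instantaneous frequency = carrier + deviation · envelope);
* amplitude modulation — the carrier loudness follows alpha power.

The audio is written as mono 16-bit PCM WAV at 44.1 kHz so it can be
muxed as an ordinary audio track next to the gaze subtitle tracks.

Pipeline: zero-phase Butterworth band-pass → squared signal → moving
average over ``window_s`` → resample to the audio rate → normalize so the
trace maximum maps to 1 (the pre-normalization peak is kept on the
envelope for absolute-power uses; traces with no band content at all map
to silence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGTrace",
    "PowerEnvelope",
    "alpha_power",
    "fm_synthesize",
    "am_synthesize",
    "write_wav",
    "read_eeg_text",
    "DEFAULT_CARRIER_HZ",
    "DEFAULT_DEVIATION_HZ",
    "ALPHA_BAND_HZ",
]

DEFAULT_CARRIER_HZ = 220.0
DEFAULT_DEVIATION_HZ = 110.0
ALPHA_BAND_HZ = (8.0, 13.0)
AUDIO_FS = 44100

# band power below this fraction of the squared input peak is numerical
# residue of the filter, not signal — mapped to silence
_SILENCE_FLOOR = 1e-12


@dataclass
class EEGTrace:
    """Uniformly sampled single-channel EEG (microvolts)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("EEG trace must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class PowerEnvelope:
    """Alpha power per audio sample, normalized to [0, 1].

    ``peak`` is the pre-normalization maximum (µV²), so ``values * peak``
    recovers the absolute smoothed band power.
    """

    values: np.ndarray
    audio_fs: float
    peak: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def raw(self) -> np.ndarray:
        return self.values * self.peak


def alpha_power(
    eeg: EEGTrace,
    band: tuple[float, float] = ALPHA_BAND_HZ,
    window_s: float = 0.25,
    audio_fs: float = AUDIO_FS,
) -> PowerEnvelope:
    """Smoothed alpha-band power of an EEG trace, resampled to the audio rate.

    The band-pass is a zero-phase 4th-order Butterworth (applied
    forward-backward).  Raises if the EEG sampling rate cannot represent
    the band (``fs <= 2 * band_high``).
    """
    lo, hi = band
    if eeg.fs <= 2 * hi:
        raise ValueError(
            f"EEG sampling rate {eeg.fs} Hz aliases the {lo}-{hi} Hz band; need fs > {2 * hi}"
        )
    x = eeg.samples
    n_out = max(1, round(eeg.duration * audio_fs))
    peak_in = float(np.max(x * x)) if x.size else 0.0
    if peak_in == 0.0:
        return PowerEnvelope(np.zeros(n_out), audio_fs, peak=0.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=eeg.fs, output="sos")
    padlen = min(x.size - 1, 3 * 2 * len(sos))
    banded = sps.sosfiltfilt(sos, x, padlen=padlen)
    power = banded * banded
    win = max(1, round(window_s * eeg.fs))
    kernel = np.ones(win) / win
    smoothed = np.convolve(power, kernel, mode="same")
    t_in = np.arange(x.size) / eeg.fs
    t_out = np.arange(n_out) / audio_fs
    env = np.interp(t_out, t_in, smoothed)
    env = np.maximum(env, 0.0)
    peak = float(env.max())
    if peak <= _SILENCE_FLOOR * peak_in:
        return PowerEnvelope(np.zeros(n_out), audio_fs, peak=0.0)
    return PowerEnvelope(env / peak, audio_fs, peak=peak)


def fm_synthesize(
    env: PowerEnvelope,
    carrier: float = DEFAULT_CARRIER_HZ,
    deviation: float = DEFAULT_DEVIATION_HZ,
) -> np.ndarray:
    """Frequency-modulated tone: pitch = carrier + deviation · envelope.

    Phase-integrated so the instantaneous frequency tracks the envelope
    continuously; output amplitude is constant (unit peak).
    """
    if env.audio_fs <= 2 * (carrier + deviation):
        raise ValueError(
            f"audio rate {env.audio_fs} Hz violates Nyquist for "
            f"{carrier} + {deviation} Hz"
        )
    inst_freq = carrier + deviation * env.values
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / env.audio_fs
    return np.sin(phase)


def am_synthesize(env: PowerEnvelope, carrier: float = DEFAULT_CARRIER_HZ) -> np.ndarray:
    """Amplitude-modulated tone: louder means stronger alpha power."""
    if env.audio_fs <= 2 * carrier:
        raise ValueError(f"audio rate {env.audio_fs} Hz violates Nyquist for {carrier} Hz")
    n = np.arange(env.values.size)
    return env.values * np.sin(2.0 * np.pi * carrier * n / env.audio_fs)


def write_wav(path, samples: np.ndarray, fs: float = AUDIO_FS, gain: float = 0.9) -> None:
    """Write float samples in [-1, 1] as mono 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(samples * gain, -1.0, 1.0)
    wavfile.write(path, int(fs), (pcm * 32767).astype(np.int16))


def read_eeg_text(path, fs: float) -> EEGTrace:
    """Read an EEG trace from delimited text, one sample value per line."""
    values = np.loadtxt(path, dtype=float, ndmin=1)
    return EEGTrace(values, fs)
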