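"""Calibrated ambient-noise spectra from duty-cycled hydrophone recordings.

The recorder chain is hydrophone (receiving sensitivity in dB re V/µPa) →
preamp gain (dB) → ADC (full-scale voltage, fixed bit depth). Converting raw
ADC counts back to acoustic pressure in µPa and estimating a one-sided Welch
power spectral density gives the noise level NL (dB re 1 µPa²/Hz) entering
the audible-area budget SNR = SL − TL − NL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal


@dataclass(frozen=True)
class CalibrationSpec:
    """End-to-end recorder calibration.

    Parameters
    ----------
    sensitivity_db : hydrophone receiving sensitivity, dB re 1 V/µPa
        (negative by convention; −165 for an HTI-96-min).
    gain_db : preamp gain in dB.
    full_scale_volts : ADC full-scale voltage (peak). 5 V default for
        AURAL-class recorders.
    bit_depth : ADC resolution in bits (16 default).
    """

    sensitivity_db: float = -165.0
    gain_db: float = 16.0
    full_scale_volts: float = 5.0
    bit_depth: int = 16

    def __post_init__(self):
        if self.sensitivity_db >= 0:
            raise ValueError("hydrophone sensitivity must be negative (dB re V/µPa)")
        if self.gain_db < 0:
            raise ValueError("gain must be non-negative")

    @property
    def counts_per_micropascal(self) -> float:
        volts_per_upa = 10.0 ** (self.sensitivity_db / 20.0) * 10.0 ** (self.gain_db / 20.0)
        counts_per_volt = 2.0 ** (self.bit_depth - 1) / self.full_scale_volts
        return volts_per_upa * counts_per_volt


def counts_to_pressure(counts: np.ndarray, calib: CalibrationSpec) -> np.ndarray:
    """Convert raw ADC counts to acoustic pressure in µPa."""
    if calib is None:
        raise ValueError("calibration required")
    return np.asarray(counts, dtype=float) / calib.counts_per_micropascal


def pressure_to_counts(pressure_upa: np.ndarray, calib: CalibrationSpec) -> np.ndarray:
    """Inverse of :func:`counts_to_pressure` (float counts, not quantized)."""
    return np.asarray(pressure_upa, dtype=float) * calib.counts_per_micropascal


@dataclass
class PSDRecord:
    """One-sided power spectral density of a single recording.

    ``psd_db`` is in dB re 1 µPa²/Hz on ascending frequency bins spaced
    fs/nfft apart.
    """

    file_id: str
    frequencies_hz: np.ndarray
    psd_db: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.ndim != 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency bins must be 1-D ascending")
        self.frequencies_hz = f
        self.psd_db = np.asarray(self.psd_db, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"file": self.file_id, "frequency_hz": self.frequencies_hz, "psd_db": self.psd_db}
        )


def welch_psd(
    pressure_upa: np.ndarray,
    fs: float,
    *,
    file_id: str = "",
    segment_minutes: float = 8.0,
    nfft: int = 65536,
    window: str = "hamming",
    overlap: float = 0.5,
) -> PSDRecord:
    """Welch PSD of the first ``segment_minutes`` of a recording.

    Hamming window, 50% overlap, density scaling: integrating the returned
    (linear) density over frequency recovers the signal variance. Recordings
    shorter than the analysis segment are used whole (with a warning); nfft
    is shrunk to the available length if needed.
    """
    x = np.asarray(pressure_upa, dtype=float)
    n_seg = int(round(segment_minutes * 60.0 * fs))
    if x.size < n_seg:
        import warnings

        warnings.warn(
            f"recording shorter than {segment_minutes} min; using all {x.size} samples",
            stacklevel=2,
        )
    else:
        x = x[:n_seg]
    nperseg = min(nfft, x.size)
    freqs, pxx = signal.welch(
        x,
        fs=fs,
        window=window,
        nperseg=nperseg,
        nfft=max(nfft, nperseg),
        noverlap=int(overlap * nperseg),
        detrend=False,
        scaling="density",
    )
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(pxx)
    return PSDRecord(file_id=file_id, frequencies_hz=freqs, psd_db=psd_db)


def noise_at_frequency(
    psd: PSDRecord, f_hz: float, *, band_bins: int = 0
) -> float:
    """Noise level NL (dB) at a frequency.

    Default is the single nearest bin (ties break to the lower bin). With
    ``band_bins`` > 0 the mean linear density over ±band_bins bins is
    returned instead.
    """
    f = psd.frequencies_hz
    if not (f[0] <= f_hz <= f[-1]):
        raise ValueError(f"frequency {f_hz} Hz outside PSD range [{f[0]}, {f[-1]}]")
    dist = np.abs(f - f_hz)
    # ties to the lower bin: argmin returns the first (lower) of equal distances
    idx = int(np.argmin(dist))
    if band_bins <= 0:
        return float(psd.psd_db[idx])
    lo = max(0, idx - band_bins)
    hi = min(f.size, idx + band_bins + 1)
    return float(10.0 * np.log10(np.mean(10.0 ** (psd.psd_db[lo:hi] / 10.0))))


def received_level_db(pressure_upa: np.ndarray) -> float:
    """Broadband RMS received level in dB re 1 µPa."""
    rms = np.sqrt(np.mean(np.square(np.asarray(pressure_upa, dtype=float))))
    return float(20.0 * np.log10(rms))
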