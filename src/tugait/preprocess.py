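"""Axis fusion, low-pass filtering and power spectra.

The waist sensor's orientation is not controlled, so all analysis runs on
the Euclidean magnitude s(t) = sqrt(x^2 + y^2 + z^2), which is invariant
under any fixed rotation of the device.  Spectra use a per-sample
normalized DFT, S(w) = |F(s)/n|^2, so that peak powers measure squared
amplitude rather than growing with trial duration; this keeps spectral
features comparable across subjects whose trials differ in length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, ParameterError, ValidationError
from .io import TriaxialRecording

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 100.0
DEFAULT_ORDER = 4


@dataclass
class MagnitudeSignal:
    """One-dimensional orientation-independent acceleration signal."""

    values: np.ndarray
    rate: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise DegenerateInputError("signal must contain at least 2 samples")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate


@dataclass
class PowerSpectrum:
    """One-sided power spectrum with frequencies in Hz (DC first)."""

    freqs: np.ndarray
    power: np.ndarray
    demeaned: bool = True

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.freqs) != len(self.power):
            raise ValidationError("freqs and power must have equal length")
        if self.freqs[0] != 0.0:
            raise ValidationError("spectrum must start at DC (0 Hz)")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")


def fuse_axes(rec: TriaxialRecording) -> MagnitudeSignal:
    """Fuse the three axes into the orientation-independent magnitude.

    s[i] = sqrt(x[i]^2 + y[i]^2 + z[i]^2).  The output is invariant under
    any fixed rotation, axis permutation or sign flip applied to (x, y, z).
    """
    values = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    return MagnitudeSignal(values=values, rate=rec.rate)


def lowpass_filter(
    sig: MagnitudeSignal,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> MagnitudeSignal:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so trial boundaries are not
    phase-shifted.  A cutoff at or above Nyquist degenerates to the
    identity: with the study's 200 Hz acquisition the default 100 Hz
    anti-aliasing cutoff is exactly Nyquist, so the digital filter passes
    the signal through unchanged (a notice is logged).
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if order < 1:
        raise ParameterError(f"filter order must be >= 1, got {order}")
    nyquist = sig.rate / 2.0
    if cutoff >= nyquist:
        log.info(
            "low-pass cutoff %.3g Hz >= Nyquist %.3g Hz: identity pass-through",
            cutoff,
            nyquist,
        )
        return MagnitudeSignal(values=sig.values.copy(), rate=sig.rate)
    sos = sps.butter(order, cutoff, btype="low", fs=sig.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.values)
    return MagnitudeSignal(values=filtered, rate=sig.rate)


def power_spectrum(sig: MagnitudeSignal, demean: bool = True) -> PowerSpectrum:
    """One-sided power spectrum S(w) = |F(s)/n|^2.

    ``demean`` (default) subtracts the signal mean first so the static
    gravity component does not occupy the DC bin and dominate peak
    searches.  An all-constant demeaned signal yields an all-zero
    spectrum, which is valid.
    """
    v = sig.values
    if demean:
        v = v - v.mean()
    n = len(v)
    spec = np.fft.rfft(v) / n
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sig.rate)
    return PowerSpectrum(freqs=freqs, power=power, demeaned=demean)
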