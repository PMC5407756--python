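"""Spectral and distance features for faller discrimination.

Ten features per signal source:

* PSE — power spectral entropy, -sum_w S(w) * log(S(w) + eps), natural
  log, eps = 0.001 guarding log(0).  Computed on the spectrum as given
  (no renormalization): it deliberately mixes spectral shape with the
  amount of acceleration energy in the signal.
* PSPF 1-3 — frequencies of the three highest spectral peaks (gait
  harmonics); successive peaks exclude a +-excl_hz band around the peaks
  already found so that adjacent bins of one lobe are not re-reported.
* PSP 1-3 — spectral power at those frequencies.
* WPSP 1-3 — frequency-weighted peak power, WPSP_i = PSPF_i * PSP_i.

These are extracted from four sources — the whole signal (the three trials
concatenated, "s") and the individual trials TUG ("t"), TUG-M ("m"),
TUG-C ("c") — giving the 40-element per-subject feature vector.  Distance
features |f_j^a - f_j^b| between pairs of sources quantify how a dual task
reshapes the gait spectrum.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateSpectrumError, ParameterError
from .preprocess import MagnitudeSignal, PowerSpectrum, power_spectrum
from .segmentation import SegmentationResult, extract_segment

DEFAULT_EPS = 1e-3
DEFAULT_EXCL_HZ = 0.25
N_PEAKS = 3

#: canonical source order: whole signal, then the three trials
SOURCES = ("s", "t", "m", "c")
SOURCE_SIGNALS = {"s": "whole", "t": "TUG", "m": "TUG-M", "c": "TUG-C"}

#: the ten per-source scalar features, in canonical order
SCALAR_FEATURES = (
    ("pse", None),
    ("pspf", 1),
    ("pspf", 2),
    ("pspf", 3),
    ("psp", 1),
    ("psp", 2),
    ("psp", 3),
    ("wpsp", 1),
    ("wpsp", 2),
    ("wpsp", 3),
)

#: the five trial-comparison pairs plus (m, c)
DEFAULT_PAIRS = (("s", "t"), ("s", "m"), ("s", "c"), ("t", "m"), ("t", "c"), ("m", "c"))
LITERAL_PAIRS = DEFAULT_PAIRS[:5]


def feature_name(family: str, index: int | None, source: str) -> str:
    """Serialized feature name, e.g. ``pse__c`` or ``wpsp_2_c``."""
    return f"{family}_{index if index is not None else ''}_{source}"


def vector_names() -> list[str]:
    """Canonical 40-entry name list (source-major, feature-minor)."""
    return [feature_name(fam, idx, src) for src in SOURCES for fam, idx in SCALAR_FEATURES]


def spectral_entropy(spec: PowerSpectrum, eps: float = DEFAULT_EPS) -> float:
    """Power spectral entropy -sum_w S(w) * log(S(w) + eps).

    The DC bin is excluded when the spectrum was demeaned (it is zero by
    construction there).  Zero-power bins contribute exactly 0 under the
    0 * log(eps) = 0 convention implemented by plain multiplication.
    """
    if eps <= 0:
        raise ParameterError(f"eps must be positive, got {eps}")
    power = spec.power[1:] if spec.demeaned else spec.power
    return float(-np.sum(power * np.log(power + eps)))


def peak_features(
    spec: PowerSpectrum,
    n_peaks: int = N_PEAKS,
    excl_hz: float = DEFAULT_EXCL_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top spectral peaks with an exclusion band around each.

    Returns (pspf, psp, wpsp), each of length ``n_peaks``: the i-th peak
    frequency is the argmax of S over bins farther than ``excl_hz`` from
    every previously found peak (DC excluded for demeaned spectra); psp is
    the power at that frequency and wpsp their product.  Ties break toward
    the lower frequency.
    """
    if excl_hz < 0:
        raise ParameterError(f"excl_hz must be non-negative, got {excl_hz}")
    freqs, power = spec.freqs, spec.power
    admissible = np.ones(len(freqs), dtype=bool)
    if spec.demeaned:
        admissible[0] = False

    pspf = np.empty(n_peaks)
    psp = np.empty(n_peaks)
    for i in range(n_peaks):
        if not admissible.any():
            raise DegenerateSpectrumError(
                f"fewer than {n_peaks} admissible bins for peak search"
            )
        masked = np.where(admissible, power, -np.inf)
        j = int(np.argmax(masked))  # argmax takes the first max: lower-frequency tie-break
        pspf[i] = freqs[j]
        psp[i] = power[j]
        admissible &= np.abs(freqs - freqs[j]) > excl_hz
    return pspf, psp, pspf * psp


def spectral_features(
    sig: MagnitudeSignal,
    eps: float = DEFAULT_EPS,
    excl_hz: float = DEFAULT_EXCL_HZ,
    demean: bool = True,
) -> dict[str, float]:
    """The ten spectral features of one signal, keyed by (family, index)."""
    spec = power_spectrum(sig, demean=demean)
    pse = spectral_entropy(spec, eps=eps)
    pspf, psp, wpsp = peak_features(spec, excl_hz=excl_hz)
    out = {("pse", None): pse}
    for i in range(N_PEAKS):
        out[("pspf", i + 1)] = float(pspf[i])
        out[("psp", i + 1)] = float(psp[i])
        out[("wpsp", i + 1)] = float(wpsp[i])
    return out


def extract_feature_vector(
    sig: MagnitudeSignal,
    seg: SegmentationResult,
    eps: float = DEFAULT_EPS,
    excl_hz: float = DEFAULT_EXCL_HZ,
    demean: bool = True,
) -> dict[str, float]:
    """The 40-element per-subject feature vector.

    Ten spectral features from each of the four sources: the concatenated
    trials ("s") and the individual TUG / TUG-M / TUG-C trials.  Keys
    follow :func:`vector_names` order.
    """
    out: dict[str, float] = {}
    for src in SOURCES:
        source_sig = extract_segment(sig, seg, SOURCE_SIGNALS[src])
        try:
            feats = spectral_features(source_sig, eps=eps, excl_hz=excl_hz, demean=demean)
        except (DegenerateSpectrumError, ParameterError) as exc:
            raise type(exc)(f"source {src!r} ({SOURCE_SIGNALS[src]}): {exc}") from exc
        for fam, idx in SCALAR_FEATURES:
            out[feature_name(fam, idx, src)] = feats[(fam, idx)]
    return out


def distance_features(
    fv: dict[str, float],
    pairs: tuple = DEFAULT_PAIRS,
) -> dict[str, float]:
    """Absolute per-feature differences between pairs of sources.

    For every scalar feature j and pair (a, b), d_j(a, b) = |f_j^a -
    f_j^b|.  The default pair set is the five comparisons of the whole
    signal and the first trial against the dual-task trials, plus (m, c).
    Names read ``d_<family>[_<index>]_<a>_<b>``, e.g. ``d_pse_s_c`` or
    ``d_wpsp_1_m_c``; the family-level distances quoted in group
    comparisons are the first-component ones (index 1).
    """
    for pair in pairs:
        if tuple(pair) not in DEFAULT_PAIRS:
            raise ParameterError(f"unknown source pair {pair!r}")
    out: dict[str, float] = {}
    for a, b in pairs:
        for fam, idx in SCALAR_FEATURES:
            tag = f"{fam}_{idx}" if idx is not None else fam
            key = f"d_{tag}_{a}_{b}"
            out[key] = abs(fv[feature_name(fam, idx, a)] - fv[feature_name(fam, idx, b)])
    return out
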