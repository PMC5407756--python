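import numpy as np
import pytest

from tugait import (
    MagnitudeSignal,
    PowerSpectrum,
    apply_manual_segments,
    distance_features,
    extract_feature_vector,
    peak_features,
    power_spectrum,
    spectral_entropy,
    vector_names,
)
from tugait.errors import DegenerateSpectrumError, ParameterError
from tugait.features import DEFAULT_PAIRS, LITERAL_PAIRS

EPS = 1e-3


def _spectrum(power, df_hz=1.0, demeaned=True):
    power = np.asarray(power, dtype=float)
    return PowerSpectrum(freqs=np.arange(len(power)) * df_hz, power=power, demeaned=demeaned)


def greedy_peak_oracle(freqs, power, n_peaks=3, excl_hz=0.25, skip_dc=True):
    """Sort-and-exclude oracle: walk bins by decreasing power (lower
    frequency first on ties), keep those outside every chosen exclusion zone."""
    order = sorted(range(len(freqs)), key=lambda j: (-power[j], freqs[j]))
    chosen = []
    for j in order:
        if skip_dc and freqs[j] == 0.0:
            continue
        if all(abs(freqs[j] - freqs[c]) > excl_hz for c in chosen):
            chosen.append(j)
        if len(chosen) == n_peaks:
            break
    return [freqs[c] for c in chosen], [power[c] for c in chosen]


class TestSpectralEntropy:
    def test_all_zero_spectrum_gives_zero(self):
        assert spectral_entropy(_spectrum([0, 0, 0, 0])) == 0.0

    def test_single_unit_bin_closed_form(self):
        spec = _spectrum([0, 1, 0, 0])
        assert spectral_entropy(spec, eps=EPS) == pytest.approx(-np.log(1.001), abs=1e-15)

    def test_two_unit_bins_additivity(self):
        spec = _spectrum([0, 1, 0, 1])
        assert spectral_entropy(spec, eps=EPS) == pytest.approx(2 * -np.log(1.001), abs=1e-15)

    def test_dc_bin_excluded_only_when_demeaned(self):
        with_dc = _spectrum([5, 1, 0, 0], demeaned=False)
        without_dc = _spectrum([5, 1, 0, 0], demeaned=True)
        expected_dc_term = -5 * np.log(5 + EPS)
        diff = spectral_entropy(with_dc) - spectral_entropy(without_dc)
        assert diff == pytest.approx(expected_dc_term)


class TestPeakFeatures:
    def test_isolated_bins_direct_evaluation(self):
        power = np.zeros(16)
        power[2], power[5], power[11] = 9.0, 4.0, 1.0
        pspf, psp, wpsp = peak_features(_spectrum(power))
        assert list(pspf) == [2.0, 5.0, 11.0]
        assert list(psp) == [9.0, 4.0, 1.0]
        assert list(wpsp) == [18.0, 20.0, 11.0]

    def test_bin_aligned_sinusoid_pair(self):
        t = np.arange(400) / 200.0
        values = 2.0 * np.sin(2 * np.pi * 1.5 * t) + 1.0 * np.sin(2 * np.pi * 4.0 * t)
        spec = power_spectrum(MagnitudeSignal(values, rate=200.0))
        pspf, psp, _ = peak_features(spec)
        assert pspf[0] == pytest.approx(1.5)
        assert pspf[1] == pytest.approx(4.0)
        assert psp[0] / psp[1] == pytest.approx(4.0, rel=1e-6)

    def test_exact_tie_breaks_to_lower_frequency(self):
        power = np.zeros(10)
        power[3] = power[7] = 2.0
        power[5] = 1.0
        pspf, _, _ = peak_features(_spectrum(power))
        assert pspf[0] == 3.0

    def test_exclusion_band_suppresses_adjacent_bins(self):
        # 0.1 Hz bin spacing: the two bins flanking the 2 Hz peak are
        # inside +-0.25 Hz and must not be returned as later peaks.
        power = np.zeros(100)
        power[20] = 10.0
        power[19] = power[21] = 9.0  # shoulders of the same lobe
        power[40] = 5.0
        power[60] = 3.0
        pspf, _, _ = peak_features(_spectrum(power, df_hz=0.1))
        assert list(pspf) == pytest.approx([2.0, 4.0, 6.0])

    def test_too_few_admissible_bins_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            peak_features(_spectrum([0.0, 1.0, 2.0]), excl_hz=5.0)

    @pytest.mark.parametrize("case", range(200))
    def test_matches_greedy_sort_and_exclude_oracle(self, case):
        rng = np.random.default_rng(900 + case)
        n = int(rng.integers(8, 129))
        df = float(rng.uniform(0.05, 0.5))
        power = rng.exponential(1.0, size=n)
        spec = _spectrum(power, df_hz=df)
        pspf, psp, _ = peak_features(spec)
        of, op = greedy_peak_oracle(spec.freqs, power)
        assert list(pspf) == pytest.approx(of)
        assert list(psp) == pytest.approx(op)


def _segmented_signal(seed=0, repeat_burst=False):
    """Signal with 3 trials at known second boundaries (manual segmentation)."""
    rng = np.random.default_rng(seed)
    rate = 200.0

    def burst(n, amp=0.3):
        t = np.arange(n) / rate
        return (
            1.0
            + amp * np.sin(2 * np.pi * 1.4 * t)
            + 0.1 * np.sin(2 * np.pi * 2.8 * t)
            + rng.normal(0, 0.05, n)
        )

    rest = lambda n: 1.0 + rng.normal(0, 0.01, n)
    b1 = burst(2000)
    b2 = b1.copy() if repeat_burst else burst(2200)
    b3 = b1.copy() if repeat_burst else burst(2800)
    values = np.concatenate([b1, rest(1000), b2, rest(1000), b3])
    sig = MagnitudeSignal(values, rate=rate)
    n1, n2 = len(b1) / rate, len(b2) / rate
    intervals = [(0, n1), (n1 + 5, n1 + 5 + n2), (n1 + 10 + n2, len(values) / rate)]
    return sig, apply_manual_segments(sig, intervals)


class TestFeatureVector:
    def test_has_exactly_40_canonically_named_entries(self):
        sig, seg = _segmented_signal()
        fv = extract_feature_vector(sig, seg)
        assert list(fv) == vector_names()
        assert len(fv) == 40

    def test_identical_trials_give_identical_trial_features(self):
        sig, seg = _segmented_signal(repeat_burst=True)
        fv = extract_feature_vector(sig, seg)
        for fam_idx in ("pse_", "pspf_1", "pspf_2", "psp_1", "psp_2", "wpsp_1"):
            t, m, c = (fv[f"{fam_idx}_t"], fv[f"{fam_idx}_m"], fv[f"{fam_idx}_c"])
            assert t == pytest.approx(m, abs=1e-12)
            assert t == pytest.approx(c, abs=1e-12)

    def test_wpsp_is_product_of_pspf_and_psp(self):
        sig, seg = _segmented_signal()
        fv = extract_feature_vector(sig, seg)
        for src in "stmc":
            for i in (1, 2, 3):
                assert fv[f"wpsp_{i}_{src}"] == fv[f"pspf_{i}_{src}"] * fv[f"psp_{i}_{src}"]

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_amplitude_scaling_covariance(self, scale):
        sig, seg = _segmented_signal()
        scaled = MagnitudeSignal(sig.values * scale, rate=sig.rate)
        fv = extract_feature_vector(sig, seg)
        fv_scaled = extract_feature_vector(scaled, seg)
        for src in "stmc":
            for i in (1, 2, 3):
                assert fv_scaled[f"pspf_{i}_{src}"] == fv[f"pspf_{i}_{src}"]
                assert fv_scaled[f"psp_{i}_{src}"] == pytest.approx(
                    scale**2 * fv[f"psp_{i}_{src}"], rel=1e-9
                )
                assert fv_scaled[f"wpsp_{i}_{src}"] == pytest.approx(
                    scale**2 * fv[f"wpsp_{i}_{src}"], rel=1e-9
                )


class TestDistanceFeatures:
    def _fv(self):
        sig, seg = _segmented_signal()
        return extract_feature_vector(sig, seg)

    def test_identical_trials_have_zero_distance(self):
        sig, seg = _segmented_signal(repeat_burst=True)
        fv = extract_feature_vector(sig, seg)
        d = distance_features(fv)
        assert d["d_pse_t_m"] == pytest.approx(0.0, abs=1e-12)
        assert d["d_wpsp_1_t_c"] == pytest.approx(0.0, abs=1e-12)

    def test_scalar_absolute_difference(self):
        fv = {name: 0.0 for name in vector_names()}
        fv["pse__s"], fv["pse__c"] = 10.0, 7.0
        d = distance_features(fv)
        assert d["d_pse_s_c"] == 3.0

    def test_symmetry_in_the_pair(self):
        fv = self._fv()
        d = distance_features(fv)
        swapped = dict(fv)
        for fam_idx in ("pse_", "pspf_1", "pspf_2", "pspf_3", "psp_1", "psp_2", "psp_3",
                        "wpsp_1", "wpsp_2", "wpsp_3"):
            swapped[f"{fam_idx}_t"], swapped[f"{fam_idx}_c"] = (
                fv[f"{fam_idx}_c"],
                fv[f"{fam_idx}_t"],
            )
        d_swapped = distance_features(swapped)
        assert d_swapped["d_pse_t_c"] == d["d_pse_t_c"]
        assert d_swapped["d_psp_2_t_c"] == d["d_psp_2_t_c"]

    def test_cardinality_extended_and_literal_pair_sets(self):
        fv = self._fv()
        assert len(distance_features(fv, pairs=DEFAULT_PAIRS)) == 60
        assert len(distance_features(fv, pairs=LITERAL_PAIRS)) == 50

    def test_unknown_pair_rejected(self):
        with pytest.raises(ParameterError):
            distance_features(self._fv(), pairs=(("s", "q"),))

    def test_all_distances_non_negative(self):
        d = distance_features(self._fv())
        assert all(v >= 0 for v in d.values())
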