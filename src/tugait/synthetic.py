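"""Synthetic TUG-like recordings and feature-level cohorts.

Two generators stand in for the 36-subject study cohort:

* :func:`generate_recording` emits a raw triaxial recording containing
  three activity bursts (a gravity baseline carrying gait harmonics plus
  Gaussian noise) separated by quiet rest, with the exact burst schedule
  returned as ground truth.  Group contrast is injected through the
  amplitudes of the second and third gait harmonics — non-fallers carry
  more energy there — rather than through trial duration, mirroring the
  empirical finding that TUG seconds alone do not separate the groups
  while spectral content does.
* :func:`generate_feature_cohort` draws per-subject feature values from
  per-group Gaussians, parameterised by default with the group mean/SD
  statistics reported for the discriminative features of the reference
  cohort (18 fallers, 18 non-fallers).

All randomness flows from a single integer seed; per-subject streams are
spawned deterministically so cohorts are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, Group, TriaxialRecording
from .errors import ValidationError
from .segmentation import SEGMENT_NAMES

#: harmonic amplitudes (fundamental, 2nd, 3rd) by group; non-fallers carry
#: larger second/third harmonics (richer, more complex gait spectrum)
GROUP_HARMONIC_AMPS = {
    Group.FALLER: (0.30, 0.06, 0.03),
    Group.NON_FALLER: (0.30, 0.14, 0.09),
    Group.UNKNOWN: (0.30, 0.10, 0.06),
}

#: group mean +- SD of the discriminative features reported for the
#: 36-subject reference cohort, as (mu_fallers, sd_fallers,
#: mu_non_fallers, sd_non_fallers).  The two fusion rows are the
#: normalised averages of the feature rows above them.
REFERENCE_GROUP_STATS = {
    "pse__c": (9.52, 2.50, 11.95, 2.90),
    "wpsp_2_c": (1.00, 0.70, 1.73, 0.90),
    "wpsp_3_c": (1.61, 0.60, 2.30, 0.80),
    "features_fusion": (0.324, 0.154, 0.500, 0.161),
    "d_pse_s_c": (6.689, 2.48, 8.497, 2.09),
    "d_psp_1_s_c": (0.024, 0.01, 0.039, 0.01),
    "d_pspf_1_t_m": (17.77, 6.13, 21.38, 4.28),
    "d_wpsp_1_m_c": (0.444, 0.32, 0.899, 0.72),
    "distances_fusion": (0.500, 0.138, 0.664, 0.115),
}


@dataclass
class SignalSpec:
    """Parameters of one synthetic three-trial recording.

    Defaults emulate the study conditions: 200 Hz waist accelerometer,
    trial durations near the reference cohort's TUG / TUG-M / TUG-C times
    (about 10, 11 and 14 s), a 1.4 Hz gait fundamental (a typical elderly
    step rate) with three harmonics, and rest gaps of 5 s.  Amplitudes
    are in gravity units (baseline 1.0).
    """

    trial_durations_s: tuple[float, float, float] = (10.0, 11.0, 14.0)
    gap_s: float = 5.0
    rate: float = 200.0
    gravity_offset: float = 1.0
    fundamental_hz: float = 1.4
    harmonic_amps: tuple[float, ...] | None = None  # default per group
    noise_sd: float = 0.05
    rest_noise_sd: float = 0.01
    lead_s: float = 0.0
    trail_s: float = 0.0
    group: Group = Group.NON_FALLER
    subject_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        self.group = Group.coerce(self.group)
        if len(self.trial_durations_s) != len(SEGMENT_NAMES):
            raise ValidationError("exactly three trial durations are required")
        if any(d <= 0 for d in self.trial_durations_s):
            raise ValidationError("trial durations must be positive")
        if self.gap_s <= 0 or self.rate <= 0 or self.noise_sd <= 0:
            raise ValidationError("gap_s, rate and noise_sd must be positive")
        if self.lead_s < 0 or self.trail_s < 0:
            raise ValidationError("lead_s and trail_s must be non-negative")
        amps = self.harmonic_amps
        if amps is not None and any(a < 0 for a in amps):
            raise ValidationError("harmonic amplitudes must be non-negative")

    @property
    def amps(self) -> tuple[float, ...]:
        if self.harmonic_amps is not None:
            return tuple(self.harmonic_amps)
        return GROUP_HARMONIC_AMPS[self.group]


def generate_recording(spec: SignalSpec):
    """Synthesise one recording; returns (recording, true_segments).

    The magnitude trace is built piecewise — rest is baseline plus small
    noise, each burst adds the gait harmonics (random phases) and larger
    noise — and then distributed over the three axes through a fixed
    random unit orientation, so that axis fusion must undo an arbitrary
    sensor attitude to recover it.  ``true_segments`` is a list of
    (start_sample, end_sample, name) half-open intervals.
    """
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate

    def rest(n):
        return spec.gravity_offset + rng.normal(0.0, spec.rest_noise_sd, n)

    pieces = [rest(int(round(spec.lead_s * rate)))]
    truth = []
    pos = len(pieces[0])
    gap_n = int(round(spec.gap_s * rate))
    for i, (dur, name) in enumerate(zip(spec.trial_durations_s, SEGMENT_NAMES)):
        n = int(round(dur * rate))
        t = np.arange(n) / rate
        burst = spec.gravity_offset + rng.normal(0.0, spec.noise_sd, n)
        for h, amp in enumerate(spec.amps, start=1):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            burst += amp * np.sin(2.0 * np.pi * h * spec.fundamental_hz * t + phase)
        pieces.append(burst)
        truth.append((pos, pos + n, name))
        pos += n
        if i < len(SEGMENT_NAMES) - 1:
            pieces.append(rest(gap_n))
            pos += gap_n
    pieces.append(rest(int(round(spec.trail_s * rate))))

    magnitude = np.concatenate(pieces)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    xyz = magnitude[:, None] * direction[None, :]
    rec = TriaxialRecording(
        subject_id=spec.subject_id,
        group=spec.group,
        rate=rate,
        x=xyz[:, 0],
        y=xyz[:, 1],
        z=xyz[:, 2],
    )
    return rec, truth


def generate_cohort_recordings(
    n_fallers: int = 18,
    n_non_fallers: int = 18,
    seed: int = 0,
    **overrides,
):
    """A list of (recording, true_segments) for a two-group cohort.

    Trial durations and gaps vary per subject around the reference
    cohort's TUG times (TUG ~8-13 s, TUG-M ~8-14 s, TUG-C ~10-20 s, gaps
    3-8 s), and each subject's harmonic amplitudes are jittered
    multiplicatively (lognormal, sigma = 0.25) around the group defaults so
    the groups overlap as real cohorts do; each subject gets an
    independent seeded stream.
    """
    master = np.random.default_rng(seed)
    out = []
    labels = [Group.FALLER] * n_fallers + [Group.NON_FALLER] * n_non_fallers
    for i, group in enumerate(labels):
        sub_seed = int(master.integers(0, 2**31 - 1))
        drng = np.random.default_rng(sub_seed)
        durations = (
            float(drng.uniform(8.0, 13.0)),
            float(drng.uniform(8.0, 14.0)),
            float(drng.uniform(10.0, 20.0)),
        )
        if "harmonic_amps" not in overrides:
            base_amps = np.array(GROUP_HARMONIC_AMPS[group])
            overrides_i = {
                "harmonic_amps": tuple(base_amps * drng.lognormal(0.0, 0.25, len(base_amps)))
            }
        else:
            overrides_i = {}
        spec = SignalSpec(
            trial_durations_s=durations,
            gap_s=float(drng.uniform(3.0, 8.0)),
            **overrides_i,
            lead_s=float(drng.uniform(2.0, 4.0)),
            trail_s=float(drng.uniform(2.0, 4.0)),
            group=group,
            subject_id=f"{group.value}_{i:03d}",
            seed=sub_seed,
            **overrides,
        )
        out.append(generate_recording(spec))
    return out


@dataclass
class CohortSpec:
    """Parameters of a feature-level synthetic cohort.

    ``features`` maps feature name to (mu_fallers, sd_fallers,
    mu_non_fallers, sd_non_fallers); the default reproduces the reference
    cohort's discriminative-feature statistics at its group sizes
    (18 + 18).  ``correlation``, if given, is a between-feature
    correlation matrix shared by both groups.
    """

    features: dict = field(default_factory=lambda: dict(REFERENCE_GROUP_STATS))
    n_pos: int = 18
    n_neg: int = 18
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValidationError("need at least 2 subjects per group")
        for name, (m1, s1, m2, s2) in self.features.items():
            if s1 <= 0 or s2 <= 0:
                raise ValidationError(f"feature {name!r}: SDs must be positive")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(self.features)
            if corr.shape != (k, k) or not np.allclose(corr, corr.T):
                raise ValidationError("correlation must be a symmetric k x k matrix")
            try:
                np.linalg.cholesky(corr)
            except np.linalg.LinAlgError:
                raise ValidationError("correlation matrix is not positive definite") from None
            self.correlation = corr


def generate_feature_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a two-group Gaussian feature cohort; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.features)
    k = len(names)
    rows = []
    for group, n, mu_i, sd_i in (
        (Group.FALLER, spec.n_pos, 0, 1),
        (Group.NON_FALLER, spec.n_neg, 2, 3),
    ):
        mus = np.array([spec.features[f][mu_i] for f in names])
        sds = np.array([spec.features[f][sd_i] for f in names])
        if spec.correlation is None:
            draws = rng.normal(size=(n, k)) * sds + mus
        else:
            chol = np.linalg.cholesky(spec.correlation)
            draws = rng.normal(size=(n, k)) @ chol.T * sds + mus
        for j in range(n):
            row = {"subject_id": f"{group.value}_{j:03d}", "group": group.value}
            row.update({f: float(v) for f, v in zip(names, draws[j])})
            rows.append(row)
    return CohortTable(pd.DataFrame(rows))
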