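"""Seeded synthetic cohort generator for phase-contrast CBF / CVR studies.

Emulates the physiological and statistical structure of a four-phase
respiratory protocol (baseline, hypoxia, recovery baseline, hypercapnia)
delivered by a prospective gas-targeting system while whole-brain blood flow
is measured with short, repeated phase-contrast (PC) acquisitions:

* subject-level baselines (nCBF, end-tidal gases, SpO2, heart rate, minute
  ventilation) drawn around healthy group norms;
* subject- and session-level cerebrovascular reactivity (CVR) to hypercapnia
  and hypoxia, including a configurable fraction of paradoxical responders
  whose blood flow *falls* under hypoxia;
* an unintentional session-specific P_ET_CO2 perturbation during hypoxia that
  couples into hypoxic blood flow through that session's true hypercapnic
  CVR — the confound the analysis-side correction removes;
* back-to-back measurement noise calibrated so that the median absolute
  difference between repeated steady-state nCBF measurements is ~2
  mL/100 g/min;
* two slice placements, with vertebral-artery flow at placement 1 optionally
  attenuated (non-orthogonal slice) so the placement-reconciliation rule has
  real work to do.

Two fidelity levels are supported: ``flow`` writes per-vessel flows directly;
``image`` additionally renders each acquisition as an 8-bin cine of
through-plane velocity (parabolic discs, pulsatile waveform, background phase
offset, voxel noise) that the quantification module can process.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

VESSELS = ("L_ICA", "R_ICA", "L_VA", "R_VA")
VERTEBRAL_VESSELS = ("L_VA", "R_VA")
STEADY_PHASES = ("BL", "HX", "RBL", "HC")
PHASE_LABELS = STEADY_PHASES + ("transition",)

#: NIfTI label values used for mask images.
MASK_LABELS = {"L_ICA": 1, "R_ICA": 2, "L_VA": 3, "R_VA": 4, "static": 5}

BRAIN_TISSUE_DENSITY_G_PER_ML = 1.06


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Schedule:
    """Timing of one scan session, in seconds on a 1-s grid.

    The session is BL -> transition -> HX -> transition -> RBL -> transition
    -> HC.  Each stimulus phase ends with three steady-state acquisitions
    (placements 2, 1, 1); hypoxia and hypercapnia begin with two placement-1
    acquisitions labelled ``transition`` that are generated but excluded from
    CVR; the recovery baseline carries a single steady acquisition.
    """

    bl_s: int = 540
    transition_s: int = 120
    hx_s: int = 600
    rbl_s: int = 240
    hc_s: int = 480
    acq_s: int = 60

    @classmethod
    def compact(cls) -> "Schedule":
        """A shorter session with the same acquisition structure.

        Used for large simulation studies where only the steady-state values
        matter; the statistical structure of the cohort is unchanged.
        """
        return cls(bl_s=180, transition_s=60, hx_s=240, rbl_s=90, hc_s=180,
                   acq_s=30)

    def validate(self) -> None:
        for name in ("bl_s", "transition_s", "hx_s", "rbl_s", "hc_s", "acq_s"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigError(f"schedule.{name} must be a positive integer")
        if 3 * self.acq_s > min(self.bl_s, self.hx_s, self.hc_s):
            raise ConfigError(
                "schedule.acq_s: three steady acquisitions must fit inside "
                "every stimulus phase")
        if self.acq_s > self.rbl_s:
            raise ConfigError("schedule.rbl_s shorter than one acquisition")

    @property
    def total_s(self) -> int:
        return (self.bl_s + self.hx_s + self.rbl_s + self.hc_s
                + 3 * self.transition_s)


@dataclass(frozen=True)
class GeometrySpec:
    """Pixel grid and vessel layout for image-fidelity cines."""

    nx: int = 96
    ny: int = 96
    pixel_size_cm: float = 0.05
    # (x, y) centres in pixels; ICAs anterior, VAs posterior
    centers: tuple = (("L_ICA", (28, 30)), ("R_ICA", (68, 30)),
                      ("L_VA", (32, 70)), ("R_VA", (64, 70)))
    radii_px: tuple = (("L_ICA", 12.0), ("R_ICA", 12.0),
                       ("L_VA", 10.0), ("R_VA", 10.0))
    static_margin_px: int = 8
    n_bins: int = 8
    pulsatility_peak_ratio: float = 1.6

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_size_cm ** 2


_POS_SD_FIELDS = (
    "baseline_ncbf_sd", "baseline_petco2_sd", "baseline_peto2_sd",
    "baseline_spo2_sd", "hx_petco2_perturb_sd", "cvr_hc_sd_subject",
    "cvr_hc_sd_session", "cvr_hx_sd_subject", "cvr_hx_sd_session",
    "ncbf_noise_sd", "brain_volume_sd", "hx_peto2_achieved_sd",
    "hc_petco2_achieved_sd", "spo2_coupling_noise_sd", "petco2_noise_sd",
    "peto2_noise_sd", "spo2_noise_sd", "hr_noise_sd", "ve_noise_sd",
    "image_noise_sd",
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults reproduce the group means/SDs of a healthy adult cohort under a
    four-phase gas protocol: baseline nCBF 63 +/- 9 mL/100 g/min, P_ET_CO2
    41.0 +/- 2.6 mmHg, P_ET_O2 112.3 +/- 8.8 mmHg, SpO2 98 +/- 1 %;
    hypercapnia targets +6 mmHg P_ET_CO2; hypoxia targets P_ET_O2 of
    55-70 mmHg with achieved levels around 61.6 +/- 3.6 mmHg and an
    unintentional concurrent P_ET_CO2 change of -0.4 +/- 0.9 mmHg.
    Hypercapnic CVR is 4.33 %/mmHg with inter-subject SD 1.13 and
    inter-session SD 1.37; hypoxic CVR is 0.10 %/-mmHg with SDs 0.07 / 0.14.
    """

    n_subjects: int = 21
    n_sessions: int = 3
    seed: int = 0

    baseline_ncbf_mean: float = 63.0
    baseline_ncbf_sd: float = 9.0
    baseline_petco2_mean: float = 41.0
    baseline_petco2_sd: float = 2.6
    baseline_peto2_mean: float = 112.3
    baseline_peto2_sd: float = 8.8
    baseline_spo2_mean: float = 98.0
    baseline_spo2_sd: float = 1.0

    hc_petco2_delta: float = 6.0
    hc_petco2_achieved_sd: float = 0.5
    hx_peto2_target_range: tuple = (55.0, 70.0)
    hx_peto2_achieved_mean: float = 61.6
    hx_peto2_achieved_sd: float = 3.6
    hx_petco2_perturb_mean: float = -0.4
    hx_petco2_perturb_sd: float = 0.9

    cvr_hc_mean: float = 4.33
    cvr_hc_sd_subject: float = 1.13
    cvr_hc_sd_session: float = 1.37
    cvr_hx_mean: float = 0.10
    cvr_hx_sd_subject: float = 0.07
    cvr_hx_sd_session: float = 0.14
    paradox_fraction: float = 0.15

    # back-to-back measurement noise on nCBF; 2.1 makes median |diff| ~ 2
    ncbf_noise_sd: float = 2.1

    vessel_split: tuple = (0.38, 0.38, 0.12, 0.12)
    brain_volume_mean: float = 1166.0
    brain_volume_sd: float = 110.0

    # SpO2 ~ baseline - slope * (P_ET_O2 drop) + noise during hypoxia
    spo2_coupling_slope: float = 0.158
    spo2_coupling_noise_sd: float = 1.0

    hr_mean: float = 67.0
    hr_sd: float = 8.0
    hr_hx_delta: float = 5.0
    hr_hc_delta: float = 1.0
    ve_mean: float = 9.2
    ve_sd: float = 2.5
    ve_hx_delta: float = 1.6
    ve_hc_delta: float = 5.4

    # within-trace sample noise (1-s grid)
    petco2_noise_sd: float = 0.3
    peto2_noise_sd: float = 1.0
    spo2_noise_sd: float = 0.3
    hr_noise_sd: float = 1.5
    ve_noise_sd: float = 0.5

    # placement-1 vertebral non-orthogonality (multiplicative attenuation)
    va_attenuation_prob: float = 0.2
    va_attenuation_range: tuple = (0.70, 1.0)

    fidelity: str = "flow"
    image_background_offset: float = 0.3  # cm/s, constant field
    image_noise_sd: float = 0.05  # cm/s voxel noise
    geometry: GeometrySpec = field(default_factory=GeometrySpec)

    schedule: Schedule = field(default_factory=Schedule)
    dropout_spec: Optional[tuple] = None  # ((subject, session, phase), ...)

    def validate(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer))
                and self.n_subjects >= 1):
            raise ConfigError("n_subjects must be a positive integer")
        if not (isinstance(self.n_sessions, (int, np.integer))
                and self.n_sessions >= 1):
            raise ConfigError("n_sessions must be a positive integer")
        for name in _POS_SD_FIELDS:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.vessel_split) != 4:
            raise ConfigError("vessel_split must have four fractions")
        if abs(sum(self.vessel_split) - 1.0) > 1e-9:
            raise ConfigError("vessel_split must sum to 1")
        if any(f <= 0 for f in self.vessel_split):
            raise ConfigError("vessel_split fractions must be positive")
        lo, hi = self.hx_peto2_target_range
        if not (0 < lo < hi < self.baseline_peto2_mean):
            raise ConfigError(
                "hx_peto2_target_range must lie within (0, baseline_peto2_mean)")
        if not (0.0 <= self.paradox_fraction <= 1.0):
            raise ConfigError("paradox_fraction must be within [0, 1]")
        a_lo, a_hi = self.va_attenuation_range
        if not (0 < a_lo <= a_hi <= 1.0):
            raise ConfigError("va_attenuation_range must satisfy 0 < lo <= hi <= 1")
        if not (0.0 <= self.va_attenuation_prob <= 1.0):
            raise ConfigError("va_attenuation_prob must be within [0, 1]")
        if self.fidelity not in ("flow", "image"):
            raise ConfigError("fidelity must be 'flow' or 'image'")
        if self.brain_volume_mean <= 0:
            raise ConfigError("brain_volume_mean must be positive")
        self.schedule.validate()
        if self.dropout_spec is not None:
            for item in self.dropout_spec:
                if len(item) != 3:
                    raise ConfigError(
                        "dropout_spec entries must be (subject, session, phase)")
                if item[2] not in STEADY_PHASES:
                    raise ConfigError(
                        f"dropout_spec phase {item[2]!r} not one of {STEADY_PHASES}")

    def without_noise(self) -> "CohortConfig":
        """A copy with every measurement/trace noise source set to zero.

        Placement attenuation is also disabled so that flows at both
        placements coincide with ground truth; CVR estimated from such a
        cohort equals the generating parameters to numerical precision.
        """
        return replace(
            self, ncbf_noise_sd=0.0, petco2_noise_sd=0.0, peto2_noise_sd=0.0,
            spo2_noise_sd=0.0, hr_noise_sd=0.0, ve_noise_sd=0.0,
            spo2_coupling_noise_sd=0.0, va_attenuation_prob=0.0,
            image_noise_sd=0.0)


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionTruth:
    """Latent per-session quantities one synthetic session was built from."""

    session: int
    cvr_hc: float            # %/mmHg P_ET_CO2
    cvr_hx: float            # %/(-mmHg P_ET_O2)
    hx_peto2: float          # achieved P_ET_O2 during hypoxia, mmHg
    hx_spo2: float           # achieved SpO2 during hypoxia, %
    petco2_perturb: float    # P_ET_CO2(HX) - P_ET_CO2(BL), mmHg
    hc_petco2_delta: float   # achieved P_ET_CO2 increase during HC, mmHg
    va_attenuation: dict     # vessel -> multiplicative factor at placement 1


@dataclass(frozen=True)
class SubjectTruth:
    """Latent subject-level parameters plus their per-session draws."""

    subject: int
    brain_volume_mL: float
    baseline_ncbf: float
    baseline_petco2: float
    baseline_peto2: float
    baseline_spo2: float
    baseline_hr: float
    baseline_ve: float
    responder_class: str     # typical | minimal | paradoxical
    sessions: tuple          # of SessionTruth

    def __post_init__(self):
        for name in ("brain_volume_mL", "baseline_ncbf", "baseline_petco2",
                     "baseline_peto2", "baseline_spo2"):
            if not math.isfinite(getattr(self, name)):
                raise DataError(f"SubjectTruth.{name} is not finite")


@dataclass
class VelocityCine:
    """One retrospectively gated PC acquisition rendered as voxel data.

    ``velocity`` has shape (nx, ny, n_bins) in cm/s; vessel masks are shared
    across cardiac bins (the synthetic vessels do not move).
    """

    velocity: np.ndarray
    pixel_area_cm2: float
    vessel_masks: dict       # vessel -> bool array (nx, ny)
    static_mask: np.ndarray  # bool array (nx, ny)

    def __post_init__(self):
        if self.velocity.ndim != 3:
            raise DataError("velocity must be (nx, ny, n_bins)")
        if not np.all(np.isfinite(self.velocity)):
            raise DataError("velocity contains non-finite values")
        for vessel, mask in self.vessel_masks.items():
            if np.any(mask & self.static_mask):
                raise DataError(
                    f"vessel mask {vessel} overlaps the static-tissue mask")

    @property
    def n_bins(self) -> int:
        return self.velocity.shape[2]

    def __eq__(self, other):
        return (isinstance(other, VelocityCine)
                and np.array_equal(self.velocity, other.velocity)
                and self.pixel_area_cm2 == other.pixel_area_cm2
                and set(self.vessel_masks) == set(other.vessel_masks)
                and all(np.array_equal(self.vessel_masks[v],
                                       other.vessel_masks[v])
                        for v in self.vessel_masks)
                and np.array_equal(self.static_mask, other.static_mask))


@dataclass
class SyntheticStudy:
    """A complete synthetic study: traces, acquisitions, anatomy, truth."""

    config: CohortConfig
    physio: dict             # (subject, session) -> DataFrame (trace schema)
    acquisitions: pd.DataFrame
    anatomy: pd.DataFrame
    truth: tuple             # of SubjectTruth
    cines: Optional[dict] = None   # acq_id -> VelocityCine (image fidelity)

    def trace(self, subject: int, session: int) -> pd.DataFrame:
        try:
            return self.physio[(subject, session)]
        except KeyError:
            raise DataError(
                f"no physiological trace for subject {subject} session {session}")

    def brain_mass_g(self, subject: int) -> float:
        row = self.anatomy.loc[self.anatomy["subject"] == subject]
        if row.empty:
            raise DataError(f"no anatomy row for subject {subject}")
        vol = float(row["gm_vol_mL"].iloc[0] + row["wm_vol_mL"].iloc[0])
        return vol * BRAIN_TISSUE_DENSITY_G_PER_ML

    def __eq__(self, other):
        if not isinstance(other, SyntheticStudy):
            return NotImplemented
        if self.config != other.config:
            return False
        if set(self.physio) != set(other.physio):
            return False
        if not all(self.physio[k].equals(other.physio[k]) for k in self.physio):
            return False
        if not self.acquisitions.equals(other.acquisitions):
            return False
        if not self.anatomy.equals(other.anatomy):
            return False
        if self.truth != other.truth:
            return False
        a, b = self.cines or {}, other.cines or {}
        return set(a) == set(b) and all(a[k] == b[k] for k in a)


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------


def sample_subject_params(config: CohortConfig, rng: np.random.Generator,
                          subject: int = 1) -> SubjectTruth:
    """Draw one subject's latent parameters and per-session deviations.

    Subject-level CVR means come from the configured normal distributions;
    hypoxic CVR is folded positive for typical responders and negative for
    the ``paradox_fraction`` of paradoxical responders, so the subject-level
    sign defines the class.  Session values add N(0, sd_session) deviations.
    """
    c = config
    volume = max(float(rng.normal(c.brain_volume_mean, c.brain_volume_sd)),
                 0.3 * c.brain_volume_mean)
    ncbf_bl = max(float(rng.normal(c.baseline_ncbf_mean, c.baseline_ncbf_sd)),
                  15.0)
    petco2_bl = float(rng.normal(c.baseline_petco2_mean, c.baseline_petco2_sd))
    peto2_bl = float(rng.normal(c.baseline_peto2_mean, c.baseline_peto2_sd))
    spo2_bl = min(float(rng.normal(c.baseline_spo2_mean, c.baseline_spo2_sd)),
                  100.0)
    hr_bl = float(rng.normal(c.hr_mean, c.hr_sd))
    ve_bl = float(rng.normal(c.ve_mean, c.ve_sd))

    paradoxical = bool(rng.random() < c.paradox_fraction)
    cvr_hc_subj = float(rng.normal(c.cvr_hc_mean, c.cvr_hc_sd_subject))
    hx_draw = abs(float(rng.normal(c.cvr_hx_mean, c.cvr_hx_sd_subject)))
    cvr_hx_subj = -hx_draw if paradoxical else hx_draw

    sessions = []
    for s in range(1, c.n_sessions + 1):
        cvr_hc_s = cvr_hc_subj + float(rng.normal(0.0, c.cvr_hc_sd_session))
        cvr_hx_s = cvr_hx_subj + float(rng.normal(0.0, c.cvr_hx_sd_session))
        hx_peto2 = float(np.clip(
            rng.normal(c.hx_peto2_achieved_mean, c.hx_peto2_achieved_sd),
            30.0, peto2_bl - 20.0))
        perturb = float(rng.normal(c.hx_petco2_perturb_mean,
                                   c.hx_petco2_perturb_sd))
        hc_delta = float(rng.normal(c.hc_petco2_delta, c.hc_petco2_achieved_sd))
        hx_spo2 = float(np.clip(
            spo2_bl - c.spo2_coupling_slope * (peto2_bl - hx_peto2)
            + rng.normal(0.0, c.spo2_coupling_noise_sd), 50.0, 100.0))
        attenuation = {}
        for vessel in VERTEBRAL_VESSELS:
            if rng.random() < c.va_attenuation_prob:
                attenuation[vessel] = float(rng.uniform(*c.va_attenuation_range))
            else:
                attenuation[vessel] = 1.0
        sessions.append(SessionTruth(
            session=s, cvr_hc=cvr_hc_s, cvr_hx=cvr_hx_s, hx_peto2=hx_peto2,
            hx_spo2=hx_spo2, petco2_perturb=perturb, hc_petco2_delta=hc_delta,
            va_attenuation=attenuation))

    # class from subject-level hypoxic CVR and the expected nCBF change under
    # a nominal P_ET_O2 drop, against the 2 mL/100 g/min meaningful threshold
    nominal_drop = c.baseline_peto2_mean - c.hx_peto2_achieved_mean
    expected_delta = ncbf_bl * cvr_hx_subj / 100.0 * nominal_drop
    if cvr_hx_subj < 0:
        responder_class = "paradoxical"
    elif abs(expected_delta) < 2.0:
        responder_class = "minimal"
    else:
        responder_class = "typical"

    return SubjectTruth(
        subject=subject, brain_volume_mL=volume, baseline_ncbf=ncbf_bl,
        baseline_petco2=petco2_bl, baseline_peto2=peto2_bl,
        baseline_spo2=spo2_bl, baseline_hr=hr_bl, baseline_ve=ve_bl,
        responder_class=responder_class, sessions=tuple(sessions))


def true_phase_ncbf(subject: SubjectTruth, session: SessionTruth) -> dict:
    """Noise-free steady-state nCBF for every phase of one session.

    Hypoxic flow includes both the hypoxic response (referenced to the
    achieved P_ET_O2 drop) and the contribution of the concurrent P_ET_CO2
    perturbation through that session's true hypercapnic CVR.
    """
    bl = subject.baseline_ncbf
    peto2_drop = subject.baseline_peto2 - session.hx_peto2
    hx = bl * (1.0 + session.cvr_hx / 100.0 * peto2_drop
               + session.cvr_hc / 100.0 * session.petco2_perturb)
    hc = bl * (1.0 + session.cvr_hc / 100.0 * session.hc_petco2_delta)
    return {"BL": bl, "HX": hx, "RBL": bl, "HC": hc}


# ---------------------------------------------------------------------------
# session timeline
# ---------------------------------------------------------------------------


def _segments(sched: Schedule) -> list:
    """(label, start, duration) for the seven contiguous session segments."""
    segs, t = [], 0
    for label, dur in (("BL", sched.bl_s), ("transition", sched.transition_s),
                       ("HX", sched.hx_s), ("transition", sched.transition_s),
                       ("RBL", sched.rbl_s), ("transition", sched.transition_s),
                       ("HC", sched.hc_s)):
        segs.append((label, t, dur))
        t += dur
    return segs


def acquisition_slots(sched: Schedule) -> list:
    """(phase_label, placement, start_s) for every PC acquisition of a session.

    Steady-state blocks end each stimulus phase with placements (2, 1, 1);
    transition-labelled scans open the hypoxia and hypercapnia blocks.
    """
    a = sched.acq_s
    segs = {label: (start, dur) for label, start, dur in _segments(sched)
            if label != "transition"}
    slots = []
    bl_start, bl_dur = segs["BL"]
    bl_end = bl_start + bl_dur
    for i, placement in enumerate((2, 1, 1)):
        slots.append(("BL", placement, bl_end - (3 - i) * a))
    hx_start, hx_dur = segs["HX"]
    hx_end = hx_start + hx_dur
    for i in range(2):
        slots.append(("transition", 1, hx_start + i * a))
    for i, placement in enumerate((2, 1, 1)):
        slots.append(("HX", placement, hx_end - (3 - i) * a))
    rbl_start, rbl_dur = segs["RBL"]
    slots.append(("RBL", 1, rbl_start + rbl_dur - a))
    hc_start, hc_dur = segs["HC"]
    hc_end = hc_start + hc_dur
    for i in range(2):
        slots.append(("transition", 1, hc_start + i * a))
    for i, placement in enumerate((2, 1, 1)):
        slots.append(("HC", placement, hc_end - (3 - i) * a))
    return slots


def _session_trace(config: CohortConfig, subject: SubjectTruth,
                   session: SessionTruth,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Render the continuous physiological recording for one session."""
    c, sched = config, config.schedule
    segs = _segments(sched)
    targets = {
        "petco2": {"BL": subject.baseline_petco2,
                   "HX": subject.baseline_petco2 + session.petco2_perturb,
                   "RBL": subject.baseline_petco2,
                   "HC": subject.baseline_petco2 + session.hc_petco2_delta},
        "peto2": {"BL": subject.baseline_peto2, "HX": session.hx_peto2,
                  "RBL": subject.baseline_peto2, "HC": subject.baseline_peto2},
        "spo2": {"BL": subject.baseline_spo2, "HX": session.hx_spo2,
                 "RBL": subject.baseline_spo2, "HC": subject.baseline_spo2},
        "hr": {"BL": subject.baseline_hr,
               "HX": subject.baseline_hr + c.hr_hx_delta,
               "RBL": subject.baseline_hr,
               "HC": subject.baseline_hr + c.hr_hc_delta},
        "ve": {"BL": subject.baseline_ve,
               "HX": subject.baseline_ve + c.ve_hx_delta,
               "RBL": subject.baseline_ve,
               "HC": subject.baseline_ve + c.ve_hc_delta},
    }
    n_total = sched.total_s
    channels = {name: np.empty(n_total) for name in targets}
    phase = np.empty(n_total, dtype=object)
    for i, (label, start, dur) in enumerate(segs):
        sl = slice(start, start + dur)
        phase[sl] = label
        for name, per_phase in targets.items():
            if label == "transition":
                prev = per_phase[segs[i - 1][0]]
                nxt = per_phase[segs[i + 1][0]]
                channels[name][sl] = np.linspace(prev, nxt, dur, endpoint=False)
            else:
                channels[name][sl] = per_phase[label]
    noise_sds = {"petco2": c.petco2_noise_sd, "peto2": c.peto2_noise_sd,
                 "spo2": c.spo2_noise_sd, "hr": c.hr_noise_sd,
                 "ve": c.ve_noise_sd}
    for name, sd in noise_sds.items():
        if sd > 0:
            channels[name] = channels[name] + rng.normal(0.0, sd, n_total)
    channels["spo2"] = np.minimum(channels["spo2"], 100.0)
    return pd.DataFrame({
        "time_s": np.arange(n_total, dtype=float),
        "petco2_mmHg": channels["petco2"],
        "peto2_mmHg": channels["peto2"],
        "spo2_pct": channels["spo2"],
        "hr_bpm": channels["hr"],
        "ve_L_min": channels["ve"],
        "phase": phase,
    })


# ---------------------------------------------------------------------------
# image-fidelity rendering
# ---------------------------------------------------------------------------


def pulsatility_waveform(n_bins: int, peak_ratio: float = 1.6) -> np.ndarray:
    """Unit-mean raised-cosine cardiac waveform with the given peak/mean ratio."""
    if peak_ratio < 1.0:
        raise ConfigError("pulsatility peak_ratio must be >= 1")
    b = np.arange(n_bins)
    return 1.0 + (peak_ratio - 1.0) * np.cos(2.0 * np.pi * b / n_bins)


def _vessel_geometry(geometry: GeometrySpec):
    centers = dict(geometry.centers)
    radii = dict(geometry.radii_px)
    m = geometry.static_margin_px
    for vessel, (cx, cy) in centers.items():
        r = radii[vessel]
        if (cx - r <= m or cy - r <= m or cx + r >= geometry.nx - m
                or cy + r >= geometry.ny - m):
            raise ConfigError(
                f"vessel disc {vessel} does not fit inside the non-static grid")
    names = list(centers)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            dist = math.hypot(centers[a][0] - centers[b][0],
                              centers[a][1] - centers[b][1])
            if dist <= radii[a] + radii[b]:
                raise ConfigError(f"vessel discs {a} and {b} overlap")
    return centers, radii


def synth_velocity_cine(flows_ml_min: dict, geometry: GeometrySpec,
                        noise_sd: float = 0.0,
                        background_offset: float = 0.0,
                        rng: Optional[np.random.Generator] = None,
                        pulsatile: bool = True) -> VelocityCine:
    """Render per-vessel flows as an 8-bin cine of through-plane velocity.

    Each vessel is a disc with a parabolic velocity profile whose analytic
    integral equals the requested per-bin flow (pixel sums therefore agree to
    discretisation accuracy, ~<2 % for disc diameters of 20 px or more).  The
    cycle-mean flow is modulated across bins by a unit-mean raised-cosine
    waveform; a constant background phase offset and iid voxel noise are
    added everywhere.
    """
    for vessel, q in flows_ml_min.items():
        if q < 0:
            raise DataError(f"flow for {vessel} must be >= 0, got {q}")
    centers, radii = _vessel_geometry(geometry)
    g = geometry
    xx, yy = np.meshgrid(np.arange(g.nx), np.arange(g.ny), indexing="ij")
    n_bins = g.n_bins
    if pulsatile:
        waveform = pulsatility_waveform(n_bins, g.pulsatility_peak_ratio)
    else:
        waveform = np.ones(n_bins)
    velocity = np.zeros((g.nx, g.ny, n_bins))
    vessel_masks = {}
    for vessel in flows_ml_min:
        cx, cy = centers[vessel]
        r_px = radii[vessel]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = r2 < r_px ** 2
        vessel_masks[vessel] = mask
        radius_cm = r_px * g.pixel_size_cm
        q_cm3_s = flows_ml_min[vessel] / 60.0
        v_max = 2.0 * q_cm3_s / (np.pi * radius_cm ** 2)  # cm/s
        profile = v_max * (1.0 - r2 / r_px ** 2)
        for b in range(n_bins):
            velocity[:, :, b][mask] += waveform[b] * profile[mask]
    m = g.static_margin_px
    static = np.zeros((g.nx, g.ny), dtype=bool)
    static[:m, :] = static[-m:, :] = True
    static[:, :m] = static[:, -m:] = True
    velocity += background_offset
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        velocity = velocity + rng.normal(0.0, noise_sd, velocity.shape)
    return VelocityCine(velocity=velocity, pixel_area_cm2=g.pixel_area_cm2,
                        vessel_masks=vessel_masks, static_mask=static)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

ACQ_FLOW_COLUMNS = [f"flow_{v}" for v in VESSELS]
ACQ_COLUMNS = ["acq_id", "subject", "session", "phase", "placement",
               "start_s", "duration_s", "spo2_start", "hr_start",
               *ACQ_FLOW_COLUMNS]


def generate_cohort(config: CohortConfig) -> SyntheticStudy:
    """Generate a full synthetic study from one seeded configuration.

    Deterministic for a fixed config (single ``default_rng(seed)`` stream,
    fixed draw order).  Steady-state per-vessel flows equal the true phase
    nCBF (baseline adjusted through true CVR and the achieved gas deltas)
    converted to mL/min via brain mass, split across the four neck vessels,
    attenuated at placement 1 for non-orthogonal vertebral arteries, plus
    nCBF-scale measurement noise.
    """
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)
    subjects = tuple(sample_subject_params(c, rng, subject=i + 1)
                     for i in range(c.n_subjects))

    dropouts = set()
    if c.dropout_spec:
        dropouts = {(int(s), int(v), p) for s, v, p in c.dropout_spec}

    slots = acquisition_slots(c.schedule)
    physio, rows, cines = {}, [], {}
    split = dict(zip(VESSELS, c.vessel_split))

    for subject in subjects:
        mass = subject.brain_volume_mL * BRAIN_TISSUE_DENSITY_G_PER_ML
        for session in subject.sessions:
            trace = _session_trace(c, subject, session, rng)
            physio[(subject.subject, session.session)] = trace
            ncbf = true_phase_ncbf(subject, session)
            for idx, (phase, placement, start) in enumerate(slots):
                if (subject.subject, session.session, phase) in dropouts:
                    continue
                if phase == "transition":
                    # not yet at steady state: between baseline and the
                    # upcoming stimulus level (excluded from CVR downstream)
                    upcoming = "HX" if start < c.schedule.bl_s + \
                        c.schedule.transition_s + c.schedule.hx_s else "HC"
                    ncbf_true = 0.5 * (ncbf["BL"] + ncbf[upcoming])
                else:
                    ncbf_true = ncbf[phase]
                noise = rng.normal(0.0, c.ncbf_noise_sd) if c.ncbf_noise_sd > 0 \
                    else 0.0
                total_flow = (ncbf_true + noise) * mass / 100.0
                flows = {v: total_flow * split[v] for v in VESSELS}
                if placement == 1:
                    for v in VERTEBRAL_VESSELS:
                        flows[v] *= session.va_attenuation[v]
                acq_id = (f"S{subject.subject:02d}_V{session.session}"
                          f"_A{idx:02d}")
                row = {
                    "acq_id": acq_id, "subject": subject.subject,
                    "session": session.session, "phase": phase,
                    "placement": placement, "start_s": float(start),
                    "duration_s": float(c.schedule.acq_s),
                    "spo2_start": float(trace["spo2_pct"].iloc[start]),
                    "hr_start": float(trace["hr_bpm"].iloc[start]),
                }
                if c.fidelity == "image":
                    cines[acq_id] = synth_velocity_cine(
                        flows, c.geometry, noise_sd=c.image_noise_sd,
                        background_offset=c.image_background_offset, rng=rng)
                    for v in VESSELS:
                        row[f"flow_{v}"] = np.nan
                else:
                    for v in VESSELS:
                        row[f"flow_{v}"] = flows[v]
                rows.append(row)

    acquisitions = pd.DataFrame(rows, columns=ACQ_COLUMNS)
    anatomy = pd.DataFrame({
        "subject": [s.subject for s in subjects],
        "gm_vol_mL": [0.6 * s.brain_volume_mL for s in subjects],
        "wm_vol_mL": [0.4 * s.brain_volume_mL for s in subjects],
    })
    return SyntheticStudy(config=c, physio=physio, acquisitions=acquisitions,
                          anatomy=anatomy, truth=subjects,
                          cines=cines if c.fidelity == "image" else None)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["geometry"] = dataclasses.asdict(config.geometry)
    d["schedule"] = dataclasses.asdict(config.schedule)
    return d


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(x) for x in obj)
    return obj


def _config_from_jsonable(d: dict) -> CohortConfig:
    d = dict(d)
    geom = d.pop("geometry")
    geom["centers"] = tuple((name, tuple(xy)) for name, xy in geom["centers"])
    geom["radii_px"] = tuple((name, r) for name, r in geom["radii_px"])
    sched = d.pop("schedule")
    for key in ("vessel_split", "hx_peto2_target_range", "va_attenuation_range",
                "dropout_spec"):
        if d.get(key) is not None:
            d[key] = _tuplify(d[key])
    return CohortConfig(geometry=GeometrySpec(**geom), schedule=Schedule(**sched),
                        **d)


def _truth_to_jsonable(truth: tuple) -> list:
    out = []
    for subj in truth:
        d = dataclasses.asdict(subj)
        d["sessions"] = [dataclasses.asdict(s) for s in subj.sessions]
        out.append(d)
    return out


def _truth_from_jsonable(items: list) -> tuple:
    subjects = []
    for d in items:
        sessions = tuple(SessionTruth(**s) for s in d.pop("sessions"))
        subjects.append(SubjectTruth(sessions=sessions, **d))
    return tuple(subjects)


def write_study(study: SyntheticStudy, directory) -> Path:
    """Serialize a study to plain-text tables (+ NIfTI cines if present)."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "config.json", "w") as fh:
        json.dump(_config_to_jsonable(study.config), fh, indent=1)
    with open(directory / "truth.json", "w") as fh:
        json.dump(_truth_to_jsonable(study.truth), fh, indent=1)
    for (subject, session), trace in study.physio.items():
        trace.to_csv(directory / f"physio_{subject:02d}_{session}.csv",
                     index=False)
    study.acquisitions.to_csv(directory / "acquisitions.csv", index=False)
    study.anatomy.to_csv(directory / "anatomy.csv", index=False)
    if study.cines:
        cine_dir = directory / "cines"
        cine_dir.mkdir(exist_ok=True)
        pix_mm = math.sqrt(next(iter(study.cines.values())).pixel_area_cm2) * 10
        for acq_id, cine in study.cines.items():
            affine = np.diag([pix_mm, pix_mm, 5.0, 1.0])
            img = nib.Nifti1Image(
                cine.velocity[:, :, np.newaxis, :].astype(np.float64), affine)
            img.header.set_zooms((pix_mm, pix_mm, 5.0, 1.0))
            nib.save(img, cine_dir / f"{acq_id}_velocity.nii")
            labels = np.zeros(cine.velocity.shape[:2], dtype=np.int16)
            for vessel, mask in cine.vessel_masks.items():
                labels[mask] = MASK_LABELS[vessel]
            labels[cine.static_mask] = MASK_LABELS["static"]
            nib.save(nib.Nifti1Image(labels[:, :, np.newaxis], affine),
                     cine_dir / f"{acq_id}_masks.nii")
    return directory


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise DataError(f"missing {what}: {path}")
    return path


def read_study(directory) -> SyntheticStudy:
    """Read a study directory written by :func:`write_study`.

    Round-trips exactly: ``read_study(write_study(s, d)) == s``.
    """
    import nibabel as nib

    directory = Path(directory)
    with open(_require(directory / "config.json", "study configuration")) as fh:
        config = _config_from_jsonable(json.load(fh))
    with open(_require(directory / "truth.json", "ground-truth parameters")) as fh:
        truth = _truth_from_jsonable(json.load(fh))
    acquisitions = pd.read_csv(
        _require(directory / "acquisitions.csv", "acquisition table"),
        float_precision="round_trip")
    anatomy = pd.read_csv(
        _require(directory / "anatomy.csv", "anatomy table"),
        float_precision="round_trip")
    physio = {}
    for subj in truth:
        for sess in subj.sessions:
            path = _require(
                directory / f"physio_{subj.subject:02d}_{sess.session}.csv",
                f"physiological trace for subject {subj.subject} "
                f"session {sess.session}")
            physio[(subj.subject, sess.session)] = pd.read_csv(
                path, float_precision="round_trip")
    cines = None
    if config.fidelity == "image":
        cines = {}
        inv_labels = {v: k for k, v in MASK_LABELS.items()}
        for acq_id in acquisitions["acq_id"]:
            vpath = _require(directory / "cines" / f"{acq_id}_velocity.nii",
                             f"velocity cine for acquisition {acq_id}")
            mpath = _require(directory / "cines" / f"{acq_id}_masks.nii",
                             f"mask image for acquisition {acq_id}")
            vimg = nib.load(vpath)
            velocity = np.asarray(vimg.dataobj)[:, :, 0, :]
            pix_cm = float(vimg.header.get_zooms()[0]) / 10.0
            labels = np.asarray(nib.load(mpath).dataobj)[:, :, 0]
            vessel_masks = {inv_labels[val]: labels == val
                            for val in np.unique(labels)
                            if val != 0 and inv_labels[val] != "static"}
            cines[acq_id] = VelocityCine(
                velocity=velocity, pixel_area_cm2=pix_cm ** 2,
                vessel_masks=vessel_masks,
                static_mask=labels == MASK_LABELS["static"])
    return SyntheticStudy(config=config, physio=physio,
                          acquisitions=acquisitions, anatomy=anatomy,
                          truth=truth, cines=cines)
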