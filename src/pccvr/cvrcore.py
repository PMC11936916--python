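"""Steady-state CBF per phase, CVR computation, and the CO2 correction.

The session-level workflow:

1. Fit, per vertebral artery across the whole group, an ordinary
   least-squares model of placement-2 steady-state flow on placement-1 flow.
2. Flag a vertebral artery in a session when its measured placement-2 flow
   exceeds the model prediction by more than ``multiplier`` (default 1.96)
   times the fit's residual SD at any steady-state timepoint: the vessel was
   not orthogonal to placement 1 and the placement-2 values substitute for
   placement 1 in every phase of that session.
3. Average placement-1 steady-state acquisitions per phase (vertebral values
   swapped in when flagged), sum the four vessels, and normalize by brain
   mass to nCBF.
4. Compute hypercapnic CVR (percent CBF change per mmHg P_ET_CO2) and
   hypoxic CVR referenced to the P_ET_O2 or SpO2 decrease (sign flipped so a
   flow increase under hypoxia is a positive reactivity).
5. Re-compute hypoxic CVR after removing the CBF contribution of the
   unintentional concurrent P_ET_CO2 change, estimated from the same
   session's hypercapnic CVR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedCVRError
from .synthgen import STEADY_PHASES, VERTEBRAL_VESSELS, VESSELS

DEFAULT_OUTLIER_MULTIPLIER = 1.96
DEFAULT_RESIDUAL_SD_FLOOR = 1.0  # mL/min


# ---------------------------------------------------------------------------
# placement reconciliation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlacementModel:
    """Group-level linear relationship of placement-2 on placement-1 flow."""

    vessel: str
    slope: float
    intercept: float
    residual_sd: float   # RMSE with n-2 degrees of freedom, mL/min
    n: int

    def predict(self, p1_flow: float) -> float:
        return self.intercept + self.slope * p1_flow


def fit_placement_model(p1_flows, p2_flows, vessel: str) -> PlacementModel:
    """OLS fit of placement-2 flow on placement-1 flow for one vessel."""
    p1 = np.asarray(p1_flows, dtype=float)
    p2 = np.asarray(p2_flows, dtype=float)
    if p1.shape != p2.shape:
        raise DataError("placement-1 and placement-2 flows differ in length")
    n = p1.size
    if n < 3:
        raise DataError(
            f"placement model for {vessel} needs >= 3 paired observations, "
            f"got {n}")
    if np.ptp(p1) == 0:
        raise DataError(
            f"placement model for {vessel}: placement-1 flows are constant")
    slope, intercept = np.polyfit(p1, p2, 1)
    residuals = p2 - (intercept + slope * p1)
    sse = float(residuals @ residuals)
    residual_sd = math.sqrt(sse / (n - 2))
    return PlacementModel(vessel=vessel, slope=float(slope),
                          intercept=float(intercept),
                          residual_sd=residual_sd, n=int(n))


def reconcile_vertebral_placements(
        model: PlacementModel, p1_flows, p2_flows,
        multiplier: float = DEFAULT_OUTLIER_MULTIPLIER,
        residual_sd_floor: float = DEFAULT_RESIDUAL_SD_FLOOR) -> bool:
    """Decide whether placement-2 flow substitutes for one vessel/session.

    ``p1_flows`` / ``p2_flows`` are paired steady-state observations from one
    session (one pair per phase where both placements were measured).  The
    rule is one-sided: substitution triggers only when placement 2 *exceeds*
    the value predicted from placement 1 by more than ``multiplier`` x the
    model residual SD at any timepoint — placement 2 reading high means the
    vessel was cut obliquely by placement 1 and its flow was underestimated.
    """
    p1 = np.asarray(p1_flows, dtype=float)
    p2 = np.asarray(p2_flows, dtype=float)
    if p1.size == 0 or p1.shape != p2.shape:
        raise DataError("need paired placement-1/placement-2 flows")
    sd = max(model.residual_sd, residual_sd_floor)
    excess = p2 - model.predict(p1)
    if sd == 0:
        if np.any(excess != 0):
            raise DataError(
                f"placement model for {model.vessel} has zero residual SD "
                "but nonzero deviations; set a positive residual-SD floor")
        return False
    return bool(np.any(excess > multiplier * sd))


# ---------------------------------------------------------------------------
# session steady-state CBF
# ---------------------------------------------------------------------------


@dataclass
class SessionCBF:
    """Per-phase steady-state CBF/nCBF for one subject-session."""

    subject: int
    session: int
    mass_g: float
    cbf: dict = field(default_factory=dict)          # phase -> mL/min
    ncbf: dict = field(default_factory=dict)         # phase -> mL/100 g/min
    vessel_flows: dict = field(default_factory=dict)  # phase -> {vessel: flow}
    substituted: dict = field(default_factory=dict)  # vessel -> bool
    physio: dict = field(default_factory=dict)       # phase -> dict of means

    def has_phase(self, phase: str) -> bool:
        return phase in self.cbf


def steady_state_cbf(acquisitions: pd.DataFrame, physio_table: pd.DataFrame,
                     subject: int, session: int, mass_g: float,
                     substitutions: Optional[dict] = None) -> SessionCBF:
    """Combine a session's steady acquisitions into per-phase CBF and physio.

    Carotid flows are the mean over placement-1 steady-state acquisitions of
    each phase; vertebral flows likewise, unless the vessel is flagged in
    ``substitutions``, in which case the placement-2 values replace them in
    every phase of the session.  Phase physio is the mean of the placement-1
    per-acquisition summaries (SpO2/HR included).  A phase with no usable
    acquisition is simply absent.
    """
    if mass_g <= 0:
        raise DataError("brain mass must be positive")
    substitutions = dict.fromkeys(VERTEBRAL_VESSELS, False) | \
        (substitutions or {})
    for vessel in substitutions:
        if vessel not in VERTEBRAL_VESSELS and substitutions[vessel]:
            raise DataError(
                f"substitution is only defined for vertebral vessels, "
                f"not {vessel!r}")
    sess_acq = acquisitions[(acquisitions["subject"] == subject)
                            & (acquisitions["session"] == session)]
    sess_phys = physio_table[(physio_table["subject"] == subject)
                             & (physio_table["session"] == session)]
    out = SessionCBF(subject=subject, session=session, mass_g=mass_g,
                     substituted=dict(substitutions))
    for phase in STEADY_PHASES:
        p1 = sess_acq[(sess_acq["phase"] == phase)
                      & (sess_acq["placement"] == 1)]
        p2 = sess_acq[(sess_acq["phase"] == phase)
                      & (sess_acq["placement"] == 2)]
        if p1.empty:
            continue
        flows = {}
        usable = True
        for vessel in VESSELS:
            col = f"flow_{vessel}"
            source = p2 if substitutions.get(vessel) else p1
            if source.empty or source[col].isna().any():
                usable = False
                break
            flows[vessel] = float(source[col].mean())
        if not usable:
            continue
        total = float(sum(flows.values()))
        out.vessel_flows[phase] = flows
        out.cbf[phase] = total
        out.ncbf[phase] = total / mass_g * 100.0
        phys = sess_phys[sess_phys["acq_id"].isin(p1["acq_id"])]
        if not phys.empty:
            out.physio[phase] = {
                var: float(phys[var].mean())
                for var in ("petco2", "peto2", "ve", "spo2", "hr")}
    return out


def backtoback_pairs(acquisitions: pd.DataFrame, mass_by_subject: dict
                     ) -> pd.DataFrame:
    """Consecutive placement-1 steady-state nCBF pairs within each phase.

    These back-to-back repetitions carry no stimulus change, so their
    differences estimate measurement noise plus natural fluctuation.
    """
    flow_cols = [f"flow_{v}" for v in VESSELS]
    steady = acquisitions[(acquisitions["placement"] == 1)
                          & acquisitions["phase"].isin(STEADY_PHASES)].copy()
    steady = steady[steady[flow_cols].notna().all(axis=1)]
    if steady.empty:
        return pd.DataFrame(columns=["subject", "session", "phase",
                                     "ncbf_first", "ncbf_second", "diff"])
    mass = steady["subject"].map(mass_by_subject)
    steady["ncbf"] = steady[flow_cols].sum(axis=1) / mass * 100.0
    steady = steady.sort_values(["subject", "session", "phase", "start_s"])
    grouped = steady.groupby(["subject", "session", "phase"], sort=False)
    steady["ncbf_first"] = grouped["ncbf"].shift(1)
    pairs = steady.dropna(subset=["ncbf_first"])
    out = pairs[["subject", "session", "phase", "ncbf_first"]].copy()
    out["ncbf_second"] = pairs["ncbf"]
    out["diff"] = out["ncbf_second"] - out["ncbf_first"]
    return out.reset_index(drop=True)


def meaningful_change_threshold(diffs) -> float:
    """Median absolute back-to-back nCBF difference (mL/100 g/min).

    Changes in nCBF smaller than this threshold are indistinguishable from
    measurement noise and natural fluctuation and are classified as minimal.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise DataError("no back-to-back pairs; cannot derive a threshold")
    return float(np.median(np.abs(d)))


def classify_response(delta_ncbf: float, threshold: float) -> str:
    """increase / decrease / minimal, against the meaningful-change threshold."""
    if threshold <= 0:
        raise DataError("classification threshold must be positive")
    if abs(delta_ncbf) < threshold:
        return "minimal"
    return "increase" if delta_ncbf > 0 else "decrease"


# ---------------------------------------------------------------------------
# CVR equations
# ---------------------------------------------------------------------------


def cvr_hypercapnic(cbf_bl: float, cbf_hc: float, petco2_bl: float,
                    petco2_hc: float) -> float:
    """Percent CBF change per mmHg P_ET_CO2 increase (%/mmHg)."""
    if cbf_bl <= 0:
        raise DataError("baseline CBF must be positive")
    dpet = petco2_hc - petco2_bl
    if dpet == 0:
        raise UndefinedCVRError("P_ET_CO2 did not change; hypercapnic CVR "
                                "is undefined")
    return 100.0 * (cbf_hc - cbf_bl) / cbf_bl / dpet


def cvr_hypoxic_peto2(cbf_bl: float, cbf_hx: float, peto2_bl: float,
                      peto2_hx: float) -> float:
    """Percent CBF change per mmHg P_ET_O2 *decrease* (%/-mmHg).

    The sign is flipped so that the expected vasodilatory flow increase under
    falling P_ET_O2 yields a positive reactivity; a paradoxical flow decrease
    yields a negative one.
    """
    if cbf_bl <= 0:
        raise DataError("baseline CBF must be positive")
    dpet = peto2_hx - peto2_bl
    if dpet == 0:
        raise UndefinedCVRError("P_ET_O2 did not change; hypoxic CVR "
                                "is undefined")
    return -100.0 * (cbf_hx - cbf_bl) / cbf_bl / dpet


def cvr_hypoxic_spo2(cbf_bl: float, cbf_hx: float, spo2_bl: float,
                     spo2_hx: float) -> float:
    """Percent CBF change per percentage-point SpO2 *decrease* (%/-%SpO2)."""
    if cbf_bl <= 0:
        raise DataError("baseline CBF must be positive")
    dspo2 = spo2_hx - spo2_bl
    if dspo2 == 0:
        raise UndefinedCVRError("SpO2 did not change; hypoxic CVR "
                                "is undefined")
    return -100.0 * (cbf_hx - cbf_bl) / cbf_bl / dspo2


def correct_for_petco2(delta_ncbf_hx: float, ncbf_bl: float, cvr_hc: float,
                       delta_petco2_hx: float) -> float:
    """Remove the CO2-attributable part of the hypoxic nCBF change.

    The session's hypercapnic CVR predicts the nCBF change caused by the
    unintentional P_ET_CO2 shift during hypoxia; subtracting that estimate
    isolates the purely hypoxic response::

        corrected = delta - ncbf_bl * (cvr_hc / 100) * delta_petco2

    With no concurrent P_ET_CO2 change the correction is the identity.
    """
    return delta_ncbf_hx - ncbf_bl * (cvr_hc / 100.0) * delta_petco2_hx


# ---------------------------------------------------------------------------
# per-session CVR results
# ---------------------------------------------------------------------------


@dataclass
class CVRResult:
    """All CVR metrics for one subject-session."""

    subject: int
    session: int
    ncbf_bl: float
    delta_ncbf_hx: Optional[float] = None
    delta_ncbf_hc: Optional[float] = None
    delta_petco2_hx: Optional[float] = None
    cvr_hc: Optional[float] = None
    cvr_hx_peto2: Optional[float] = None
    cvr_hx_spo2: Optional[float] = None
    delta_ncbf_hx_corrected: Optional[float] = None
    cvr_hx_peto2_corrected: Optional[float] = None
    cvr_hx_spo2_corrected: Optional[float] = None
    response_hx: Optional[str] = None
    response_hc: Optional[str] = None
    substituted: dict = field(default_factory=dict)


def compute_session_cvr(session_cbf: SessionCBF, threshold: float,
                        apply_co2_correction: bool = True) -> CVRResult:
    """CVR metrics for one session from its per-phase steady-state summary.

    Hypoxic metrics need BL and HX; hypercapnic needs BL and HC.  Corrected
    hypoxic metrics are attached only when the session's own hypercapnic CVR
    is available; they never overwrite the uncorrected values.
    """
    s = session_cbf
    if not s.has_phase("BL") or "BL" not in s.physio:
        raise DataError(
            f"subject {s.subject} session {s.session}: no baseline phase; "
            "CVR undefined")
    res = CVRResult(subject=s.subject, session=s.session,
                    ncbf_bl=s.ncbf["BL"], substituted=dict(s.substituted))
    bl_phys = s.physio["BL"]
    if s.has_phase("HC") and "HC" in s.physio:
        res.delta_ncbf_hc = s.ncbf["HC"] - s.ncbf["BL"]
        res.cvr_hc = cvr_hypercapnic(s.ncbf["BL"], s.ncbf["HC"],
                                     bl_phys["petco2"],
                                     s.physio["HC"]["petco2"])
        res.response_hc = classify_response(res.delta_ncbf_hc, threshold)
    if s.has_phase("HX") and "HX" in s.physio:
        hx_phys = s.physio["HX"]
        res.delta_ncbf_hx = s.ncbf["HX"] - s.ncbf["BL"]
        res.delta_petco2_hx = hx_phys["petco2"] - bl_phys["petco2"]
        res.cvr_hx_peto2 = cvr_hypoxic_peto2(
            s.ncbf["BL"], s.ncbf["HX"], bl_phys["peto2"], hx_phys["peto2"])
        if hx_phys["spo2"] != bl_phys["spo2"]:
            res.cvr_hx_spo2 = cvr_hypoxic_spo2(
                s.ncbf["BL"], s.ncbf["HX"], bl_phys["spo2"], hx_phys["spo2"])
        res.response_hx = classify_response(res.delta_ncbf_hx, threshold)
        if apply_co2_correction and res.cvr_hc is not None:
            corr = correct_for_petco2(res.delta_ncbf_hx, s.ncbf["BL"],
                                      res.cvr_hc, res.delta_petco2_hx)
            res.delta_ncbf_hx_corrected = corr
            ncbf_hx_corr = s.ncbf["BL"] + corr
            res.cvr_hx_peto2_corrected = cvr_hypoxic_peto2(
                s.ncbf["BL"], ncbf_hx_corr, bl_phys["peto2"],
                hx_phys["peto2"])
            if hx_phys["spo2"] != bl_phys["spo2"]:
                res.cvr_hx_spo2_corrected = cvr_hypoxic_spo2(
                    s.ncbf["BL"], ncbf_hx_corr, bl_phys["spo2"],
                    hx_phys["spo2"])
    return res


def placement_pair_table(acquisitions: pd.DataFrame) -> pd.DataFrame:
    """Paired placement-1/placement-2 vertebral flows per session and phase.

    Placement-1 flow is the mean over that phase's placement-1 steady
    acquisitions; placement-2 flow likewise (usually a single scan).  Columns:
    subject, session, phase, vessel, p1, p2.
    """
    steady = acquisitions[acquisitions["phase"].isin(STEADY_PHASES)]
    cols = [f"flow_{v}" for v in VERTEBRAL_VESSELS]
    agg = steady.groupby(["subject", "session", "phase", "placement"],
                         sort=False)[cols].mean()
    rows = []
    for vessel in VERTEBRAL_VESSELS:
        wide = agg[f"flow_{vessel}"].unstack("placement")
        if 1 not in wide.columns or 2 not in wide.columns:
            continue
        paired = wide[[1, 2]].dropna().reset_index()
        paired.columns = ["subject", "session", "phase", "p1", "p2"]
        paired.insert(3, "vessel", vessel)
        rows.append(paired)
    if not rows:
        return pd.DataFrame(columns=["subject", "session", "phase", "vessel",
                                     "p1", "p2"])
    return pd.concat(rows, ignore_index=True)


def fit_group_placement_models(acquisitions: pd.DataFrame,
                               pooled: bool = False) -> dict:
    """Fit placement models for each vertebral artery across the group.

    Pairs one placement-2 steady acquisition with the mean of the placement-1
    steady acquisitions of the same phase/session.  With ``pooled`` a single
    model is fitted to both vertebral arteries' pairs and shared.
    """
    pairs = placement_pair_table(acquisitions)
    if pooled:
        model = fit_placement_model(pairs["p1"], pairs["p2"], "VA_pooled")
        return {v: model for v in VERTEBRAL_VESSELS}
    models = {}
    for vessel in VERTEBRAL_VESSELS:
        sub = pairs[pairs["vessel"] == vessel]
        models[vessel] = fit_placement_model(sub["p1"], sub["p2"], vessel)
    return models


def all_session_substitutions(
        acquisitions: pd.DataFrame, models: dict,
        multiplier: float = DEFAULT_OUTLIER_MULTIPLIER,
        residual_sd_floor: float = DEFAULT_RESIDUAL_SD_FLOOR) -> dict:
    """Reconciliation flags for every session: (subject, session) -> flags."""
    pairs = placement_pair_table(acquisitions)
    flags = {}
    for (subject, session), grp in pairs.groupby(["subject", "session"],
                                                 sort=False):
        vessel_flags = {}
        for vessel in VERTEBRAL_VESSELS:
            sub = grp[grp["vessel"] == vessel]
            if sub.empty:
                vessel_flags[vessel] = False
                continue
            vessel_flags[vessel] = reconcile_vertebral_placements(
                models[vessel], sub["p1"], sub["p2"], multiplier=multiplier,
                residual_sd_floor=residual_sd_floor)
        flags[(subject, session)] = vessel_flags
    return flags


def session_substitutions(acquisitions: pd.DataFrame, models: dict,
                          subject: int, session: int,
                          multiplier: float = DEFAULT_OUTLIER_MULTIPLIER,
                          residual_sd_floor: float = DEFAULT_RESIDUAL_SD_FLOOR
                          ) -> dict:
    """Apply the reconciliation rule to one session; vessel -> flag."""
    sess = acquisitions[(acquisitions["subject"] == subject)
                        & (acquisitions["session"] == session)]
    all_flags = all_session_substitutions(
        sess, models, multiplier=multiplier,
        residual_sd_floor=residual_sd_floor)
    return all_flags.get((subject, session),
                         dict.fromkeys(VERTEBRAL_VESSELS, False))
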