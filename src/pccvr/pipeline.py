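"""End-to-end orchestration: quantify, per-session CVR, reliability report.

This is the layer the command-line interface and the analysis drivers call;
each step delegates to the module that owns the computation (``pcflow``,
``physio``, ``cvrcore``, ``reliability``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from . import cvrcore, pcflow, physio, reliability
from .errors import DataError
from .synthgen import STEADY_PHASES, VESSELS, SyntheticStudy

log = logging.getLogger("pccvr")


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis-stage knobs; defaults match the standard workflow."""

    meaningful_change_threshold: Optional[float] = None  # None: derive
    residual_sd_floor: float = cvrcore.DEFAULT_RESIDUAL_SD_FLOOR
    outlier_multiplier: float = cvrcore.DEFAULT_OUTLIER_MULTIPLIER
    apply_co2_correction: bool = True
    icc_variant: str = "single"
    placement_model_pooled: bool = False
    background_correction: str = "constant"

    def validate(self) -> None:
        if self.outlier_multiplier <= 0:
            raise DataError("outlier_multiplier must be positive")
        if self.meaningful_change_threshold is not None \
                and self.meaningful_change_threshold <= 0:
            raise DataError("meaningful_change_threshold must be positive")


def quantify_study(study: SyntheticStudy,
                   options: AnalysisOptions = AnalysisOptions()
                   ) -> pd.DataFrame:
    """Acquisition table with per-vessel flows filled in.

    Flow-fidelity studies pass through unchanged; image-fidelity studies are
    quantified from their cines (background-corrected mean-velocity x area).
    """
    acquisitions = study.acquisitions.copy()
    if study.config.fidelity == "flow":
        return acquisitions
    if not study.cines:
        raise DataError("image-fidelity study has no cines to quantify")
    for i, acq_id in enumerate(acquisitions["acq_id"]):
        if acq_id not in study.cines:
            raise DataError(f"missing cine for acquisition {acq_id}")
        flows = pcflow.quantify_cine(
            study.cines[acq_id], correct_background=True,
            mode=options.background_correction)
        for vessel in VESSELS:
            acquisitions.loc[acquisitions.index[i], f"flow_{vessel}"] = \
                flows[vessel]
    log.info("quantified %d cines", len(acquisitions))
    return acquisitions


@dataclass
class AnalysisResult:
    """Everything the analysis stage produces for one study."""

    cvr_results: pd.DataFrame
    session_cbf: list
    placement_models: dict
    threshold: float
    backtoback: pd.DataFrame
    physio_table: pd.DataFrame
    phase_ncbf: pd.DataFrame
    options: AnalysisOptions = field(default_factory=AnalysisOptions)


_RESULT_COLUMNS = [
    "subject", "session", "ncbf_bl", "delta_ncbf_hx", "delta_ncbf_hc",
    "delta_petco2_hx", "cvr_hc", "cvr_hx_peto2", "cvr_hx_spo2",
    "delta_ncbf_hx_corrected", "cvr_hx_peto2_corrected",
    "cvr_hx_spo2_corrected", "response_hx", "response_hc",
    "substituted_L_VA", "substituted_R_VA",
]


def analyze_study(study: SyntheticStudy,
                  acquisitions: Optional[pd.DataFrame] = None,
                  options: AnalysisOptions = AnalysisOptions()
                  ) -> AnalysisResult:
    """Full CVR analysis of one (quantified) study."""
    options.validate()
    if acquisitions is None:
        acquisitions = quantify_study(study, options)
    physio_table = physio.acquisition_physio_table(study)

    models = cvrcore.fit_group_placement_models(
        acquisitions, pooled=options.placement_model_pooled)
    mass_by_subject = {
        int(row.subject): study.brain_mass_g(int(row.subject))
        for row in study.anatomy.itertuples()}

    backtoback = cvrcore.backtoback_pairs(acquisitions, mass_by_subject)
    if options.meaningful_change_threshold is not None:
        threshold = options.meaningful_change_threshold
    else:
        threshold = cvrcore.meaningful_change_threshold(backtoback["diff"])

    all_subs = cvrcore.all_session_substitutions(
        acquisitions, models, multiplier=options.outlier_multiplier,
        residual_sd_floor=options.residual_sd_floor)
    physio_by_session = dict(iter(physio_table.groupby(
        ["subject", "session"], sort=False)))
    session_cbfs, rows, ncbf_rows = [], [], []
    n_subs = 0
    for (subject, session), sess_acq in acquisitions.groupby(
            ["subject", "session"], sort=False):
        subs = all_subs.get((subject, session),
                            dict.fromkeys(("L_VA", "R_VA"), False))
        n_subs += sum(subs.values())
        scbf = cvrcore.steady_state_cbf(
            sess_acq, physio_by_session[(subject, session)], subject, session,
            mass_by_subject[subject], substitutions=subs)
        session_cbfs.append(scbf)
        for phase in STEADY_PHASES:
            if scbf.has_phase(phase):
                ncbf_rows.append({"subject": subject, "session": session,
                                  "phase": phase, "ncbf": scbf.ncbf[phase]})
        if not scbf.has_phase("BL"):
            log.warning("subject %s session %s: no baseline; skipped",
                        subject, session)
            continue
        if not scbf.has_phase("HC"):
            log.warning("subject %s session %s: hypercapnia absent; "
                        "hypoxic-only outputs, corrected CVR unavailable",
                        subject, session)
        res = cvrcore.compute_session_cvr(
            scbf, threshold, apply_co2_correction=options.apply_co2_correction)
        row = dataclasses.asdict(res)
        subflags = row.pop("substituted")
        row["substituted_L_VA"] = bool(subflags.get("L_VA", False))
        row["substituted_R_VA"] = bool(subflags.get("R_VA", False))
        rows.append(row)
    log.info("analyzed %d sessions; %d vertebral substitutions; "
             "meaningful-change threshold %.3f mL/100 g/min",
             len(rows), n_subs, threshold)
    cvr_results = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    return AnalysisResult(
        cvr_results=cvr_results, session_cbf=session_cbfs,
        placement_models=models, threshold=threshold, backtoback=backtoback,
        physio_table=physio_table,
        phase_ncbf=pd.DataFrame(
            ncbf_rows, columns=["subject", "session", "phase", "ncbf"]),
        options=options)


def metric_matrix(cvr_results: pd.DataFrame, metric: str,
                  sessions=None) -> np.ndarray:
    """Subjects x sessions matrix of one CVR metric (NaN where missing)."""
    wide = cvr_results.pivot_table(index="subject", columns="session",
                                   values=metric, aggfunc="mean")
    if sessions is not None:
        wide = wide.reindex(columns=list(sessions))
    return wide.to_numpy()


RELIABILITY_METRICS = ("cvr_hc", "cvr_hx_peto2", "cvr_hx_spo2",
                       "cvr_hx_peto2_corrected", "cvr_hx_spo2_corrected")


def reliability_report(result: AnalysisResult,
                       icc_variant: str = "single") -> dict:
    """ICCs, variance components, correlations and R^2 for one analysis.

    ``icc`` holds the requested primary variant; ``icc_single`` and
    ``icc_average`` always hold both one-way forms (the average-measures
    ICC(1,k) is the one comparable to agreement coefficients computed on
    session-mean metrics).
    """
    res = result.cvr_results
    sessions = sorted(res["session"].unique())
    report = {"threshold_ml_100g_min": result.threshold, "icc": {},
              "icc_single": {}, "icc_average": {},
              "icc_session_pairs": {}, "variance_components": {},
              "correlations": {}, "r_squared": {}, "backtoback": {},
              "response_counts": {}}

    for metric in RELIABILITY_METRICS:
        if res[metric].notna().sum() < 4:
            continue
        matrix = metric_matrix(res, metric, sessions)
        try:
            for variant in ("single", "average"):
                report[f"icc_{variant}"][metric] = reliability.icc_oneway(
                    matrix, variant=variant)
            report["icc"][metric] = report[f"icc_{icc_variant}"][metric]
        except DataError:
            pass
        pair_iccs = {}
        for pair in combinations(sessions, 2):
            try:
                pair_iccs[f"{pair[0]}-{pair[1]}"] = reliability.icc_oneway(
                    metric_matrix(res, metric, pair), variant=icc_variant)
            except DataError:
                continue
        if pair_iccs:
            report["icc_session_pairs"][metric] = pair_iccs
        long = res[["subject", metric]].dropna().rename(
            columns={metric: "value"})
        try:
            vc = reliability.variance_components(long)
            report["variance_components"][metric] = {
                "inter_subject_sd": vc.inter_subject_sd,
                "inter_session_sd": vc.inter_session_sd,
                "mean": vc.grand_mean, "truncated": vc.truncated}
        except DataError:
            pass

    # concurrent P_ET_CO2 changes vs hypoxic nCBF changes, before/after
    # correction
    for label, col in (("uncorrected", "delta_ncbf_hx"),
                       ("corrected", "delta_ncbf_hx_corrected")):
        sub = res[["delta_petco2_hx", col]].dropna()
        if len(sub) >= 3 and np.ptp(sub[col].to_numpy()) > 0:
            r, p = reliability.pearson_r(sub["delta_petco2_hx"], sub[col])
            report["correlations"][f"petco2_vs_delta_ncbf_{label}"] = {
                "r": r, "p": p, "n": int(len(sub))}

    # shared variance between hypercapnic and hypoxic CVR
    for label, col in (("hx_peto2", "cvr_hx_peto2"),
                       ("hx_spo2", "cvr_hx_spo2"),
                       ("hx_peto2_corrected", "cvr_hx_peto2_corrected"),
                       ("hx_spo2_corrected", "cvr_hx_spo2_corrected")):
        sub = res[["subject", "cvr_hc", col]].dropna()
        try:
            report["r_squared"][f"cvr_hc_vs_{label}"] = \
                reliability.r_squared_mixed(
                    sub["cvr_hc"], sub[col], sub["subject"])
        except DataError:
            continue

    bb = result.backtoback
    if len(bb):
        for phase, grp in bb.groupby("phase"):
            entry = {"n_pairs": int(len(grp)),
                     "median_abs_diff": float(np.median(np.abs(grp["diff"])))}
            if np.any(grp["diff"].to_numpy() != 0):
                stat, p = reliability.wilcoxon_signed_rank(grp["diff"])
                entry["wilcoxon_p"] = p
            pairs = grp[["ncbf_first", "ncbf_second"]].to_numpy()
            if len(pairs) >= 2:
                try:
                    entry["icc_backtoback"] = reliability.icc_oneway(pairs)
                except DataError:
                    pass
            report["backtoback"][phase] = entry

    for stim in ("hx", "hc"):
        col = f"response_{stim}"
        counts = res[col].value_counts(dropna=True).to_dict()
        by_session = {
            int(sess): grp[col].value_counts(dropna=True).to_dict()
            for sess, grp in res.groupby("session")}
        report["response_counts"][stim] = {"overall": counts,
                                           "by_session": by_session}
    return report


def phase_test_table(study: SyntheticStudy,
                     result: AnalysisResult) -> pd.DataFrame:
    """Bonferroni-flagged paired comparisons of each phase with baseline."""
    phys = result.physio_table
    steady = phys[phys["phase"].isin(STEADY_PHASES)
                  & (phys["placement"] == 1)]
    per_phase = steady.groupby(
        ["subject", "session", "phase"],
        as_index=False)[["petco2", "peto2", "ve", "spo2", "hr"]].mean()
    merged = per_phase.merge(result.phase_ncbf,
                             on=["subject", "session", "phase"], how="left")
    return reliability.phase_comparisons(
        merged, variables=("petco2", "peto2", "ve", "spo2", "hr", "ncbf"))
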