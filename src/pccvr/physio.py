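"""Align continuous physiological traces with PC acquisition windows.

End-tidal gases and minute ventilation are averaged over each acquisition's
half-open window [start, start + duration); SpO2 and heart rate are taken as
the sample nearest the scan start, matching how a pulse-oximeter reading is
logged at the beginning of each acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .synthgen import STEADY_PHASES, SyntheticStudy

TRACE_COLUMNS = ("time_s", "petco2_mmHg", "peto2_mmHg", "spo2_pct",
                 "hr_bpm", "ve_L_min")


@dataclass(frozen=True)
class AcquisitionPhysio:
    """Physiological summary of one acquisition window."""

    acq_id: str
    petco2: float
    peto2: float
    ve: float
    spo2: float
    hr: float


def align_acquisition(trace: pd.DataFrame, start: float, duration: float,
                      acq_id: str = "", average_start_values: bool = False
                      ) -> AcquisitionPhysio:
    """Summarize one scan window against a continuous trace.

    The window is half-open: a sample exactly at ``start + duration`` is
    excluded, so adjacent scans never share samples.  With
    ``average_start_values`` the SpO2/HR convention switches from
    nearest-sample-at-start to window means.
    """
    for col in TRACE_COLUMNS:
        if col not in trace.columns:
            raise DataError(f"trace is missing column {col!r}")
    if duration <= 0:
        raise DataError("acquisition duration must be positive")
    t = trace["time_s"].to_numpy()
    in_window = (t >= start) & (t < start + duration)
    n = int(in_window.sum())
    if n == 0:
        raise DataError(
            f"acquisition window [{start}, {start + duration}) lies outside "
            f"the trace support [{t[0]}, {t[-1]}]")
    if n < 2:
        raise DataError(
            f"acquisition window [{start}, {start + duration}) covers only "
            f"{n} trace sample(s); need at least 2")
    window = trace.loc[in_window]
    if average_start_values:
        spo2 = float(window["spo2_pct"].mean())
        hr = float(window["hr_bpm"].mean())
    else:
        nearest = int(np.argmin(np.abs(t - start)))
        spo2 = float(trace["spo2_pct"].iloc[nearest])
        hr = float(trace["hr_bpm"].iloc[nearest])
    return AcquisitionPhysio(
        acq_id=acq_id,
        petco2=float(window["petco2_mmHg"].mean()),
        peto2=float(window["peto2_mmHg"].mean()),
        ve=float(window["ve_L_min"].mean()),
        spo2=spo2, hr=hr)


def acquisition_physio_table(study: SyntheticStudy,
                             average_start_values: bool = False
                             ) -> pd.DataFrame:
    """Per-acquisition physiological summaries for a whole study.

    Same window semantics as :func:`align_acquisition`, vectorized per
    session trace.
    """
    rows = []
    channel_cols = {"petco2": "petco2_mmHg", "peto2": "peto2_mmHg",
                    "ve": "ve_L_min", "spo2": "spo2_pct", "hr": "hr_bpm"}
    for (subject, session), grp in study.acquisitions.groupby(
            ["subject", "session"], sort=False):
        trace = study.trace(subject, session)
        t = trace["time_s"].to_numpy()
        arrays = {name: trace[col].to_numpy()
                  for name, col in channel_cols.items()}
        for acq in grp.itertuples():
            i0 = int(np.searchsorted(t, acq.start_s, "left"))
            i1 = int(np.searchsorted(t, acq.start_s + acq.duration_s, "left"))
            if i1 - i0 < 2:
                raise DataError(
                    f"acquisition {acq.acq_id}: window "
                    f"[{acq.start_s}, {acq.start_s + acq.duration_s}) covers "
                    f"{i1 - i0} trace sample(s); need at least 2")
            if average_start_values:
                spo2 = float(arrays["spo2"][i0:i1].mean())
                hr = float(arrays["hr"][i0:i1].mean())
            else:
                nearest = int(np.argmin(np.abs(t - acq.start_s)))
                spo2 = float(arrays["spo2"][nearest])
                hr = float(arrays["hr"][nearest])
            rows.append({
                "acq_id": acq.acq_id, "subject": subject, "session": session,
                "phase": acq.phase, "placement": acq.placement,
                "petco2": float(arrays["petco2"][i0:i1].mean()),
                "peto2": float(arrays["peto2"][i0:i1].mean()),
                "ve": float(arrays["ve"][i0:i1].mean()),
                "spo2": spo2, "hr": hr})
    return pd.DataFrame(rows)


PHASE_VARIABLES = ("petco2", "peto2", "ve", "spo2", "hr")


def summarize_phases(study: SyntheticStudy,
                     ncbf_by_phase: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group mean +/- SD per steady-state phase, pooling all sessions.

    Only steady-state acquisitions contribute (transition-labelled scans are
    excluded); the initial baseline and the recovery baseline are summarized
    as separate phases.  ``ncbf_by_phase`` (columns subject, session, phase,
    ncbf) may be joined in to add an nCBF row per phase.
    """
    table = acquisition_physio_table(study)
    steady = table[table["phase"].isin(STEADY_PHASES)]
    rows = []
    for phase in STEADY_PHASES:
        sub = steady[steady["phase"] == phase]
        if sub.empty:
            warnings.warn(f"phase {phase} has no steady-state acquisitions; "
                          "omitted from the summary")
            continue
        row = {"phase": phase, "n_acquisitions": len(sub)}
        for var in PHASE_VARIABLES:
            row[f"{var}_mean"] = float(sub[var].mean())
            row[f"{var}_sd"] = float(sub[var].std(ddof=1)) \
                if len(sub) > 1 else 0.0
        if ncbf_by_phase is not None:
            nc = ncbf_by_phase[ncbf_by_phase["phase"] == phase]["ncbf"]
            if len(nc):
                row["ncbf_mean"] = float(nc.mean())
                row["ncbf_sd"] = float(nc.std(ddof=1)) if len(nc) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
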