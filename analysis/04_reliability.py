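#!/usr/bin/env python
"""Reliability and confound analysis of the CVR results.

Computes test-retest ICCs (single- and average-measures, one-way random
effects), inter-subject and inter-session variance components, the
correlation between concurrent P_ET_CO2 changes and hypoxic nCBF changes
before and after correction, and mixed-model coefficients of determination
between hypercapnic and hypoxic CVR.  Writes
results/reliability_report.json.
"""

import json
from pathlib import Path

import pandas as pd

import pccvr

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main():
    study = pccvr.read_study(STUDY)
    flows = pd.read_csv(STUDY / "vessel_flows.csv",
                        float_precision="round_trip")
    result = pccvr.analyze_study(study, acquisitions=flows)
    report = pccvr.reliability_report(result)
    with open(ROOT / "reliability_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)

    print("ICC (average-measures, published style):")
    for metric, value in report["icc_average"].items():
        print(f"  {metric}: {value:.2f}")
    print("variance components (inter-subject / inter-session SD):")
    for metric, vc in report["variance_components"].items():
        print(f"  {metric}: {vc['inter_subject_sd']:.3f} / "
              f"{vc['inter_session_sd']:.3f}")
    for label in ("uncorrected", "corrected"):
        key = f"petco2_vs_delta_ncbf_{label}"
        if key in report["correlations"]:
            c = report["correlations"][key]
            print(f"P_ET_CO2 vs hypoxic dnCBF ({label}): "
                  f"r = {c['r']:.2f}, p = {c['p']:.3f}")


if __name__ == "__main__":
    main()
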