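#!/usr/bin/env python
"""Statistical assessment of the virtual surgeries on the reference data.

Pairs each specimen's states on pooled temperature+humidity average theta
(18 pairs) and runs the exact Wilcoxon signed-rank test; checks the
sibling specimens' concordance by OLS and Pearson correlation. Writes the
full report to results/surgery_stats.json.
"""

import json
from pathlib import Path

from nasalair.profile_io import load_fixture
from nasalair.surgery_stats import (
    pooled_average_theta,
    replicate_concordance,
    state_comparison_report,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def profiles(table_id):
    return [load_fixture(table_id, q) for q in ("temperature", "humidity")]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    report = {
        "subadult_case01": state_comparison_report(
            {"original": profiles("T1"), "operated": profiles("T2")}
        ),
        "adult_case03": state_comparison_report(
            {"original": profiles("T3"), "obstructed": profiles("T4"),
             "operated": profiles("T5")}
        ),
        "adult_case02": state_comparison_report(
            {"original": profiles("T6"), "obstructed": profiles("T7"),
             "operated": profiles("T8")}
        ),
        "sibling_concordance": replicate_concordance(
            pooled_average_theta(profiles("T6")), pooled_average_theta(profiles("T3"))
        ),
    }
    (OUT / "surgery_stats.json").write_text(json.dumps(report, indent=2) + "\n")

    print("Wilcoxon verdicts on pooled average theta (alpha = 0.05):")
    for case in ("subadult_case01", "adult_case03", "adult_case02"):
        for pair, entry in report[case]["pairwise"].items():
            w = entry["wilcoxon"]
            tag = "significant" if w["significant"] else "not significant"
            print(f"  {case} {pair}: p = {w['p_value']:.4f} ({tag})")
    conc = report["sibling_concordance"]
    print(f"\nSibling specimens pooled-theta concordance: "
          f"slope = {conc['slope']:.3f}, r = {conc['pearson_r']:.3f}")
    print(f"full report: {OUT / 'surgery_stats.json'}")


if __name__ == "__main__":
    main()
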