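#!/usr/bin/env python
"""Mesh-convergence quality control on the probe table.

Computes the relative error of each probe value on the coarse and medium
meshes against the finest mesh and reports the convergence verdict at a
2% threshold, plus the percent reduction in RE from coarse to medium.
"""

import json
from pathlib import Path

from nasalair.mesh_qc import convergence_report
from nasalair.profile_io import load_fixture

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    report = convergence_report(load_fixture("T10"), threshold=2.0)
    (OUT / "mesh_convergence.json").write_text(json.dumps(report, indent=2) + "\n")

    print(f"overall pass at {report['threshold_percent']}% threshold: {report['pass']}")
    print(f"{'probe':28s} {'RE coarse':>10s} {'RE medium':>10s} {'reduction':>10s}")
    for name, entry in report["probes"].items():
        re = entry["re_percent"]
        note = "  (" + entry["note"] + ")" if "note" in entry else ""
        print(f"{name:28s} {re['coarse']:>9.2f}% {re['medium']:>9.2f}% "
              f"{entry['re_reduction_coarse_to_medium_percent']:>9.1f}%{note}")
    print(f"full report: {OUT / 'mesh_convergence.json'}")


if __name__ == "__main__":
    main()
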