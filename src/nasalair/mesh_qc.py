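"""Mesh-convergence quality control.

Relative error of a probe value on a coarser mesh against the finest
mesh, RE = |finest - other| / |finest| * 100, and a convergence verdict
over a probe table: per-probe REs, a coarse-to-medium monotone-decrease
flag, the percent reduction in RE, and an overall pass when every
medium-mesh RE sits below the threshold.

Velocity probes are the contractual QC surface; pressure probes printed
as integers near atmospheric cannot be verified from printed precision
and are annotated as such in reports.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .profile_io import MeshProbeTable

PRESSURE_ANNOTATION = "not independently verifiable from printed precision"


def relative_error(finest_value: float, other_value: float) -> float:
    """RE in percent, normalized by the finest-mesh value (asymmetric)."""
    if finest_value == 0:
        raise ZeroDivisionError("finest-mesh value is zero; RE undefined")
    return abs(finest_value - other_value) / abs(finest_value) * 100.0


def convergence_report(table: MeshProbeTable, threshold: float = 2.0) -> dict:
    """Convergence verdict for a mesh probe table.

    Requires at least two non-finest rows (coarse and medium). The overall
    pass requires every medium-mesh RE to be at or below ``threshold`` (%).
    """
    others = table.non_finest()
    if len(others) < 2:
        raise ValidationError("need at least two non-finest mesh rows")
    finest = table.finest
    coarse, medium = others[0], others[-1]
    probes = table.probe_names
    report = {"threshold_percent": threshold, "probes": {}, "mesh_labels": [r["mesh_label"] for r in table.rows]}
    all_pass = True
    for name in probes:
        f = finest["probes"][name]
        re_by_mesh = {
            row["mesh_label"]: relative_error(f, row["probes"][name]) for row in others
        }
        re_coarse = re_by_mesh[coarse["mesh_label"]]
        re_medium = re_by_mesh[medium["mesh_label"]]
        decreasing = re_medium <= re_coarse
        reduction = (
            100.0 * (re_coarse - re_medium) / re_coarse if re_coarse > 0 else 0.0
        )
        entry = {
            "re_percent": {k: round(v, 2) for k, v in re_by_mesh.items()},
            "re_percent_raw": re_by_mesh,
            "monotone_decrease": bool(decreasing),
            "re_reduction_coarse_to_medium_percent": reduction,
            "pass": bool(re_medium <= threshold),
        }
        if "pressure" in name:
            entry["note"] = PRESSURE_ANNOTATION
        report["probes"][name] = entry
        all_pass = all_pass and entry["pass"]
    report["pass"] = bool(all_pass)
    velocity = [n for n in probes if "velocity" in n]
    report["velocity_monotone_decrease"] = bool(
        all(report["probes"][n]["monotone_decrease"] for n in velocity)
    )
    return report
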