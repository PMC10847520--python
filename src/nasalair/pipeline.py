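"""End-to-end orchestration: standardize -> average -> fit -> compare ->
stats -> mesh QC, driven by one flat configuration mapping.

The canonical report payload is deterministic for a given configuration
and seed (no timestamps), so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import mesh_qc, profile_io, standardize, surgery_stats, synthetic_airway
from .errors import ConfigError

KNOWN_KEYS = {"simulate", "inputs", "fixtures", "stats", "mesh_qc", "output"}


def _load_state_profiles(config) -> dict:
    """Resolve the configured data source into {state: [ProfileSet, ...]}."""
    sources = [k for k in ("simulate", "inputs", "fixtures") if k in config]
    if len(sources) != 1:
        raise ConfigError(
            "exactly one of 'simulate', 'inputs' or 'fixtures' must be configured"
        )
    source = sources[0]
    if source == "simulate":
        sim = dict(config["simulate"])
        seed = int(sim.pop("seed", 0))
        noise = float(sim.pop("noise_sigma", 0.0))
        blockage = float(sim.pop("blockage_fraction", 0.7))
        slice_number = int(sim.pop("slice", 2))
        if sim:
            raise ConfigError(f"unknown simulate keys: {sorted(sim)}")
        geom = synthetic_airway.make_geometry()
        obstruction = synthetic_airway.obstruction_at_slice(geom, slice_number, blockage)
        flow = synthetic_airway.FlowConditions(noise_sigma=noise)
        bundle = synthetic_airway.generate_study(
            seed=seed, obstruction=obstruction, geometry=geom, flow=flow
        )
        states = {}
        for (state, _q), prof in bundle.items():
            states.setdefault(state, []).append(prof)
        return states
    if source == "fixtures":
        states = {}
        for table_id in config["fixtures"]:
            _specimen, state = profile_io.FIXTURE_META[table_id]
            states[state] = [
                profile_io.load_fixture(table_id, q) for q in ("temperature", "humidity")
            ]
        return states
    states = {}
    for state, paths in config["inputs"].items():
        profs = []
        for quantity, path in paths.items():
            profs.append(
                profile_io.read_profile_csv(
                    path, value_kind="standardized_theta", state=state, quantity=quantity
                )
            )
        states[state] = profs
    return states


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages and return the canonical report."""
    if not isinstance(config, dict) or not config:
        raise ConfigError("empty configuration")
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    states = _load_state_profiles(config)
    for state, profs in states.items():
        states[state] = [standardize.average_scenarios(p) for p in profs]

    stats_cfg = dict(config.get("stats") or {})
    alpha = float(stats_cfg.pop("alpha", 0.05))
    if stats_cfg:
        raise ConfigError(f"unknown stats keys: {sorted(stats_cfg)}")
    report = {"comparison": surgery_stats.state_comparison_report(states, alpha=alpha)}

    if "mesh_qc" in config:
        qc = dict(config["mesh_qc"])
        threshold = float(qc.pop("threshold", 2.0))
        path = qc.pop("path", None)
        if qc:
            raise ConfigError(f"unknown mesh_qc keys: {sorted(qc)}")
        table = (
            profile_io.load_fixture("T10")
            if path is None
            else profile_io.read_mesh_probe_csv(path)
        )
        report["mesh_qc"] = mesh_qc.convergence_report(table, threshold=threshold)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        for state, profs in states.items():
            for p in profs:
                profile_io.write_profile_csv(p, outdir / f"{state}_{p.quantity}.csv")
    return report
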