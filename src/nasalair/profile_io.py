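"""Domain types, CSV readers/writers and embedded reference tables.

The package's canonical container is the :class:`ProfileSet`: per-slice
distances along the nasopharyngeal tract plus one value column per
environmental scenario (and their average) for a single specimen state
and quantity (temperature or humidity). Values are either raw physical
units or the dimensionless theta used throughout the analysis.

Eight standardized profile tables (three lion specimens in original,
obstructed and operated states) and one mesh-convergence probe table are
shipped verbatim as in-package CSV fixtures; they are the ground truth the
test-suite checks the pipeline against.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .humidity import absolute_humidity

MINUS_SIGN = "−"  # typographic minus, normalized to ASCII on read

#: nostril-to-choana tract length per specimen, mm
TRACT_LENGTH_MM = {
    "ZPB_PL_001": 80.28,
    "ZPB_PL_002": 155.57,
    "ZPB_PL_003": 157.24,
}

#: obstructive-material dimensions per specimen (length, width in mm;
#: surface mm^2; volume mm^3)
OBSTRUCTION_MATERIAL = {
    "ZPB_PL_001": {"length_mm": 18.95, "width_mm": 6.98, "surface_mm2": 336.49, "volume_mm3": 695.55},
    "ZPB_PL_002": {"length_mm": 26.66, "width_mm": 19.4, "surface_mm2": 763.85, "volume_mm3": 984.11},
    "ZPB_PL_003": {"length_mm": 21.23, "width_mm": 19.21, "surface_mm2": 610.92, "volume_mm3": 856.89},
}

TEMPERATURE_SCENARIOS = ("temp_28_60", "temp_40_05", "temp_05_10")
HUMIDITY_SCENARIOS = ("hum_28_60", "hum_40_05", "hum_05_10")

_INLET_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioConditions:
    """One environmental simulation case plus the airway-wall reference.

    The wall (body) side defaults to core conditions of 38.5 degC at
    saturation; the ambient side is the inhaled atmosphere. Derived
    absolute humidities (kg/m^3) feed the humidity standardization.
    """

    ambient_temp: float
    ambient_rh: float
    wall_temp: float = 38.5
    wall_rh: float = 100.0
    label: str = ""

    def __post_init__(self):
        for name, rh in (("ambient_rh", self.ambient_rh), ("wall_rh", self.wall_rh)):
            if not 0.0 <= rh <= 100.0:
                raise ValidationError(f"{name} must lie in [0, 100], got {rh}")

    @property
    def ambient_abs_humidity(self) -> float:
        return absolute_humidity(self.ambient_temp, self.ambient_rh)

    @property
    def wall_abs_humidity(self) -> float:
        return absolute_humidity(self.wall_temp, self.wall_rh)

    def references(self, quantity: str) -> tuple[float, float]:
        """(wall, external) reference pair for ``quantity``."""
        if quantity == "temperature":
            return self.wall_temp, self.ambient_temp
        if quantity == "humidity":
            return self.wall_abs_humidity, self.ambient_abs_humidity
        raise ValidationError(f"unknown quantity {quantity!r}")


#: the three environmental scenarios used in every simulation:
#: temperate forest, warm desert, cold high mountain
DEFAULT_SCENARIOS = (
    ScenarioConditions(28.0, 60.0, label="28_60"),
    ScenarioConditions(40.0, 5.0, label="40_05"),
    ScenarioConditions(5.0, 10.0, label="05_10"),
)


@dataclass
class ProfileSet:
    """Per-slice profile values for one specimen state and quantity."""

    specimen_id: str
    state: str  # original | obstructed | operated
    quantity: str  # temperature | humidity
    value_kind: str  # raw_physical | standardized_theta
    slice_index: np.ndarray  # int, >= 1
    distance: np.ndarray  # normalized d* in [0, 1]
    scenario_names: tuple[str, ...]
    values: np.ndarray  # shape (n_slices, n_scenarios)
    average: np.ndarray  # shape (n_slices,)

    def __post_init__(self):
        self.slice_index = np.asarray(self.slice_index, dtype=int)
        self.distance = np.asarray(self.distance, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.average = np.asarray(self.average, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.slice_index)
        if n < 3:
            raise ValidationError(f"need at least 3 slices, got {n}")
        if len(np.unique(self.slice_index)) != n:
            raise ValidationError("duplicate slice indices")
        if self.distance.shape != (n,) or self.average.shape != (n,):
            raise ValidationError("distance/average length mismatch")
        if self.values.shape != (n, len(self.scenario_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} slices x {len(self.scenario_names)} scenarios"
            )
        if np.any(np.diff(self.distance) <= 0):
            raise ValidationError("slice distances must be strictly increasing")
        if abs(self.distance[0]) > 1e-12 or abs(self.distance[-1] - 1.0) > 1e-12:
            raise ValidationError("normalized distances must run from 0 to 1")
        if self.state not in ("original", "obstructed", "operated"):
            raise ValidationError(f"unknown state {self.state!r}")
        if self.quantity not in ("temperature", "humidity"):
            raise ValidationError(f"unknown quantity {self.quantity!r}")
        if self.value_kind not in ("raw_physical", "standardized_theta"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "standardized_theta":
            inlet = self.values[0]
            if np.any(np.abs(inlet + 1.0) > _INLET_TOL):
                raise ValidationError(
                    f"standardized inlet values must equal -1 exactly, got {inlet}"
                )

    @property
    def n_slices(self) -> int:
        return len(self.slice_index)

    def with_average(self, average: np.ndarray) -> "ProfileSet":
        return replace(self, average=np.asarray(average, dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"slice": self.slice_index, "distance": self.distance})
        for j, name in enumerate(self.scenario_names):
            df[name] = self.values[:, j]
        df["average"] = self.average
        return df


@dataclass
class MeshProbeTable:
    """Probe velocities/pressures per mesh resolution for convergence QC."""

    rows: list  # list of dicts: mesh_label, n_elements, probes: {name: value}
    printed_re: dict = field(default_factory=dict)  # (mesh_label, probe) -> %

    def __post_init__(self):
        labels = [r["mesh_label"] for r in self.rows]
        if labels.count("finest") != 1:
            raise ValidationError("exactly one row must be labeled 'finest'")
        order = sorted(self.rows, key=lambda r: r["n_elements"])
        counts = [r["n_elements"] for r in order]
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValidationError("element counts must be strictly increasing")
        if order[-1]["mesh_label"] != "finest":
            raise ValidationError("the finest row must have the most elements")
        self.rows = order

    @property
    def finest(self) -> dict:
        return self.rows[-1]

    @property
    def probe_names(self) -> list[str]:
        return list(self.finest["probes"].keys())

    def non_finest(self) -> list[dict]:
        return self.rows[:-1]


# ---------------------------------------------------------------------------
# CSV input/output


def _clean_numeric(raw: str) -> float:
    text = str(raw).strip().replace(MINUS_SIGN, "-")
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"cell {raw!r} is not numeric") from exc


def normalize_distances_inplace(distances: np.ndarray) -> np.ndarray:
    """Divide raw distances (mm) by the last slice's distance (dc)."""
    if distances[0] != 0.0:
        raise ValidationError("first slice distance must be 0")
    return distances / distances[-1]


def read_profile_csv(
    path,
    value_kind: str = "standardized_theta",
    specimen_id: str = "",
    state: str = "original",
    quantity: Optional[str] = None,
) -> ProfileSet:
    """Read a profile CSV (``slice,distance,<scenarios...>,average``).

    Distances greater than 1 at the last slice are taken to be raw mm and
    are normalized by the nostril-choana length dc (the last slice).
    Typographic minus signs are accepted and normalized.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise ParseError(f"cannot read {path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    if "slice" not in cols or "distance" not in cols or "average" not in cols:
        raise ParseError(f"missing required columns in {path}: have {cols}")
    df.columns = cols
    scen = tuple(c for c in cols if c not in ("slice", "distance", "average"))
    if not scen:
        raise ParseError("no scenario columns found")
    try:
        slice_idx = df["slice"].map(_clean_numeric).astype(int).to_numpy()
    except ParseError:
        raise
    if len(slice_idx) != len(set(slice_idx)):
        raise ParseError("duplicate slice indices in file")
    if len(slice_idx) < 3:
        raise ValidationError(f"need at least 3 slices, got {len(slice_idx)}")
    dist = df["distance"].map(_clean_numeric).to_numpy()
    if np.any(np.diff(dist) <= 0):
        raise ValidationError("distances are not strictly increasing")
    if abs(dist[-1] - 1.0) > 1e-9:  # raw mm input: rescale by dc
        dist = normalize_distances_inplace(dist)
    values = np.column_stack([df[c].map(_clean_numeric).to_numpy() for c in scen])
    avg = df["average"].map(_clean_numeric).to_numpy()
    if quantity is None:
        quantity = "humidity" if scen[0].startswith("hum") else "temperature"
    return ProfileSet(
        specimen_id=specimen_id,
        state=state,
        quantity=quantity,
        value_kind=value_kind,
        slice_index=slice_idx,
        distance=dist,
        scenario_names=scen,
        values=values,
        average=avg,
    )


def format_profile_csv(profile: ProfileSet) -> str:
    """Canonical 4-decimal CSV serialization (ASCII minus, dot decimal)."""
    buf = io.StringIO()
    header = ["slice", "distance", *profile.scenario_names, "average"]
    buf.write(",".join(header) + "\n")
    for i in range(profile.n_slices):
        cells = [str(int(profile.slice_index[i])), f"{profile.distance[i]:.4f}"]
        cells += [f"{v:.4f}" for v in profile.values[i]]
        cells.append(f"{profile.average[i]:.4f}")
        buf.write(",".join(cells) + "\n")
    return buf.getvalue()


def write_profile_csv(profile: ProfileSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(format_profile_csv(profile))


def read_mesh_probe_csv(path) -> MeshProbeTable:
    """Read a long-format probe CSV (``mesh_label,n_elements,probe,value``)."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    required = {"mesh_label", "n_elements", "probe", "value"}
    if not required.issubset(df.columns):
        raise ParseError(f"probe CSV needs columns {sorted(required)}")
    rows: dict[str, dict] = {}
    printed: dict[tuple[str, str], float] = {}
    for _, rec in df.iterrows():
        label = rec["mesh_label"].strip()
        row = rows.setdefault(
            label,
            {"mesh_label": label, "n_elements": float(_clean_numeric(rec["n_elements"])), "probes": {}},
        )
        row["probes"][rec["probe"].strip()] = _clean_numeric(rec["value"])
        re_col = rec.get("re_percent_printed")
        if isinstance(re_col, str) and re_col.strip():
            printed[(label, rec["probe"].strip())] = _clean_numeric(re_col)
    return MeshProbeTable(rows=list(rows.values()), printed_re=printed)


# ---------------------------------------------------------------------------
# Embedded fixtures

#: table id -> (specimen, state)
FIXTURE_META = {
    "T1": ("ZPB_PL_001", "original"),
    "T2": ("ZPB_PL_001", "operated"),
    "T3": ("ZPB_PL_003", "original"),
    "T4": ("ZPB_PL_003", "obstructed"),
    "T5": ("ZPB_PL_003", "operated"),
    "T6": ("ZPB_PL_002", "original"),
    "T7": ("ZPB_PL_002", "obstructed"),
    "T8": ("ZPB_PL_002", "operated"),
}

PROFILE_FIXTURE_IDS = tuple(FIXTURE_META)
ALL_FIXTURE_IDS = PROFILE_FIXTURE_IDS + ("T10",)


def _data_path(name: str):
    return resources.files("nasalair.data").joinpath(name)


def fixture_csv_text(table_id: str, quantity: str = "temperature") -> str:
    """Raw CSV text of a shipped fixture (canonical serialization)."""
    if table_id == "T10":
        name = "T10_mesh.csv"
    else:
        name = f"{table_id}_{quantity}.csv"
    return _data_path(name).read_text(encoding="utf-8")


def load_fixture(table_id: str, quantity: str = "temperature"):
    """Load a shipped reference table as typed data.

    ``T1``..``T8`` return a :class:`ProfileSet` for the requested quantity
    (temperature or humidity); ``T10`` returns the :class:`MeshProbeTable`.
    """
    if table_id == "T10":
        with resources.as_file(_data_path("T10_mesh.csv")) as p:
            return read_mesh_probe_csv(p)
    if table_id not in FIXTURE_META:
        raise KeyError(f"unknown fixture table {table_id!r}")
    if quantity not in ("temperature", "humidity"):
        raise ValidationError(f"unknown quantity {quantity!r}")
    specimen, state = FIXTURE_META[table_id]
    with resources.as_file(_data_path(f"{table_id}_{quantity}.csv")) as p:
        return read_profile_csv(
            p,
            value_kind="standardized_theta",
            specimen_id=specimen,
            state=state,
            quantity=quantity,
        )


def iter_profile_fixtures():
    """Yield (table_id, quantity, ProfileSet) for all 16 profile fixtures."""
    for table_id in PROFILE_FIXTURE_IDS:
        for quantity in ("temperature", "humidity"):
            yield table_id, quantity, load_fixture(table_id, quantity)
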