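"""Reduced-order nasal-duct simulator.

Stands in for the 3-D CFD stage: a quasi-1D variable-geometry duct in
which the bulk air state x (temperature or absolute humidity) relaxes
toward the wall value along the tract,

    dx/ds = -(k P(s) / Q) (x - x_wall),      x(0) = ambient,

integrated exactly (exponential) across segments of constant properties.
In dimensionless form theta(d*) decays from -1 toward 0, which is the
acclimatization signature the downstream analysis expects. An obstruction
scales a station's cross-section area and wetted perimeter by
(1 - blockage_fraction); the reduced perimeter lowers local exchange and
delays acclimatization, while the reduced area raises local velocity Q/A.

The generator produces study bundles shaped like the reference tables:
9 slices from nares (theta = -1 exactly) to choana, three environmental
scenarios per quantity, original/obstructed/operated states, optional
Gaussian theta noise (inlet kept exact, values clipped to [-1, 0]).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import DegenerateScenarioError, ValidationError
from .profile_io import DEFAULT_SCENARIOS, ProfileSet, ScenarioConditions, TRACT_LENGTH_MM
from .standardize import invert_theta

# default duct: adult specimen tract length, turbinate-rich cross-section
DEFAULT_DC_MM = TRACT_LENGTH_MM["ZPB_PL_003"]
DEFAULT_AREA_MM2 = 400.0
DEFAULT_PERIMETER_MM = 300.0
DEFAULT_Q_LPM = 15.0

# Exchange coefficient calibrated so the unobstructed default duct reaches
# theta = -0.25 at slice 2 (d* = 1/8), the scale of the healthy reference
# tables: k P dc / Q = ln(4) / 0.125.
DEFAULT_K = (
    (np.log(4.0) / 0.125)
    * (DEFAULT_Q_LPM / 60000.0)
    / ((DEFAULT_PERIMETER_MM / 1000.0) * (DEFAULT_DC_MM / 1000.0))
)


@dataclass(frozen=True)
class Obstruction:
    """Axial extent (mm) and severity of a blockage."""

    start_mm: float
    end_mm: float
    blockage_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.blockage_fraction < 1.0:
            raise ValidationError("blockage_fraction must lie in [0, 1)")
        if self.end_mm < self.start_mm:
            raise ValidationError("obstruction end precedes start")


@dataclass(frozen=True)
class FlowConditions:
    """Volumetric flow, exchange coefficient and theta-noise level."""

    q_lpm: float = DEFAULT_Q_LPM
    k: float = DEFAULT_K  # m/s, calibration constant
    noise_sigma: float = 0.0  # theta units
    seed: Optional[int] = None

    def __post_init__(self):
        if self.q_lpm <= 0 or self.k <= 0 or self.noise_sigma < 0:
            raise ValidationError("need q_lpm > 0, k > 0, noise_sigma >= 0")

    @property
    def q_m3s(self) -> float:
        return self.q_lpm / 60000.0


@dataclass(frozen=True)
class AirwayGeometry:
    """Discretized duct: station positions with area/perimeter, plus an
    optional obstruction that scales the affected stations."""

    s_mm: np.ndarray
    area_mm2: np.ndarray
    perimeter_mm: np.ndarray
    obstruction: Optional[Obstruction] = None

    def __post_init__(self):
        object.__setattr__(self, "s_mm", np.asarray(self.s_mm, dtype=float))
        object.__setattr__(self, "area_mm2", np.asarray(self.area_mm2, dtype=float))
        object.__setattr__(self, "perimeter_mm", np.asarray(self.perimeter_mm, dtype=float))
        s = self.s_mm
        if s[0] != 0.0 or np.any(np.diff(s) <= 0):
            raise ValidationError("station positions must increase strictly from 0")
        if np.any(self.area_mm2 <= 0) or np.any(self.perimeter_mm <= 0):
            raise ValidationError("area and perimeter must be positive")
        if self.obstruction is not None:
            ob = self.obstruction
            if ob.start_mm < 0 or ob.end_mm > self.dc_mm:
                raise ValidationError("obstruction lies outside [0, dc]")

    @property
    def dc_mm(self) -> float:
        return float(self.s_mm[-1])

    @property
    def n_stations(self) -> int:
        return len(self.s_mm)

    def _mask(self) -> np.ndarray:
        if self.obstruction is None:
            return np.zeros(self.n_stations, dtype=bool)
        return (self.s_mm >= self.obstruction.start_mm) & (
            self.s_mm <= self.obstruction.end_mm
        )

    @property
    def effective_area_mm2(self) -> np.ndarray:
        scale = np.where(self._mask(), 1.0 - self.obstruction.blockage_fraction, 1.0) \
            if self.obstruction else 1.0
        return self.area_mm2 * scale

    @property
    def effective_perimeter_mm(self) -> np.ndarray:
        scale = np.where(self._mask(), 1.0 - self.obstruction.blockage_fraction, 1.0) \
            if self.obstruction else 1.0
        return self.perimeter_mm * scale

    def with_obstruction(self, obstruction: Obstruction) -> "AirwayGeometry":
        return replace(self, obstruction=obstruction)

    def without_obstruction(self) -> "AirwayGeometry":
        """Remove the obstruction; restores the base geometry exactly."""
        return replace(self, obstruction=None)

    def local_velocity_ms(self, flow: FlowConditions) -> np.ndarray:
        """Bulk velocity Q/A per station (m/s); rises inside an obstruction."""
        return flow.q_m3s / (self.effective_area_mm2 * 1e-6)


def make_geometry(
    n_segments: int = 9,
    dc_mm: float = DEFAULT_DC_MM,
    area_profile: str = "uniform",
    obstruction: Optional[Obstruction] = None,
    area_mm2: float = DEFAULT_AREA_MM2,
    perimeter_mm: float = DEFAULT_PERIMETER_MM,
) -> AirwayGeometry:
    """Build a duct with ``n_segments`` equidistant stations from 0 to dc.

    ``area_profile='tapered'`` tapers area and perimeter linearly from
    125% at the nares to 75% at the choana, mimicking the narrowing tract.
    """
    if n_segments < 9:
        raise ValidationError("need at least 9 stations (inlet through choana)")
    if dc_mm <= 0:
        raise ValidationError("dc must be positive")
    s = np.linspace(0.0, dc_mm, n_segments)
    if area_profile == "uniform":
        area = np.full(n_segments, area_mm2)
        per = np.full(n_segments, perimeter_mm)
    elif area_profile == "tapered":
        taper = np.linspace(1.25, 0.75, n_segments)
        area = area_mm2 * taper
        per = perimeter_mm * taper
    else:
        raise ValidationError(f"unknown area_profile {area_profile!r}")
    return AirwayGeometry(s_mm=s, area_mm2=area, perimeter_mm=per, obstruction=obstruction)


def obstruction_at_slice(
    geom: AirwayGeometry, slice_number: int = 2, blockage_fraction: float = 0.7
) -> Obstruction:
    """An obstruction spanning exactly one station (1-based slice number)."""
    i = slice_number - 1
    if not 0 < i < geom.n_stations:
        raise ValidationError("slice_number outside the duct")
    half = 0.25 * min(
        geom.s_mm[i] - geom.s_mm[i - 1],
        (geom.s_mm[i + 1] - geom.s_mm[i]) if i + 1 < geom.n_stations else np.inf,
    )
    return Obstruction(geom.s_mm[i] - half, geom.s_mm[i] + half, blockage_fraction)


def _theta_profile(geom: AirwayGeometry, flow: FlowConditions) -> np.ndarray:
    """Noise-free theta at each station; exact per-segment exponential."""
    s = geom.s_mm / 1000.0
    per = geom.effective_perimeter_mm / 1000.0
    theta = np.empty(geom.n_stations)
    theta[0] = -1.0
    for j in range(1, geom.n_stations):
        decay = np.exp(-flow.k * per[j] * (s[j] - s[j - 1]) / flow.q_m3s)
        theta[j] = theta[j - 1] * decay
    return theta


def _add_noise(theta: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return theta
    noise = rng.normal(0.0, sigma, theta.shape)
    noise[0] = 0.0  # inlet theta stays exactly -1
    return np.clip(theta + noise, -1.0, 0.0)


def simulate_acclimatization(
    geom: AirwayGeometry,
    scenario: ScenarioConditions,
    flow: FlowConditions,
    quantity: str = "temperature",
    rng: Optional[np.random.Generator] = None,
) -> ProfileSet:
    """Simulate one scenario; returns a raw-physical ProfileSet."""
    wall, ext = scenario.references(quantity)
    if wall == ext:
        raise DegenerateScenarioError("wall equals ambient; nothing to exchange")
    theta = _theta_profile(geom, flow)
    if flow.noise_sigma > 0:
        theta = _add_noise(theta, flow.noise_sigma, rng or np.random.default_rng(flow.seed))
    phys = invert_theta(theta, wall, ext)
    name = ("temp_" if quantity == "temperature" else "hum_") + (scenario.label or "scn")
    return ProfileSet(
        specimen_id="synthetic",
        state="original",
        quantity=quantity,
        value_kind="raw_physical",
        slice_index=np.arange(1, geom.n_stations + 1),
        distance=geom.s_mm / geom.dc_mm,
        scenario_names=(name,),
        values=theta_to_values(theta, wall, ext),
        average=phys,
    )


def theta_to_values(theta: np.ndarray, wall: float, ext: float) -> np.ndarray:
    return invert_theta(theta, wall, ext)[:, None]


def _standardized_profile(
    geom: AirwayGeometry,
    scenarios,
    flow: FlowConditions,
    quantity: str,
    state: str,
    rng: np.random.Generator,
) -> ProfileSet:
    base = _theta_profile(geom, flow)
    cols = []
    for _ in scenarios:
        cols.append(_add_noise(base, flow.noise_sigma, rng))
    values = np.column_stack(cols)
    prefix = "temp_" if quantity == "temperature" else "hum_"
    return ProfileSet(
        specimen_id="synthetic",
        state=state,
        quantity=quantity,
        value_kind="standardized_theta",
        slice_index=np.arange(1, geom.n_stations + 1),
        distance=geom.s_mm / geom.dc_mm,
        scenario_names=tuple(prefix + sc.label for sc in scenarios),
        values=values,
        average=values.mean(axis=1),
    )


def generate_study(
    seed: int = 0,
    obstruction: Optional[Obstruction] = None,
    scenarios=DEFAULT_SCENARIOS,
    geometry: Optional[AirwayGeometry] = None,
    flow: FlowConditions = FlowConditions(),
) -> dict:
    """Generate the full virtual-surgery study bundle.

    Returns ``{(state, quantity): ProfileSet}`` of standardized theta for
    states original/obstructed/operated and both quantities. The operated
    state is the obstructed duct with the obstruction removed, which
    restores the original geometry exactly; with ``noise_sigma = 0`` the
    operated profiles are therefore bit-identical to the originals.
    Deterministic for a given seed.
    """
    geom = geometry or make_geometry()
    if obstruction is None:
        obstruction = obstruction_at_slice(geom, slice_number=2, blockage_fraction=0.7)
    duct = {
        "original": geom.without_obstruction(),
        "obstructed": geom.with_obstruction(obstruction),
        "operated": geom.with_obstruction(obstruction).without_obstruction(),
    }
    children = np.random.SeedSequence(seed).spawn(6)
    bundle = {}
    i = 0
    for state in ("original", "obstructed", "operated"):
        for quantity in ("temperature", "humidity"):
            rng = np.random.default_rng(children[i])
            i += 1
            bundle[(state, quantity)] = _standardized_profile(
                duct[state], scenarios, flow, quantity, state, rng
            )
    return bundle
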