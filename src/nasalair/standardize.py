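"""Similarity transformation of airway profiles.

Physical temperature/absolute-humidity profiles are made dimensionless with

    theta = (x - x_wall) / (x_wall - x_external)

so that theta = -1 where the air is still at ambient (inlet) conditions and
theta = 0 once it has fully equilibrated with the airway wall. Distances are
normalized by the nostril-to-choana length dc, d* = d/dc in [0, 1]. Profiles
from different specimens and environmental scenarios then collapse onto a
single acclimatization curve.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateScenarioError, ValidationError
from .humidity import HumidityModel, absolute_humidity  # re-export
from .profile_io import ProfileSet, ScenarioConditions

__all__ = [
    "normalize_distance",
    "compute_theta",
    "invert_theta",
    "absolute_humidity",
    "HumidityModel",
    "average_scenarios",
    "standardize_profile",
    "audit_printed_averages",
    "round_half_even",
]


def normalize_distance(distances) -> np.ndarray:
    """Rescale raw distances (mm from the nares) to d* = d/dc in [0, 1]."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValidationError("need at least two distances")
    if d[0] != 0.0:
        raise ValidationError("first distance must be 0 (at the nares)")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    if np.any(np.diff(d) <= 0):
        raise ValidationError("distances must be strictly increasing")
    out = d / d[-1]
    out[-1] = 1.0
    return out


def _check_references(wall_value: float, external_value: float) -> None:
    if wall_value == external_value:
        raise DegenerateScenarioError(
            "wall and external reference values coincide; theta is undefined"
        )


def compute_theta(value, wall_value: float, external_value: float):
    """Dimensionless theta = (value - wall) / (wall - external).

    -1 when the value equals the external (ambient) reference, 0 when the
    value equals the wall (body) reference.
    """
    _check_references(wall_value, external_value)
    v = np.asarray(value, dtype=float)
    theta = (v - wall_value) / (wall_value - external_value)
    return float(theta) if theta.ndim == 0 else theta


def invert_theta(theta, wall_value: float, external_value: float):
    """Physical value from theta; exact inverse of :func:`compute_theta`."""
    _check_references(wall_value, external_value)
    t = np.asarray(theta, dtype=float)
    v = wall_value + t * (wall_value - external_value)
    return float(v) if v.ndim == 0 else v


def average_scenarios(profile: ProfileSet) -> ProfileSet:
    """Recompute the average column as the mean over scenario columns."""
    if profile.values.shape[1] < 1:
        raise ValidationError("profile has no scenario columns")
    return profile.with_average(profile.values.mean(axis=1))


def standardize_profile(
    profile: ProfileSet, scenarios: tuple[ScenarioConditions, ...]
) -> ProfileSet:
    """Convert a raw-physical ProfileSet to standardized theta.

    One ScenarioConditions per scenario column supplies the wall/external
    reference pair appropriate to the profile's quantity. The average column
    is recomputed from the standardized scenarios.
    """
    if profile.value_kind != "raw_physical":
        raise ValidationError("profile is already standardized")
    if len(scenarios) != len(profile.scenario_names):
        raise ValidationError(
            f"{len(profile.scenario_names)} scenario columns but "
            f"{len(scenarios)} scenario conditions"
        )
    theta = np.empty_like(profile.values)
    for j, sc in enumerate(scenarios):
        wall, ext = sc.references(profile.quantity)
        theta[:, j] = compute_theta(profile.values[:, j], wall, ext)
    out = ProfileSet(
        specimen_id=profile.specimen_id,
        state=profile.state,
        quantity=profile.quantity,
        value_kind="standardized_theta",
        slice_index=profile.slice_index,
        distance=profile.distance,
        scenario_names=profile.scenario_names,
        values=theta,
        average=theta.mean(axis=1),
    )
    return out


def round_half_even(x, decimals: int = 4):
    """Half-even rounding used for comparisons against 4-decimal tables."""
    return np.round(np.asarray(x, dtype=float), decimals)


def audit_printed_averages(profile: ProfileSet, tol: float = 0.00005):
    """Compare the stored average column against the recomputed mean.

    Returns a list of ``(slice_index, recomputed, printed)`` records for
    cells where the stored (printed) average disagrees with the mean of the
    stored scenario cells by more than ``tol``. Reference tables printed at
    four decimals occasionally carry averages computed from unrounded solver
    output; those cells are reported here rather than silently accepted.
    """
    recomputed = profile.values.mean(axis=1)
    mismatches = []
    for i in range(profile.n_slices):
        if abs(recomputed[i] - profile.average[i]) > tol:
            mismatches.append(
                (int(profile.slice_index[i]), float(recomputed[i]), float(profile.average[i]))
            )
    return mismatches
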