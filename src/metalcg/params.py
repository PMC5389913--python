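"""Shared configuration: per-metal shell parameters and detection constants.

The per-metal defaults (initial and updated distance cutoffs, most-abundant
element statistics, carbon distance mode, element whitelist, small-angle
removal cutoff and the compressed/normal training band) ship in
``data/metal_params.yaml`` and can be overridden by a user YAML file of the
same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["MetalParams", "DetectionConfig", "load_metal_params", "DEFAULT_METALS"]

DEFAULT_METALS = ("Zn", "Mg", "Ca", "Fe", "Na")


@dataclass(frozen=True)
class MetalParams:
    """Shell cutoffs and bond-length defaults for one metal element."""

    metal: str
    atomic_radius_pm: float
    initial_upper: float
    abundant_element: str
    abundant_mean: float
    abundant_sd: float
    carbon_mode: float
    elements: tuple[str, ...]
    updated_upper: float
    small_angle_cut: float
    rf_band: tuple[float, float]
    lower: float = 1.3


@dataclass
class DetectionConfig:
    """Constants of the ligand-detection procedure.

    accept_z
        number of resolution-adjusted standard deviations within which a
        bond length is accepted as a true ligand (retains ~98.8% of true
        ligands under the fitted normal model).
    misassign_cutoff
        average mode-normalized bond-length deviation above which the whole
        site is treated as a likely metal misassignment.
    element_min_fraction
        minimum occurrence fraction for an element to stay on the whitelist
        after the first bootstrap round.
    triangular_factor
        ratio of the second-shell exclusion ("triangular") rule.
    resolution_fit_cap / min_points_per_resolution
        data-quality limits for fitting the bond-length-sd-vs-resolution
        slope.
    nonredundant_resolution / nonredundant_occupancy
        thresholds defining the nonredundant site set used for clustering.
    """

    accept_z: float = 2.5
    misassign_cutoff: float = 0.91
    element_min_fraction: float = 0.05
    triangular_factor: float = 1.5
    resolution_fit_cap: float = 3.5
    min_points_per_resolution: int = 30
    nonredundant_resolution: float = 3.0
    nonredundant_occupancy: float = 0.9
    sd_floor: float = 0.01
    nmr_resolution: float = 2.5
    metal_cluster_distance: float = 3.0
    min_seqres_length: int = 20
    pair_distance_min: float = 1.5
    pair_distance_max: float = 6.0
    water_names: tuple[str, ...] = ("HOH", "WAT", "DOD")


def _params_from_mapping(metal: str, entry: dict, lower: float) -> MetalParams:
    return MetalParams(
        metal=metal,
        atomic_radius_pm=float(entry["atomic_radius_pm"]),
        initial_upper=float(entry["initial_upper"]),
        abundant_element=str(entry["abundant_element"]),
        abundant_mean=float(entry["abundant_mean"]),
        abundant_sd=float(entry["abundant_sd"]),
        carbon_mode=float(entry["carbon_mode"]),
        elements=tuple(entry["elements"]),
        updated_upper=float(entry["updated_upper"]),
        small_angle_cut=float(entry["small_angle_cut"]),
        rf_band=tuple(float(x) for x in entry["rf_band"]),
        lower=lower,
    )


def load_metal_params(path: str | Path | None = None) -> dict[str, MetalParams]:
    """Load per-metal parameters, from a YAML file or the shipped defaults."""
    if path is None:
        text = (
            resources.files("metalcg").joinpath("data/metal_params.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    lower = float(raw.get("shell_lower", 1.3))
    return {
        metal: _params_from_mapping(metal, entry, lower)
        for metal, entry in raw["metals"].items()
    }
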