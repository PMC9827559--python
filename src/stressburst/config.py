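"""Scenario configuration: the full parameterization of one synthetic experiment.

A scenario bundles every time-varying rate and instrument constant needed to
emulate a mother-machine mutagenesis experiment and its companion
single-particle-tracking (SPT) measurement. Scenarios are loaded from YAML;
three fixtures ship with the package:

* ``WT_100uM`` — wild-type cells under a sudden 100 μM H2O2 step: two-fold
  elongation drop, transient mortality, a sharp mutagenesis burst
  (baseline 0.0029 → peak 0.021 events·cell⁻¹·min⁻¹ at 4.5 min, FWHM 12 min).
* ``OxyR_100uM`` — the SPT experiment: two-species diffusion
  (D_bound 0.17, D_free 0.8 μm²/s) with a bound probability peaking at
  5 min post-treatment and relaxing with a 15-min half-life.
* ``null_untreated`` — steady-state control: constant baseline mismatch rate,
  zero hazard, no burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from stressburst.curves import BoundProbCurve, GaussianBurstCurve, PiecewiseLinearCurve

__all__ = ["ScenarioConfig", "SPTParams", "OpticsParams", "ScenarioError",
           "load_scenario", "packaged_scenario", "available_scenarios"]

#: default fluorophore maturation time constant, minutes (SCFP3A at 37 °C)
DEFAULT_MATURATION_TAU = 6.4
#: default trace cadence, minutes
DEFAULT_FRAME_INTERVAL_TRACE = 3.0
#: default SPT frame interval, seconds
DEFAULT_FRAME_INTERVAL_SPT = 0.01548
#: default image pixel size, μm
DEFAULT_PIXEL_SIZE = 0.096


class ScenarioError(ValueError):
    """Raised when a scenario file is missing a field or violates an invariant."""


@dataclass
class SPTParams:
    """Kinetic and optical parameters of the single-particle-tracking arm.

    ``d_bound`` is the *apparent* diffusion coefficient of the immobile
    species (localization error folded in); set ``explicit_error=True`` to
    instead simulate a truly immobile species blurred by ``loc_error_sigma``.
    """

    d_bound: float = 0.17          # μm²/s
    d_free: float = 0.8            # μm²/s
    bound_prob_curve: BoundProbCurve = field(
        default_factory=lambda: BoundProbCurve(0.10, 0.35, 5.0, 15.0)
    )
    k_switch: float = 0.0          # s⁻¹, bound↔free switching within a track
    loc_error_sigma: float = 0.0   # μm per frame per axis
    track_length_mean: float = 8.0  # geometric mean track length, frames
    density: float = 2.0           # concurrent molecules per frame
    cell_length_um: float = 3.0    # reflecting-rectangle confinement
    cell_width_um: float = 0.9
    explicit_error: bool = False

    def validate(self) -> None:
        if self.d_bound < 0 or self.d_free < 0:
            raise ScenarioError("spt diffusion coefficients must be >= 0")
        if self.bound_prob_curve.min_value < 0 or max(
            self.bound_prob_curve.basal, self.bound_prob_curve.peak
        ) > 1:
            raise ScenarioError("spt.bound_prob_curve must stay within [0, 1]")
        if self.track_length_mean < 1:
            raise ScenarioError("spt.track_length_mean must be >= 1 frame")
        if self.cell_length_um <= 0 or self.cell_width_um <= 0:
            raise ScenarioError("spt cell dimensions must be positive")


@dataclass
class OpticsParams:
    """Rendering parameters for synthetic trench images."""

    trench_length_px: int = 80
    trench_width_px: int = 12
    background_offset: float = 100.0
    cell_signal: float = 120.0       # cytoplasmic channel counts above background
    foci_cell_signal: float = 4.0   # diffuse reporter counts in the foci channel
    focus_amplitude: float = 250.0   # peak counts of a rendered focus
    psf_sigma_px: float = 1.0
    read_noise_sd: float = 2.0      # Gaussian read noise, counts

    def validate(self) -> None:
        if self.trench_length_px < 4 or self.trench_width_px < 3:
            raise ScenarioError("optics trench dimensions too small to render")
        if self.psf_sigma_px <= 0:
            raise ScenarioError("optics.psf_sigma_px must be positive")


@dataclass
class ScenarioConfig:
    """All parameters for one named synthetic experiment.

    Rate curves are functions of minutes relative to treatment onset
    (``t_treatment`` maps them onto the experiment clock).
    """

    name: str
    t_treatment: float
    elongation_rate_curve: PiecewiseLinearCurve    # specific rate, min⁻¹
    death_hazard_curve: PiecewiseLinearCurve       # min⁻¹
    mismatch_rate_curve: GaussianBurstCurve        # events·cell⁻¹·min⁻¹
    promoter_activity_curve: PiecewiseLinearCurve  # au·min⁻¹·px⁻²
    fate_mix: dict[str, float] = field(
        default_factory=lambda: {"arrest": 0.5, "lysis": 0.3, "filamentation": 0.2}
    )
    frame_interval_trace: float = DEFAULT_FRAME_INTERVAL_TRACE  # minutes
    frame_interval_spt: float = DEFAULT_FRAME_INTERVAL_SPT      # seconds
    pixel_size: float = DEFAULT_PIXEL_SIZE                      # μm/px
    maturation_tau: float = DEFAULT_MATURATION_TAU              # minutes
    foci_persistence_frames: int = 2
    length_noise_cv: float = 0.01     # multiplicative length measurement noise
    birth_length_um: float = 2.2      # mean length right after division
    division_length_um: float = 4.4   # length triggering division
    spt: SPTParams = field(default_factory=SPTParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_interval_trace <= 0 or self.frame_interval_spt <= 0:
            raise ScenarioError("frame intervals must be strictly positive")
        if self.pixel_size <= 0:
            raise ScenarioError("pixel_size must be strictly positive")
        if self.maturation_tau <= 0:
            raise ScenarioError("maturation_tau must be strictly positive")
        total = sum(self.fate_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ScenarioError(f"fate_mix must sum to 1 (got {total})")
        unknown = set(self.fate_mix) - {"arrest", "lysis", "filamentation"}
        if unknown:
            raise ScenarioError(f"fate_mix has unknown fates: {sorted(unknown)}")
        if any(p < 0 for p in self.fate_mix.values()):
            raise ScenarioError("fate_mix probabilities must be nonnegative")
        for cname in ("elongation_rate_curve", "death_hazard_curve",
                      "mismatch_rate_curve", "promoter_activity_curve"):
            curve = getattr(self, cname)
            if curve.min_value < 0:
                raise ScenarioError(f"{cname} must be nonnegative")
        if self.foci_persistence_frames < 1:
            raise ScenarioError("foci_persistence_frames must be >= 1")
        if self.division_length_um <= self.birth_length_um:
            raise ScenarioError("division_length_um must exceed birth_length_um")
        self.spt.validate()
        self.optics.validate()


# ---------------------------------------------------------------------------
# YAML loading

_REQUIRED = ("name", "t_treatment", "mismatch_rate_curve", "elongation_rate_curve")


def _parse_pwl(node, fieldname: str) -> PiecewiseLinearCurve:
    if isinstance(node, (int, float)):
        return PiecewiseLinearCurve.constant(float(node))
    if isinstance(node, dict) and "knots" in node:
        try:
            return PiecewiseLinearCurve.from_knots(node["knots"])
        except ValueError as exc:
            raise ScenarioError(f"{fieldname}: {exc}") from exc
    raise ScenarioError(f"{fieldname} must be a number or a mapping with 'knots'")


def _parse_burst(node, fieldname: str) -> GaussianBurstCurve:
    if isinstance(node, (int, float)):
        v = float(node)
        return GaussianBurstCurve(v, v, 0.0, 0.0)
    if not isinstance(node, dict):
        raise ScenarioError(f"{fieldname} must be a number or a mapping")
    missing = {"baseline", "peak", "t_peak", "fwhm"} - set(node)
    if missing:
        raise ScenarioError(f"{fieldname} missing fields: {sorted(missing)}")
    return GaussianBurstCurve(
        float(node["baseline"]), float(node["peak"]),
        float(node["t_peak"]), float(node["fwhm"]),
    )


def _parse_bound_prob(node) -> BoundProbCurve:
    missing = {"basal", "peak", "t_peak", "t_half"} - set(node)
    if missing:
        raise ScenarioError(f"spt.bound_prob_curve missing fields: {sorted(missing)}")
    return BoundProbCurve(
        float(node["basal"]), float(node["peak"]),
        float(node["t_peak"]), float(node["t_half"]),
    )


def _from_mapping(doc: dict) -> ScenarioConfig:
    for key in _REQUIRED:
        if key not in doc:
            raise ScenarioError(f"scenario is missing required field {key!r}")

    kwargs: dict = {
        "name": str(doc["name"]),
        "t_treatment": float(doc["t_treatment"]),
        "elongation_rate_curve": _parse_pwl(doc["elongation_rate_curve"],
                                            "elongation_rate_curve"),
        "death_hazard_curve": _parse_pwl(doc.get("death_hazard_curve", 0.0),
                                         "death_hazard_curve"),
        "mismatch_rate_curve": _parse_burst(doc["mismatch_rate_curve"],
                                            "mismatch_rate_curve"),
        "promoter_activity_curve": _parse_pwl(doc.get("promoter_activity_curve", 1.0),
                                              "promoter_activity_curve"),
    }
    for key in ("frame_interval_trace", "frame_interval_spt", "pixel_size",
                "maturation_tau", "length_noise_cv", "birth_length_um",
                "division_length_um"):
        if key in doc:
            kwargs[key] = float(doc[key])
    for key in ("foci_persistence_frames", "seed"):
        if key in doc:
            kwargs[key] = int(doc[key])
    if "fate_mix" in doc:
        kwargs["fate_mix"] = {k: float(v) for k, v in doc["fate_mix"].items()}

    if "spt" in doc:
        node = dict(doc["spt"])
        spt_kwargs = {}
        if "bound_prob_curve" in node:
            spt_kwargs["bound_prob_curve"] = _parse_bound_prob(node.pop("bound_prob_curve"))
        rename = {"D_bound": "d_bound", "D_free": "d_free"}
        for k, v in node.items():
            spt_kwargs[rename.get(k, k)] = v
        kwargs["spt"] = SPTParams(**spt_kwargs)
    if "optics" in doc:
        kwargs["optics"] = OpticsParams(**doc["optics"])

    try:
        return ScenarioConfig(**kwargs)
    except TypeError as exc:
        raise ScenarioError(f"unknown scenario field: {exc}") from exc


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML file.

    Unspecified fields take the documented defaults (e.g. maturation_tau
    6.4 min, 3-min trace cadence, 15.48-ms SPT frames, 96-nm pixels).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ScenarioError(f"{path} does not contain a scenario mapping")
    return _from_mapping(doc)


def packaged_scenario(name: str) -> ScenarioConfig:
    """Load one of the scenarios shipped with the package by name."""
    ref = resources.files("stressburst.scenarios").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ScenarioError(
            f"no packaged scenario {name!r}; available: {available_scenarios()}"
        )
    doc = yaml.safe_load(ref.read_text())
    return _from_mapping(doc)


def available_scenarios() -> list[str]:
    return sorted(
        p.name[:-5]
        for p in resources.files("stressburst.scenarios").iterdir()
        if p.name.endswith(".yaml")
    )
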