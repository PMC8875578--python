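"""Model parameters, scenario configuration, and validation.

Every symbol of the tumor-transport model lives here in SI units
(m, s, Pa, mol·m⁻³, T).  The shipped defaults are the doxorubicin
parameterization for a perfused solid tumor with a necrotic core:
tissue hydraulics (Darcy/Starling), solute transport and binding
kinetics, the permanent-magnet description, and the nanoparticle
properties.  Configurations are flat key–value files (YAML mapping,
``section.field`` keys); values may carry a unit suffix, e.g.
``nanoparticle.radius_a: "100 nm"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .units import normalize_units

__all__ = [
    "TissueParams",
    "KineticParams",
    "VascularParams",
    "MagnetSpec",
    "NanoparticleSpec",
    "Geometry",
    "BoundaryConditions",
    "SolverSettings",
    "Scenario",
    "ConfigError",
    "ValidationError",
    "load_config",
    "write_config",
    "nanoparticle_diffusivity",
    "hindrance_factor",
    "REFERENCE_RADIUS",
]

#: Reference particle radius at which the tabulated effective diffusivity applies (m).
REFERENCE_RADIUS = 100e-9


class ConfigError(ValueError):
    """Unparseable configuration file or unknown key."""


class ValidationError(ValueError):
    """One or more parameter invariants violated; message lists every field."""


@dataclass
class TissueParams:
    """Tumor tissue hydraulic and vascular-exchange parameters."""

    kappa: float = 3e-14        # interstitium hydraulic conductivity, m^2/Pa/s
    Lp: float = 2.10e-11        # microvascular wall hydraulic conductivity, m/Pa/s
    SV: float = 2e4             # vascular surface area per tissue volume, 1/m
    PB: float = 2.1e3           # vascular fluid pressure, Pa
    piB: float = 2.7e3          # plasma osmotic pressure, Pa
    pii: float = 2e3            # interstitial osmotic pressure, Pa
    sigma_s: float = 0.9        # osmotic reflection coeff., plasma proteins
    Lpl: float = 0.0            # lymphatic wall hydraulic conductivity, m/Pa/s
    SLV: float = 0.0            # lymphatic surface area per volume, 1/m
    PL: float = 0.0             # lymphatic pressure, Pa
    eta: float = 1.12e-3        # interstitial fluid dynamic viscosity, Pa*s

    @property
    def starling_equilibrium(self) -> float:
        """Interstitial pressure at which transvascular filtration stops (Pa)."""
        return self.PB - self.sigma_s * (self.piB - self.pii)

    def validate(self) -> list[str]:
        errs = []
        for name in ("kappa", "Lp", "SV", "Lpl", "SLV"):
            if getattr(self, name) < 0:
                errs.append(f"tissue.{name} must be >= 0")
        if not 0.0 <= self.sigma_s <= 1.0:
            errs.append("tissue.sigma_s must lie in [0, 1]")
        if self.eta <= 0:
            errs.append("tissue.eta must be > 0")
        return errs


@dataclass
class KineticParams:
    """Binding/internalization kinetics and the cell-survival constant.

    ``omega`` enters the survival model SF = exp(-1e6·ω·C_I) with C_I in
    molar units (the dose–response was measured in vitro on molar
    concentrations; in SI the exponent is 1e3·ω·C_I[mol/m³]).
    """

    K_ON: float = 0.15          # binding rate, m^3/mol/s  (1.5e2 1/M/s)
    K_OFF: float = 8e-3         # unbinding rate, 1/s
    K_INT: float = 5e-5         # internalization rate, 1/s
    C_rec: float = 1e-2         # surface receptor concentration, mol/m^3 (1e-5 M)
    phi: float = 0.3            # tumor volume fraction accessible to drug
    D_eff: float = 3.40e-10     # reference effective diffusivity, m^2/s
    omega: float = 0.4938       # cell-survival constant, m^3/mol

    def validate(self) -> list[str]:
        errs = []
        for name in ("K_ON", "K_OFF", "K_INT", "C_rec", "D_eff", "omega"):
            if getattr(self, name) < 0:
                errs.append(f"kinetics.{name} must be >= 0")
        if not 0.0 < self.phi <= 1.0:
            errs.append("kinetics.phi must lie in (0, 1]")
        return errs


@dataclass
class VascularParams:
    """Transvascular solute exchange (pore model)."""

    P_perm: float = 3.00e-6     # microvessel permeability, m/s (3.00e-4 cm/s)
    sigma_f: float = 0.0        # osmotic reflection coeff. for nanoparticles
    C_p: float = 0.0            # plasma drug concentration, mol/m^3 (IP dosing: plasma is a sink)

    def validate(self) -> list[str]:
        errs = []
        if self.P_perm < 0:
            errs.append("vascular.P_perm must be >= 0")
        if not 0.0 <= self.sigma_f <= 1.0:
            errs.append("vascular.sigma_f must lie in [0, 1]")
        if self.C_p < 0:
            errs.append("vascular.C_p must be >= 0")
        return errs


@dataclass
class MagnetSpec:
    """Permanent magnet: rectangular cross-section, remanence toward the tumor.

    The magnet is centered on the vertical axis through the tumor center on
    the +y side; ``distance_d`` is measured from the tumor center to the
    nearest magnet face.  The remanence points along −y (toward the tumor),
    so the magnetic force inside the tumor points toward the magnet and the
    drug is driven in from the tumor face away from the magnet.
    """

    length_l: float = 0.20      # in-plane magnet length (x), m
    height_h: float = 0.10      # in-plane magnet height (y), m
    distance_d: float = 0.05    # tumor center -> nearest face, m
    B_rem: float = 1.5          # remnant flux density, T
    mu_r: float = 1000.0        # relative permeability of the magnet body
    placement: str = "+y"       # orientation convention token

    def validate(self) -> list[str]:
        errs = []
        if self.B_rem < 0:
            errs.append("magnet.B_rem must be >= 0")
        if self.mu_r < 1:
            errs.append("magnet.mu_r must be >= 1")
        for name in ("length_l", "height_h"):
            if getattr(self, name) <= 0:
                errs.append(f"magnet.{name} must be > 0")
        if self.distance_d <= 0:
            errs.append("magnet.distance_d must be > 0")
        if self.placement != "+y":
            errs.append("magnet.placement: only '+y' is supported")
        return errs


@dataclass
class NanoparticleSpec:
    """Drug-coated magnetic nanoparticle.

    ``chi`` is the intrinsic susceptibility entering the magnetization
    χ/(1+χ/3)·H with a saturation clamp at ``mu0_Msat``.  ``mobility_scale``
    is a dimensionless calibration factor multiplying the magnetic force; it
    absorbs particle magnetic content that published parameter tables do not
    pin down (susceptibility, saturation moment, carriers per drug dose) and
    is normally set once by calibrating the baseline magnetic penetration
    depth.  ``hindrance_scale`` is the ECM steric-hindrance length used by
    both the size-dependent diffusivity and the tissue mobility factor.
    """

    radius_a: float = 100e-9    # particle radius, m
    chi: float = 1.0            # magnetic susceptibility
    mu0_Msat: float = 0.5       # saturation magnetization as flux density, T
    mobility_scale: float = 1.0
    hindrance_scale: float = 150e-9  # ECM hindrance length, m

    @property
    def volume(self) -> float:
        """Particle volume (4/3)πa³ (m³)."""
        import math

        return 4.0 / 3.0 * math.pi * self.radius_a**3

    def validate(self) -> list[str]:
        errs = []
        if self.radius_a <= 0:
            errs.append("nanoparticle.radius_a must be > 0")
        if self.chi <= 0:
            errs.append("nanoparticle.chi must be > 0")
        if self.mu0_Msat < 0:
            errs.append("nanoparticle.mu0_Msat must be >= 0")
        if self.mobility_scale < 0:
            errs.append("nanoparticle.mobility_scale must be >= 0")
        if self.hindrance_scale <= 0:
            errs.append("nanoparticle.hindrance_scale must be > 0")
        return errs


@dataclass
class Geometry:
    """Circular tumor with a concentric necrotic core."""

    R: float = 0.01             # tumor radius, m
    Rn: float = 0.005           # necrotic core radius, m (default 0.5 R)
    center: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> list[str]:
        errs = []
        if self.R <= 0:
            errs.append("geometry.R must be > 0")
        if not 0.0 <= self.Rn < self.R:
            errs.append("geometry.Rn must satisfy 0 <= Rn < R")
        return errs


@dataclass
class BoundaryConditions:
    """Dirichlet rim values: gauge pressure and free-drug concentration."""

    Pi_outer: float = 0.0       # interstitial pressure at rim, Pa (peritoneal gauge)
    C_outer: float = 1.0        # free drug at rim, mol/m^3 (calibrated; metrics scale-invariant)

    def validate(self) -> list[str]:
        errs = []
        if self.C_outer < 0:
            errs.append("boundary.C_outer must be >= 0")
        return errs


@dataclass
class SolverSettings:
    """Discretization controls (artifact plumbing, not physics)."""

    n_theta: int = 96           # angular cell count
    dr_min: float = 8e-6        # radial spacing at the rim, m (resolves ~60 um layer)
    dr_max: float = 1.5e-4      # interior radial spacing cap, m
    grading: float = 1.12       # geometric growth of radial spacing inward
    dt: float = 2.0             # time step, s
    t_end: float = 3600.0       # treatment horizon, s
    theta_scheme: float = 1.0   # implicitness weight in [0.5, 1]
    lin_tol: float = 1e-10      # linear-solver residual tolerance
    checkpoint_every: float = 300.0  # checkpoint interval, s

    def validate(self) -> list[str]:
        errs = []
        if self.n_theta < 4:
            errs.append("solver.n_theta must be >= 4")
        if not 0 < self.dr_min <= 1e-5:
            errs.append("solver.dr_min must lie in (0, 1e-5] m")
        if self.dr_max < self.dr_min:
            errs.append("solver.dr_max must be >= dr_min")
        if self.grading <= 1.0:
            errs.append("solver.grading must be > 1")
        if not 0 < self.dt <= 5.0:
            errs.append("solver.dt must lie in (0, 5] s")
        if self.t_end <= 0:
            errs.append("solver.t_end must be > 0")
        if not 0.5 <= self.theta_scheme <= 1.0:
            errs.append("solver.theta_scheme must lie in [0.5, 1]")
        return errs


_SECTIONS = {
    "tissue": TissueParams,
    "kinetics": KineticParams,
    "vascular": VascularParams,
    "magnet": MagnetSpec,
    "nanoparticle": NanoparticleSpec,
    "geometry": Geometry,
    "boundary": BoundaryConditions,
    "solver": SolverSettings,
}


@dataclass
class Scenario:
    """A complete, validated model configuration."""

    tissue: TissueParams = field(default_factory=TissueParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    vascular: VascularParams = field(default_factory=VascularParams)
    magnet: MagnetSpec = field(default_factory=MagnetSpec)
    nanoparticle: NanoparticleSpec = field(default_factory=NanoparticleSpec)
    geometry: Geometry = field(default_factory=Geometry)
    boundary: BoundaryConditions = field(default_factory=BoundaryConditions)
    solver: SolverSettings = field(default_factory=SolverSettings)
    name: str = "scenario"

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violated invariant."""
        errs: list[str] = []
        for section in _SECTIONS:
            errs.extend(getattr(self, section).validate())
        if errs:
            raise ValidationError("; ".join(errs))

    def replace(self, **overrides: Any) -> "Scenario":
        """Return a deep copy with ``section.field`` overrides applied."""
        new = Scenario.from_dict(self.to_dict())
        new.name = self.name
        for key, value in overrides.items():
            section, _, fieldname = key.partition(".")
            if not fieldname or section not in _SECTIONS:
                raise ConfigError(f"unknown override key: {key!r}")
            sub = getattr(new, section)
            if fieldname not in {f.name for f in dataclasses.fields(sub)}:
                raise ConfigError(f"unknown override key: {key!r}")
            setattr(sub, fieldname, _coerce(sub, fieldname, value))
        new.validate()
        return new

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"name": self.name}
        for section in _SECTIONS:
            for f in dataclasses.fields(getattr(self, section)):
                val = getattr(getattr(self, section), f.name)
                if isinstance(val, tuple):
                    val = list(val)
                out[f"{section}.{f.name}"] = val
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Scenario":
        sc = cls()
        sc.name = str(data.get("name", "scenario"))
        for key, raw in data.items():
            if key == "name":
                continue
            section, _, fieldname = key.partition(".")
            if section not in _SECTIONS or not fieldname:
                raise ConfigError(f"unknown configuration key: {key!r}")
            sub = getattr(sc, section)
            if fieldname not in {f.name for f in dataclasses.fields(sub)}:
                raise ConfigError(f"unknown configuration key: {key!r}")
            setattr(sub, fieldname, _coerce(sub, fieldname, raw))
        return sc


def _coerce(sub: Any, fieldname: str, raw: Any) -> Any:
    """Coerce a raw config value; strings may carry a unit suffix."""
    current = getattr(sub, fieldname)
    if isinstance(current, str):
        return str(raw)
    if isinstance(current, tuple):
        vals = list(raw)
        return tuple(float(v) for v in vals)
    if isinstance(raw, str):
        parts = raw.split()
        if len(parts) == 2:
            return normalize_units(float(parts[0]), parts[1])
        raw = float(raw)
    if isinstance(current, int) and not isinstance(current, bool):
        return int(raw)
    return float(raw)


def load_config(path: str | Path) -> Scenario:
    """Load and validate a scenario configuration.

    Missing fields are filled from the shipped defaults; all values are
    normalized to SI.  An empty file yields the full default scenario.
    """
    path = Path(path)
    try:
        text = path.read_text()
        data = yaml.safe_load(text)
    except FileNotFoundError:
        raise
    except Exception as exc:  # yaml errors
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    flat: dict[str, Any] = {}
    for key, val in data.items():
        if isinstance(val, dict):  # nested section form also accepted
            for sub, v in val.items():
                flat[f"{key}.{sub}"] = v
        else:
            flat[key] = val
    sc = Scenario.from_dict(flat)
    sc.validate()
    return sc


def write_config(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as a flat SI key–value file (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=True)


def hindrance_factor(radius_a: float, hindrance_scale: float) -> float:
    """ECM steric hindrance exp(−(a−a_ref)/ℓ), equal to 1 at the reference radius."""
    import math

    if radius_a <= 0:
        raise ValueError("radius_a must be > 0")
    if hindrance_scale <= 0:
        raise ValueError("hindrance_scale must be > 0")
    return math.exp(-(radius_a - REFERENCE_RADIUS) / hindrance_scale)


def nanoparticle_diffusivity(
    spec: NanoparticleSpec,
    kinetics: KineticParams,
    hindrance_scale: float | None = None,
) -> float:
    """Size-dependent effective diffusivity of the particle in tissue.

    D(a) = D_eff · (a_ref/a) · exp(−(a−a_ref)/ℓ) with a_ref = 100 nm: the
    Stokes–Einstein 1/a factor times an exponential ECM hindrance whose
    length scale ℓ defaults to the particle's ``hindrance_scale``.
    D(a_ref) = D_eff exactly, and D is strictly decreasing in a.
    """
    if spec.radius_a <= 0:
        raise ValueError("radius_a must be > 0")
    ell = spec.hindrance_scale if hindrance_scale is None else hindrance_scale
    return (
        kinetics.D_eff
        * (REFERENCE_RADIUS / spec.radius_a)
        * hindrance_factor(spec.radius_a, ell)
    )
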