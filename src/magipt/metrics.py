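"""Treatment-efficacy metrics: cell kill, penetration depth, penetration area.

Cell kill follows an exponential in-vitro dose–response on the
internalized drug: SF = exp(−10⁶·ω·C_I) with C_I in molar units and
ω = 0.4938 m³/mol (fields in this package carry mol/m³, so the exponent
evaluates as 10³·ω·C_I).  The fraction of killed cells is FK = 1 − SF.

Penetration is summarized by

* ``w½`` — distance from the tumor border at which the free-drug
  concentration first falls to 50% of its border value;
* ``PA`` / ``PA_rel`` — the drug penetration area: total area where free
  drug exceeds a threshold fraction of the border concentration (default
  0.5%), absolute and as % of the tumor cross-section;
* ``FK_PA`` — area-averaged kill fraction inside the penetration area;
* ``FK_eff`` — whole-tumor effective kill, FK_eff = FK_PA·PA_rel/100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PolarGrid
from .params import BoundaryConditions

__all__ = [
    "MOLAR_PER_SI",
    "EfficacyReport",
    "survival_fraction",
    "penetration_half_depth",
    "penetration_area",
    "kill_metrics",
    "compute_efficacy",
]

#: mol/m³ → mol/L conversion entering the survival exponent.
MOLAR_PER_SI = 1e-3


def survival_fraction(C_I: np.ndarray | float, omega: float) -> np.ndarray | float:
    """Surviving cell fraction SF = exp(−10⁶·ω·C_I[M]) for C_I in mol/m³."""
    C = np.asarray(C_I, dtype=float)
    if np.any(C < 0):
        raise ValueError("internalized concentration must be non-negative")
    out = np.exp(-1e6 * omega * MOLAR_PER_SI * C)
    return float(out) if np.isscalar(C_I) else out


@dataclass
class HalfDepth:
    depth: float          # m, from the tumor border along the ray
    full_ray: bool        # no crossing found: drug penetrated the whole ray

    def __float__(self) -> float:
        return self.depth


def _ray_profile(
    C_F: np.ndarray, grid: PolarGrid, angle: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """(depth-from-border, concentration) samples along the measurement ray.

    ``angle=None``: the angle-averaged radial profile (radially symmetric
    case), ray length R.  Otherwise the full diameter entering the rim at
    ``angle``, ray length 2R.
    """
    if angle is None:
        prof = C_F.mean(axis=1)
        s = grid.R - grid.radii[::-1]
        return s, prof[::-1]
    j_in = grid.ray_index(angle)
    j_out = grid.ray_index(angle + np.pi)
    s_in = grid.R - grid.radii[::-1]
    s_out = grid.R + grid.radii
    s = np.concatenate([s_in, s_out])
    c = np.concatenate([C_F[::-1, j_in], C_F[:, j_out]])
    return s, c


def penetration_half_depth(
    C_F: np.ndarray,
    grid: PolarGrid,
    bc: BoundaryConditions,
    angle: float | None = None,
) -> HalfDepth:
    """Distance from the border at which C_F first falls to 0.5·C_border.

    The border value is the Dirichlet rim concentration.  Linear
    interpolation between samples; the first downward crossing is used
    (monotone-profile guard).  A profile that never crosses is reported as
    full-ray penetration with the ray length as depth.
    """
    if bc.C_outer <= 0:
        raise ValueError("rim concentration is zero; half-depth undefined")
    target = 0.5 * bc.C_outer
    s, c = _ray_profile(C_F, grid, angle)
    # prepend the border point itself
    s = np.concatenate([[0.0], s])
    c = np.concatenate([[bc.C_outer], c])
    below = c < target
    if not below.any():
        ray_len = grid.R if angle is None else 2.0 * grid.R
        return HalfDepth(depth=ray_len, full_ray=True)
    k = int(np.argmax(below))  # first sample below target
    if k == 0:
        return HalfDepth(depth=0.0, full_ray=False)
    s0, s1 = s[k - 1], s[k]
    c0, c1 = c[k - 1], c[k]
    w = s0 + (c0 - target) / (c0 - c1) * (s1 - s0)
    return HalfDepth(depth=float(w), full_ray=False)


def penetration_area(
    C_F: np.ndarray,
    grid: PolarGrid,
    bc: BoundaryConditions,
    threshold_frac: float = 0.005,
) -> tuple[float, float, np.ndarray]:
    """Penetration area: cells with C_F ≥ threshold_frac·C_border.

    Returns (PA in m², PA_rel in %, boolean cell mask).
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    mask = C_F >= threshold_frac * bc.C_outer
    PA = float(grid.cell_areas[mask].sum())
    PA_rel = 100.0 * PA / grid.total_area
    return PA, PA_rel, mask


def kill_metrics(
    C_I: np.ndarray,
    pa_mask: np.ndarray,
    grid: PolarGrid,
    omega: float,
    PA_rel: float,
) -> tuple[float, float]:
    """(FK_PA, FK_eff) in %, given the penetration-area mask.

    FK_PA is the area-weighted mean kill fraction over the penetration
    area; FK_eff = FK_PA·PA_rel/100 refers the kill to the whole tumor.
    An empty penetration area reports (0, 0).
    """
    if not pa_mask.any():
        return 0.0, 0.0
    FK = 1.0 - survival_fraction(C_I, omega)
    w = grid.cell_areas
    FK_PA = 100.0 * float((FK * w)[pa_mask].sum() / w[pa_mask].sum())
    FK_eff = FK_PA * PA_rel / 100.0
    return FK_PA, FK_eff


@dataclass
class EfficacyReport:
    """Scenario efficacy summary (the quantities of the comparison tables)."""

    w_half: float            # m
    w_half_rel: float        # w½/R, %
    full_ray: bool
    PA: float                # m²
    PA_rel: float            # %
    FK_PA: float             # %
    FK_eff: float            # %
    mean_CF: float           # mol/m³, area-weighted tumor mean at t_end
    mean_CB: float
    mean_CI: float
    threshold_used: float    # PA threshold as fraction of the rim concentration

    def to_dict(self) -> dict:
        return {
            "w_half_m": self.w_half,
            "w_half_cm": self.w_half * 100.0,
            "w_half_rel_pct": self.w_half_rel,
            "full_ray": self.full_ray,
            "PA_m2": self.PA,
            "PA_rel_pct": self.PA_rel,
            "FK_PA_pct": self.FK_PA,
            "FK_eff_pct": self.FK_eff,
            "mean_CF": self.mean_CF,
            "mean_CB": self.mean_CB,
            "mean_CI": self.mean_CI,
            "pa_threshold_frac": self.threshold_used,
        }


def compute_efficacy(
    C_F: np.ndarray,
    C_B: np.ndarray,
    C_I: np.ndarray,
    grid: PolarGrid,
    bc: BoundaryConditions,
    omega: float,
    threshold_frac: float = 0.005,
    ray_angle: float | None = None,
) -> EfficacyReport:
    """Assemble the full efficacy report from the final concentration fields."""
    hd = penetration_half_depth(C_F, grid, bc, angle=ray_angle)
    PA, PA_rel, mask = penetration_area(C_F, grid, bc, threshold_frac)
    FK_PA, FK_eff = kill_metrics(C_I, mask, grid, omega, PA_rel)
    w = grid.cell_areas
    tot = w.sum()
    return EfficacyReport(
        w_half=hd.depth,
        w_half_rel=100.0 * hd.depth / grid.R,
        full_ray=hd.full_ray,
        PA=PA,
        PA_rel=PA_rel,
        FK_PA=FK_PA,
        FK_eff=FK_eff,
        mean_CF=float((C_F * w).sum() / tot),
        mean_CB=float((C_B * w).sum() / tot),
        mean_CI=float((C_I * w).sum() / tot),
        threshold_used=threshold_frac,
    )
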