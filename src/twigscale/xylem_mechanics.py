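"""Stem hydraulic-architecture, density, water-content, and mechanical traits.

Derivations from raw measurement tables:

* vessel axes  -> Poiseuille-equivalent diameter, hydraulically weighted
  diameter, vessel density/fraction, theoretical specific conductivity;
* gravimetric masses/volume -> wood density and saturated water content;
* three-point bending load-deflection series -> flexural stiffness and
  structural modulus of elasticity.

Vessel axes are interpreted as SEMI-axes: with that convention the
equivalent-diameter formula returns the true diameter of a circular conduit
(a = b = r gives D = 2r).  A helper flag converts full-axis input on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import units

__all__ = [
    "PhysicalConstants",
    "VesselSet",
    "StemHydraulics",
    "GravimetricRecord",
    "BendingTest",
    "ellipse_equivalent_diameter",
    "hydraulic_weighted_diameter",
    "vessel_stats",
    "theoretical_conductivity",
    "stem_composition",
    "bending_moe",
    "derive_stem_hydraulics",
    "derive_vessel_table",
    "derive_gravimetric_table",
    "derive_bending_table",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Water properties at 20 degC; overridable in config."""

    rho_water: float = 998.2  # kg m^-3
    mu_water: float = 1.002e-9  # MPa s


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass
class VesselSet:
    """Per-stem vessel semi-axis measurements plus analyzed xylem area."""

    stem_id: str
    semi_major_a: np.ndarray  # um
    semi_minor_b: np.ndarray  # um
    analyzed_xylem_area: float  # mm^2
    sapwood_area: float | None = None  # mm^2, informational

    def __post_init__(self):
        self.semi_major_a = np.asarray(self.semi_major_a, dtype=float)
        self.semi_minor_b = np.asarray(self.semi_minor_b, dtype=float)
        if self.semi_major_a.size == 0:
            raise ValueError(f"stem {self.stem_id}: at least one vessel required")
        if self.semi_major_a.shape != self.semi_minor_b.shape:
            raise ValueError(f"stem {self.stem_id}: axis arrays differ in length")
        if np.any(self.semi_minor_b <= 0) or np.any(
            self.semi_major_a < self.semi_minor_b
        ):
            raise ValueError(
                f"stem {self.stem_id}: require a >= b > 0 for every vessel"
            )
        if not self.analyzed_xylem_area > 0:
            raise ValueError(f"stem {self.stem_id}: analyzed xylem area must be > 0")

    @classmethod
    def from_full_axes(cls, stem_id, major, minor, analyzed_xylem_area, **kw):
        """Build from full (not semi-) axis measurements, halving on ingest."""
        return cls(
            stem_id,
            np.asarray(major, dtype=float) / 2.0,
            np.asarray(minor, dtype=float) / 2.0,
            analyzed_xylem_area,
            **kw,
        )

    @property
    def n_vessels(self) -> int:
        return int(self.semi_major_a.size)


@dataclass(frozen=True)
class StemHydraulics:
    stem_id: str
    D_per_vessel: np.ndarray  # um
    D_h: float  # um
    VD: float  # mm^-2
    VF: float  # fraction
    K_theo: float  # kg m^-1 MPa^-1 s^-1


def ellipse_equivalent_diameter(a, b):
    """Diameter of the circular conduit hydraulically equivalent to an ellipse.

    ``a`` and ``b`` are the semi-major and semi-minor axes (um).  Solves
    pi d^4/128 = pi a^3 b^3 / (4 (a^2+b^2)), i.e. equal Poiseuille
    conductance, giving D = [32 (ab)^3 / (a^2 + b^2)]^(1/4).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("vessel axes must be positive")
    return (32.0 * (a * b) ** 3 / (a**2 + b**2)) ** 0.25


def hydraulic_weighted_diameter(D: Sequence[float]) -> float:
    """Fourth-power mean of vessel diameters: D_h = [1/n sum(D^4)]^(1/4)."""
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("empty diameter sequence")
    if np.any(D <= 0):
        raise ValueError("diameters must be positive")
    return float(np.mean(D**4) ** 0.25)


def vessel_stats(vessels: VesselSet) -> tuple[float, float]:
    """Vessel density (mm^-2) and lumen fraction of the analyzed xylem area.

    VF = mean ellipse lumen area (pi*a*b) x VD, returned as a fraction.
    """
    vd = vessels.n_vessels / vessels.analyzed_xylem_area
    mean_lumen_mm2 = float(
        np.mean(np.pi * vessels.semi_major_a * vessels.semi_minor_b)
        * units.UM2_TO_MM2
    )
    vf = mean_lumen_mm2 * vd
    if vf >= 1.0:
        warnings.warn(
            f"stem {vessels.stem_id}: vessel fraction {vf:.3f} >= 1; "
            "inconsistent vessel/area measurements",
            stacklevel=2,
        )
    return float(vd), float(vf)


def theoretical_conductivity(
    D: Sequence[float],
    A_s: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Hagen-Poiseuille theoretical specific conductivity.

    K_theo = pi * rho / (128 * mu * A_s) * sum(D^4), with D in um and A_s in
    mm^2 converted to SI internally; result in kg m^-1 MPa^-1 s^-1.
    """
    if not A_s > 0:
        raise ValueError("sapwood area must be positive")
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        warnings.warn("no vessels supplied; K_theo = 0", stacklevel=2)
        return 0.0
    sum_d4 = np.sum((D * units.UM_TO_M) ** 4)
    area_m2 = A_s * units.MM2_TO_M2
    return float(
        np.pi
        * constants.rho_water
        / (128.0 * constants.mu_water * area_m2)
        * sum_d4
    )


def derive_stem_hydraulics(
    vessels: VesselSet, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> StemHydraulics:
    """All hydraulic-architecture traits for one stem.

    The conductivity is referenced to the analyzed xylem area, i.e. it is the
    area-specific conductivity of the measured sapwood window.
    """
    D = ellipse_equivalent_diameter(vessels.semi_major_a, vessels.semi_minor_b)
    vd, vf = vessel_stats(vessels)
    return StemHydraulics(
        stem_id=vessels.stem_id,
        D_per_vessel=D,
        D_h=hydraulic_weighted_diameter(D),
        VD=vd,
        VF=vf,
        K_theo=theoretical_conductivity(D, vessels.analyzed_xylem_area, constants),
    )


@dataclass(frozen=True)
class GravimetricRecord:
    stem_id: str
    fresh_weight: float  # g
    saturated_weight: float  # g
    dry_weight: float  # g
    fresh_volume: float  # cm^3

    def __post_init__(self):
        if not (self.dry_weight > 0 and self.fresh_volume > 0):
            raise ValueError(f"stem {self.stem_id}: masses and volume must be > 0")
        if not (
            self.saturated_weight >= self.fresh_weight >= self.dry_weight
        ):
            raise ValueError(
                f"stem {self.stem_id}: require SW >= FW >= DW "
                f"(got {self.saturated_weight}, {self.fresh_weight}, "
                f"{self.dry_weight})"
            )


def stem_composition(rec: GravimetricRecord) -> tuple[float, float]:
    """Wood density (g cm^-3) and saturated water content (%).

    WD = DW / fresh volume; SWC = (FW - DW) / (SW - DW) * 100.
    """
    wd = rec.dry_weight / rec.fresh_volume
    denom = rec.saturated_weight - rec.dry_weight
    if denom <= 0:
        raise ZeroDivisionError(
            f"stem {rec.stem_id}: SW equals DW; saturated water content is "
            "undefined (no saturable pore space measured)"
        )
    swc = (rec.fresh_weight - rec.dry_weight) / denom * 100.0
    return float(wd), float(swc)


@dataclass
class BendingTest:
    """One three-point bending series for a solid circular stem segment."""

    stem_id: str
    span: float  # mm
    diameter: float  # mm
    loads: np.ndarray  # N, strictly increasing
    deflections: np.ndarray  # mm

    def __post_init__(self):
        self.loads = np.asarray(self.loads, dtype=float)
        self.deflections = np.asarray(self.deflections, dtype=float)
        if self.loads.shape != self.deflections.shape or self.loads.size < 3:
            raise ValueError(
                f"stem {self.stem_id}: need >= 3 matching load-deflection pairs"
            )
        if np.any(np.diff(self.loads) <= 0):
            raise ValueError(f"stem {self.stem_id}: loads must strictly increase")
        if not (self.span > 0 and self.diameter > 0):
            raise ValueError(f"stem {self.stem_id}: span and diameter must be > 0")
        ratio = self.span / self.diameter
        if ratio < 20:
            raise ValueError(
                f"stem {self.stem_id}: span-to-diameter ratio {ratio:.1f} < 20; "
                "shear would contaminate the bending estimate"
            )
        if ratio < 25 - 1e-9:
            warnings.warn(
                f"stem {self.stem_id}: span-to-diameter ratio {ratio:.1f} below "
                "the recommended 25:1",
                stacklevel=2,
            )


def bending_moe(test: BendingTest) -> tuple[float, float]:
    """Flexural stiffness EI (N mm^2) and structural MOE (MPa).

    A least-squares line is fit to deflection vs load; only its slope s is
    used, so load-independent offsets cancel.  For center loading of a simply
    supported beam EI = L^3 / (48 s), and MOE = EI / I with the solid-circle
    second moment of area I = pi d^4 / 64.
    """
    slope, intercept = np.polyfit(test.loads, test.deflections, 1)
    fitted = slope * test.loads + intercept
    ss_res = float(np.sum((test.deflections - fitted) ** 2))
    ss_tot = float(np.sum((test.deflections - test.deflections.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.8:
        raise ValueError(
            f"stem {test.stem_id}: deflection-load relation is not linear "
            f"(r^2 = {r2:.3f} < 0.8); rejecting test"
        )
    if r2 < 0.95:
        warnings.warn(
            f"stem {test.stem_id}: weak bending linearity (r^2 = {r2:.3f})",
            stacklevel=2,
        )
    if slope <= 0:
        raise ValueError(f"stem {test.stem_id}: non-positive deflection slope")
    ei = test.span**3 / (48.0 * slope)
    second_moment = np.pi * test.diameter**4 / 64.0
    return float(ei), float(ei / second_moment)


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def derive_vessel_table(
    vessel_df: pd.DataFrame,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    full_axes: bool = False,
) -> pd.DataFrame:
    """Per-stem hydraulic traits from a long-format vessel table.

    Expects columns stem_id, a_um, b_um, analyzed_area_mm2 (area repeated on
    every row of a stem), plus optional grouping columns (species, individual)
    carried through.
    """
    rows = []
    carry = [c for c in ("species", "individual") if c in vessel_df.columns]
    for stem_id, grp in vessel_df.groupby("stem_id", sort=True):
        area = float(grp["analyzed_area_mm2"].iloc[0])
        builder = VesselSet.from_full_axes if full_axes else VesselSet
        vs = builder(str(stem_id), grp["a_um"].values, grp["b_um"].values, area)
        hyd = derive_stem_hydraulics(vs, constants)
        row = {
            "stem_id": stem_id,
            "Dh": hyd.D_h,
            "VD": hyd.VD,
            "VF": hyd.VF,
            "Ktheo": hyd.K_theo,
        }
        for c in carry:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def derive_gravimetric_table(grav_df: pd.DataFrame) -> pd.DataFrame:
    """Per-stem WD and SWC from columns stem_id, fw_g, sw_g, dw_g, volume_cm3."""
    rows = []
    carry = [c for c in ("species", "individual") if c in grav_df.columns]
    for _, rec in grav_df.iterrows():
        record = GravimetricRecord(
            str(rec["stem_id"]),
            float(rec["fw_g"]),
            float(rec["sw_g"]),
            float(rec["dw_g"]),
            float(rec["volume_cm3"]),
        )
        wd, swc = stem_composition(record)
        row = {"stem_id": rec["stem_id"], "WD": wd, "SWC": swc}
        for c in carry:
            row[c] = rec[c]
        rows.append(row)
    return pd.DataFrame(rows)


def derive_bending_table(bend_df: pd.DataFrame) -> pd.DataFrame:
    """Per-stem EI and MOE from a long table of load steps.

    Expects stem_id, span_mm, diameter_mm, load_n, deflection_mm; one row per
    load step, span/diameter repeated within a stem.
    """
    rows = []
    carry = [c for c in ("species", "individual") if c in bend_df.columns]
    for stem_id, grp in bend_df.groupby("stem_id", sort=True):
        grp = grp.sort_values("load_n")
        test = BendingTest(
            str(stem_id),
            float(grp["span_mm"].iloc[0]),
            float(grp["diameter_mm"].iloc[0]),
            grp["load_n"].values,
            grp["deflection_mm"].values,
        )
        ei, moe = bending_moe(test)
        row = {"stem_id": stem_id, "EI": ei, "MOE": moe}
        for c in carry:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
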