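"""Twig-level leaf/stem architecture traits and species-level aggregation.

A twig is one current-year terminal shoot.  Derived traits:

* SLA  = total lamina area / total lamina dry mass (m^2 kg^-1)
* ILA  = total lamina area / leaf count (cm^2)
* ILM  = total lamina mass / leaf count (g)
* IPM  = total petiole mass / leaf count (g)
* LI   = leaf count / stem dry mass (g^-1)

Species means are two-stage arithmetic means: twigs are averaged within each
individual first, then individuals within each species.  With unbalanced twig
counts this differs from a pooled mean, and the two-stage form is the one
used throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import units

#: raw measurement columns of the twig table
RAW_COLUMNS = [
    "species",
    "individual",
    "twig",
    "stem_area_mm2",
    "stem_mass_g",
    "leaf_count",
    "total_lamina_area_cm2",
    "total_lamina_mass_g",
    "total_petiole_mass_g",
    "petiole_area_mm2",
]

#: mapping from derived/renamed trait code to source in the derived table
TWIG_TRAIT_CODES = [
    "SA", "SM", "PA", "TLA", "LeM", "ILA", "ILM", "IPM", "SLA", "LI",
]

#: leaf-anatomy columns that pass through derivation untouched (measured)
ANATOMY_COLUMNS = {
    "lt_um": "LT",
    "uet_um": "UET",
    "pt_um": "PT",
    "sp_um": "SP",
    "let_um": "LET",
    "ss_um": "SS",
    "sd_per_mm2": "SD",
}

#: full Table-1-style trait code order for species tables
ALL_TRAIT_CODES = [
    "SA", "SM", "Dh", "VD", "VF", "Ktheo", "WD", "SWC", "MOE", "PA",
    "IPM", "TLA", "ILA", "LeM", "ILM", "SLA", "LI",
    "LT", "UET", "PT", "SP", "LET", "SS", "SD",
]


@dataclass(frozen=True)
class TwigRecord:
    species: str
    individual: str
    twig: str
    stem_area: float  # mm^2
    stem_mass: float  # g
    leaf_count: int
    total_lamina_area: float  # cm^2
    total_lamina_mass: float  # g
    total_petiole_mass: float  # g
    petiole_area: float  # mm^2

    def __post_init__(self):
        if self.leaf_count < 1:
            raise ValueError(
                f"twig {self.species}/{self.individual}/{self.twig}: "
                "leaf count must be >= 1"
            )
        for name in (
            "stem_area",
            "stem_mass",
            "total_lamina_area",
            "total_lamina_mass",
            "total_petiole_mass",
            "petiole_area",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(
                    f"twig {self.species}/{self.individual}/{self.twig}: "
                    f"{name} must be positive"
                )


def derive_twig_traits(twig_df: pd.DataFrame) -> pd.DataFrame:
    """Add derived trait columns to a raw twig table.

    Returns a new frame with Table-1-style trait codes alongside the grouping
    keys.  Leaf-anatomy columns, when present, are carried through renamed.
    """
    missing = [c for c in RAW_COLUMNS if c not in twig_df.columns]
    if missing:
        raise ValueError(f"twig table missing columns: {missing}")
    if (twig_df["leaf_count"] < 1).any():
        bad = twig_df.loc[twig_df["leaf_count"] < 1, ["species", "twig"]]
        raise ValueError(f"leaf count < 1 for rows:\n{bad}")

    out = twig_df[["species", "individual", "twig"]].copy()
    n = twig_df["leaf_count"].astype(float)
    out["SA"] = twig_df["stem_area_mm2"]
    out["SM"] = twig_df["stem_mass_g"]
    out["PA"] = twig_df["petiole_area_mm2"]
    out["TLA"] = twig_df["total_lamina_area_cm2"]
    out["LeM"] = twig_df["total_lamina_mass_g"]
    out["ILA"] = twig_df["total_lamina_area_cm2"] / n
    out["ILM"] = twig_df["total_lamina_mass_g"] / n
    out["IPM"] = twig_df["total_petiole_mass_g"] / n
    out["SLA"] = (
        twig_df["total_lamina_area_cm2"]
        / twig_df["total_lamina_mass_g"]
        * units.CM2_PER_G_TO_M2_PER_KG
    )
    out["LI"] = n / twig_df["stem_mass_g"]
    for raw, code in ANATOMY_COLUMNS.items():
        if raw in twig_df.columns:
            out[code] = twig_df[raw]
    return out


def aggregate_species_means(
    derived: pd.DataFrame,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Two-stage species means: twigs -> individual -> species.

    ``derived`` must carry species/individual keys plus numeric trait columns
    (e.g. the output of :func:`derive_twig_traits`).  Species whose values are
    entirely missing for a trait get NA there (with a warning).
    """
    if trait_columns is None:
        trait_columns = [
            c
            for c in derived.columns
            if c not in ("species", "individual", "twig")
            and pd.api.types.is_numeric_dtype(derived[c])
        ]
    per_individual = (
        derived.groupby(["species", "individual"], sort=True)[trait_columns]
        .mean()
        .reset_index()
    )
    species_means = per_individual.groupby("species", sort=True)[trait_columns].mean()
    if species_means.isna().any().any():
        bad = species_means.columns[species_means.isna().any()].tolist()
        warnings.warn(f"species means contain NA for traits {bad}", stacklevel=2)
    species_means.index.name = "species"
    return species_means
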