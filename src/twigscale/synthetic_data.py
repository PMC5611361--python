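"""Synthetic phylogenies, species trait tables, and raw measurement tables.

The generator mirrors the nested sampling design of a multi-species
common-garden twig study: a Yule tree over the species, species-level trait
means evolved by multivariate Brownian motion on log10 scale, configurable
allometric exponents and trade-off correlations injected on top of the BM
deviates, and individual- and twig-level multiplicative measurement noise.

Trait bookkeeping
-----------------
A *core* set of traits is simulated directly; the remaining trait codes are
deterministic functions of the core set so the species table stays
self-consistent:

* ``TLA = n_leaf * ILA``, ``LeM = n_leaf * ILM``, ``SM = n_leaf / LI``
  (n_leaf = mean leaves per twig),
* ``SLA = 0.1 * ILA / ILM`` (cm^2/g to m^2/kg),
* ``VF`` and ``Ktheo`` from ``Dh``/``VD`` and the vessel-population shape
  parameters.

When an allometric or trade-off adjustment targets a derived trait, the
change is back-propagated into one designated core partner (e.g. adjusting
``TLA`` moves ``ILA``) and every derived trait is recomputed.

Allometric adjustments are calibrated for SMA: the pair is generated so the
*standard-deviation ratio* equals the requested exponent and the squared
correlation equals the requested r^2, which is what an SMA fit estimates.

All randomness flows from one ``numpy`` Generator in a single documented
order: tree, Brownian increments (preorder), adjustment residuals (config
order), then measurement noise per species (sorted), individual, and twig.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import Phylogeny, _Node
from .twig_architecture import ALL_TRAIT_CODES
from .xylem_mechanics import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "CORE_TRAITS",
    "DERIVED_TRAITS",
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_tree",
    "simulate_species_traits",
    "expand_to_measurements",
    "generate_dataset",
    "simulate_sma_dataset",
]

CORE_TRAITS = [
    "SA", "ILA", "ILM", "IPM", "PA", "LI",
    "Dh", "VD", "WD", "SWC", "MOE",
    "LT", "UET", "PT", "SP", "LET", "SS", "SD",
]
DERIVED_TRAITS = ["TLA", "LeM", "SM", "SLA", "VF", "Ktheo"]

# physical clamps applied both to species means and per-stem draws, keeping
# the truth table consistent with what the measurement model can express
WD_MAX = 1.4  # g cm^-3, below the ~1.53 cell-wall density
SWC_MIN, SWC_MAX = 1.0, 99.5  # %
VF_SPECIES_MAX = 0.6  # species-mean vessel fraction ceiling
VF_STEM_MAX = 0.8  # per-stem expected vessel fraction ceiling

#: log10 root states for plausible broadleaf twig traits in reporting units
DEFAULT_ROOT_STATE = {
    "SA": np.log10(10.0),      # mm^2
    "ILA": np.log10(80.0),     # cm^2
    "ILM": np.log10(0.8),      # g
    "IPM": np.log10(0.08),     # g
    "PA": np.log10(3.0),       # mm^2
    "LI": np.log10(1.5),       # no. g^-1
    "Dh": np.log10(35.0),      # um
    "VD": np.log10(60.0),      # mm^-2
    "WD": np.log10(0.45),      # g cm^-3
    "SWC": np.log10(80.0),     # %
    "MOE": np.log10(3000.0),   # MPa
    "LT": np.log10(200.0),     # um
    "UET": np.log10(20.0),
    "PT": np.log10(80.0),
    "SP": np.log10(90.0),
    "LET": np.log10(15.0),
    "SS": np.log10(25.0),
    "SD": np.log10(300.0),     # mm^-2
}


@dataclass
class SimulationConfig:
    n_species: int = 28
    n_individuals: int = 3
    n_twigs_min: int = 3
    n_twigs_max: int = 5
    traits: list[str] = field(default_factory=lambda: list(CORE_TRAITS))
    root_state: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROOT_STATE)
    )
    #: diagonal BM rates (log10^2 per unit depth); overridden by a full matrix.
    #: size traits vary over orders of magnitude across species, bounded
    #: physical traits (densities, water content) over much less
    bm_rates: dict[str, float] = field(
        default_factory=lambda: {
            t: {
                "Dh": 0.03, "VD": 0.03,
                "WD": 0.01, "SWC": 0.005, "MOE": 0.02,
                "LT": 0.10, "UET": 0.10, "PT": 0.10, "SP": 0.10,
                "LET": 0.10, "SS": 0.10, "SD": 0.10,
            }.get(t, 0.35)
            for t in CORE_TRAITS
        }
    )
    bm_rate_matrix: np.ndarray | None = None
    #: (trait_y, trait_x) -> SMA exponent beta
    allometric_exponents: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (trait_y, trait_x) -> target r^2 (default 0.9 where unspecified)
    allometric_r2: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (trait_a, trait_b) -> target Pearson r; trait_a is adjusted
    tradeoff_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd_individual: float = 0.05  # log10 units
    noise_sd_twig: float = 0.08  # log10 units
    n_leaf_min: int = 8
    n_leaf_max: int = 15
    vessel_sigma: float = 0.15  # ln-scale sd of vessel diameters within a stem
    vessel_aspect_min: float = 0.7  # semi-minor / semi-major
    vessel_aspect_max: float = 1.0
    analyzed_area_mm2: float = 0.5
    min_vessels: int = 30
    wood_volume_cm3: float = 1.5
    bending_noise: float = 0.002  # relative deflection jitter
    n_load_steps: int = 5
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.noise_sd_individual < 0 or self.noise_sd_twig < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (1 <= self.n_twigs_min <= self.n_twigs_max):
            raise ValueError("need 1 <= n_twigs_min <= n_twigs_max")
        if not (1 <= self.n_leaf_min <= self.n_leaf_max):
            raise ValueError("need 1 <= n_leaf_min <= n_leaf_max")
        if not (0 < self.vessel_aspect_min <= self.vessel_aspect_max <= 1.0):
            raise ValueError("vessel aspect ratios must lie in (0, 1]")
        missing = [t for t in self.traits if t not in self.root_state]
        if missing:
            raise ValueError(f"root_state missing traits: {missing}")
        _ = self.rate_matrix()  # PSD check

    def rate_matrix(self) -> np.ndarray:
        p = len(self.traits)
        if self.bm_rate_matrix is not None:
            mat = np.asarray(self.bm_rate_matrix, dtype=float)
            if mat.shape != (p, p):
                raise ValueError(
                    f"bm_rate_matrix must be {p}x{p} for traits {self.traits}"
                )
        else:
            mat = np.diag([self.bm_rates.get(t, 0.0) for t in self.traits])
        if not np.allclose(mat, mat.T):
            raise ValueError("bm_rate_matrix must be symmetric")
        eig = np.linalg.eigvalsh(mat)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise ValueError("bm_rate_matrix must be positive semi-definite")
        return mat

    @property
    def mean_leaf_count(self) -> float:
        return (self.n_leaf_min + self.n_leaf_max) / 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constants"] = dataclasses.asdict(self.constants)
        d["bm_rate_matrix"] = (
            None if self.bm_rate_matrix is None
            else np.asarray(self.bm_rate_matrix).tolist()
        )
        for key in ("allometric_exponents", "allometric_r2",
                    "tradeoff_correlations"):
            d[key] = {f"{a}~{b}": v for (a, b), v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "constants" in d and isinstance(d["constants"], dict):
            d["constants"] = PhysicalConstants(**d["constants"])
        if d.get("bm_rate_matrix") is not None:
            d["bm_rate_matrix"] = np.asarray(d["bm_rate_matrix"], dtype=float)
        for key in ("allometric_exponents", "allometric_r2",
                    "tradeoff_correlations"):
            if key in d and d[key]:
                d[key] = {
                    tuple(k.split("~")): float(v) for k, v in d[key].items()
                }
        return cls(**d)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default trade-off scenario: big twigs are conductive but weak.

    Size (SA) organizes leaf traits near isometry, hydraulic efficiency rises
    with size, wood density falls with size, and mechanical strength tracks
    wood density -- the qualitative sign structure a hydraulics/mechanics
    trade-off produces.
    """
    cfg = SimulationConfig(
        allometric_exponents={
            ("ILA", "SA"): 1.0,
            ("LI", "SA"): -1.0,
            ("ILM", "ILA"): 1.15,
            ("IPM", "ILA"): 1.39,  # inverse of lamina-area ~ petiole-mass 0.72
        },
        allometric_r2={
            ("ILA", "SA"): 0.85,
            ("LI", "SA"): 0.75,
            ("ILM", "ILA"): 0.80,
            ("IPM", "ILA"): 0.83,
        },
        tradeoff_correlations={
            ("WD", "SA"): -0.6,
            ("Ktheo", "SA"): 0.7,
            ("MOE", "WD"): 0.7,
        },
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    species_means: pd.DataFrame
    twig_table: pd.DataFrame
    vessel_table: pd.DataFrame
    gravimetric_table: pd.DataFrame
    bending_table: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tree.write(outdir / "tree.nwk")
        self.species_means.to_csv(outdir / "species_means_true.csv")
        self.twig_table.to_csv(outdir / "twig_table.csv", index=False)
        self.vessel_table.to_csv(outdir / "vessel_table.csv", index=False)
        self.gravimetric_table.to_csv(
            outdir / "gravimetric_table.csv", index=False
        )
        self.bending_table.to_csv(outdir / "bending_table.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_species: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> Phylogeny:
    """Yule (pure-birth) tree scaled to root-to-tip depth 1.

    Tips are labelled ``sp01`` ... in left-to-right order; the same seed
    always yields the same newick string.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)

    root = _Node(length=0.0)
    root.children = [_Node(), _Node()]
    tips: list[tuple[_Node, float]] = [(c, 0.0) for c in root.children]
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(len(tips)))
        node, birth = tips.pop(idx)
        node.length = t - birth
        node.children = [_Node(), _Node()]
        tips.extend((c, t) for c in node.children)
    t += rng.exponential(1.0 / n_species)  # extend final tips past last split
    for node, birth in tips:
        node.length = t - birth

    # scale depth to 1 and label tips left to right
    def scale(node: _Node) -> None:
        node.length /= t
        for c in node.children:
            scale(c)

    for c in root.children:
        scale(c)
    width = max(2, len(str(n_species)))
    counter = 0

    def label(node: _Node) -> None:
        nonlocal counter
        if not node.children:
            counter += 1
            node.name = f"sp{counter:0{width}d}"
        for c in node.children:
            label(c)

    label(root)
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# species-level traits
# ---------------------------------------------------------------------------

def _ktheo_log_factor(constants: PhysicalConstants) -> float:
    # K = pi*rho/(128*mu) * VD[mm^-2]*1e6 * (Dh[um]*1e-6)^4
    return float(
        np.log10(np.pi * constants.rho_water / (128.0 * constants.mu_water))
        + 6.0
        - 24.0
    )


def _aspect_area_factor(cfg: SimulationConfig) -> float:
    """E[sqrt((1+q^2)/(32 q))] over the vessel aspect-ratio distribution.

    For a vessel of Poiseuille-equivalent diameter D and aspect q = b/a the
    lumen area is pi*a*b = pi*D^2*sqrt((1+q^2)/(32 q)); circular vessels give
    exactly 1/4.
    """
    if cfg.vessel_aspect_min == cfg.vessel_aspect_max:
        q = cfg.vessel_aspect_min
        return float(np.sqrt((1 + q * q) / (32.0 * q)))
    q = np.linspace(cfg.vessel_aspect_min, cfg.vessel_aspect_max, 2001)
    g = np.sqrt((1 + q * q) / (32.0 * q))
    return float(np.trapezoid(g, q) / (cfg.vessel_aspect_max - cfg.vessel_aspect_min))


def _derived_log_columns(core: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Compute derived trait columns (log10) from a core log10 table."""
    out = core.copy()
    log_n = np.log10(cfg.mean_leaf_count)
    s2 = cfg.vessel_sigma**2
    have = set(core.columns)
    if "ILA" in have:
        out["TLA"] = core["ILA"] + log_n
    if "ILM" in have:
        out["LeM"] = core["ILM"] + log_n
    if "LI" in have:
        out["SM"] = log_n - core["LI"]
    if {"ILA", "ILM"} <= have:
        out["SLA"] = core["ILA"] - core["ILM"] - 1.0  # cm^2/g -> m^2/kg
    if {"Dh", "VD"} <= have:
        out["VF"] = (
            np.log10(np.pi * _aspect_area_factor(cfg))
            - 2.0 * s2 / np.log(10.0)
            - 6.0
            + 2.0 * core["Dh"]
            + core["VD"]
        )
        out["Ktheo"] = (
            _ktheo_log_factor(cfg.constants) + core["VD"] + 4.0 * core["Dh"]
        )
    return out


def _backpropagate(
    core: pd.DataFrame, trait: str, new_log: np.ndarray, cfg: SimulationConfig
) -> None:
    """Write an adjusted (possibly derived) trait back into the core table."""
    log_n = np.log10(cfg.mean_leaf_count)
    s2 = cfg.vessel_sigma**2
    if trait in core.columns:
        core[trait] = new_log
    elif trait == "TLA":
        core["ILA"] = new_log - log_n
    elif trait == "LeM":
        core["ILM"] = new_log - log_n
    elif trait == "SM":
        core["LI"] = log_n - new_log
    elif trait == "SLA":
        core["ILM"] = core["ILA"] - 1.0 - new_log
    elif trait == "Ktheo":
        core["Dh"] = (
            new_log - _ktheo_log_factor(cfg.constants) - core["VD"]
        ) / 4.0
    elif trait == "VF":
        const = (
            np.log10(np.pi * _aspect_area_factor(cfg))
            - 2.0 * s2 / np.log(10.0)
            - 6.0
        )
        core["Dh"] = (new_log - const - core["VD"]) / 2.0
    else:
        raise ValueError(f"cannot adjust unknown trait {trait!r}")


def simulate_species_traits(
    tree: Phylogeny,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Species x trait table (natural scale) from BM plus structural tuning.

    Brownian motion runs over the core traits; requested allometric exponents
    are then imposed so that an SMA fit of the pair recovers the exponent
    (sd ratio = |beta|, squared correlation = r^2), and trade-off
    correlations are injected by regressing the first-named trait onto the
    second.  Derived traits stay consistent with the core set throughout.
    """
    if tree.n_tips < 2:
        raise ValueError("tree must have >= 2 tips")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    traits = config.traits
    p = len(traits)
    sigma = config.rate_matrix()
    w, v = np.linalg.eigh(sigma)
    sqrt_sigma = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    root = np.array([config.root_state[t] for t in traits], dtype=float)

    values: dict[int, np.ndarray] = {id(tree.root): root}
    tip_rows: dict[str, np.ndarray] = {}
    parents = _parent_lookup(tree)
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_val = values[id(parents[id(node)])]
        step = np.sqrt(node.length) * (sqrt_sigma @ rng.standard_normal(p))
        values[id(node)] = parent_val + step
        if node.is_leaf:
            tip_rows[node.name] = values[id(node)]

    core = pd.DataFrame.from_dict(tip_rows, orient="index", columns=traits)
    core = core.sort_index()
    core.index.name = "species"

    # allometric structure: y tuned to x so SMA recovers beta at the given r^2
    for (yname, xname), beta in config.allometric_exponents.items():
        if beta == 0:
            raise ValueError(f"allometric exponent for ({yname},{xname}) is 0")
        full = _derived_log_columns(core, config)
        x = full[xname].values
        mu_y = float(full[yname].mean()) if yname in full else 0.0
        r2 = float(config.allometric_r2.get((yname, xname), 0.9))
        if not (0 < r2 <= 1):
            raise ValueError("allometric r^2 must be in (0, 1]")
        sd_x = float(np.std(x, ddof=1))
        centered = x - x.mean()
        y_new = mu_y + np.sign(beta) * np.sqrt(r2) * abs(beta) * centered
        if r2 < 1:
            y_new = y_new + abs(beta) * sd_x * np.sqrt(1 - r2) * (
                rng.standard_normal(len(x))
            )
        _backpropagate(core, yname, y_new, config)

    # trade-off correlations: trait_a regressed onto trait_b at target r
    for (aname, bname), r in config.tradeoff_correlations.items():
        if not -1 <= r <= 1:
            raise ValueError(f"target correlation for ({aname},{bname}) not in [-1,1]")
        full = _derived_log_columns(core, config)
        a, b = full[aname].values, full[bname].values
        sd_a = float(np.std(a, ddof=1))
        sd_b = float(np.std(b, ddof=1))
        a_new = (
            a.mean()
            + r * (sd_a / sd_b) * (b - b.mean())
            + sd_a * np.sqrt(1 - r * r) * rng.standard_normal(len(a))
        )
        _backpropagate(core, aname, a_new, config)

    # physical ceiling: shrink Dh where the implied vessel fraction is
    # unattainably large, then recompute the derived hydraulic traits
    if {"Dh", "VD"} <= set(core.columns):
        full = _derived_log_columns(core, config)
        over = full["VF"] > np.log10(VF_SPECIES_MAX)
        if over.any():
            core.loc[over, "Dh"] -= (
                full.loc[over, "VF"] - np.log10(VF_SPECIES_MAX)
            ) / 2.0

    full = _derived_log_columns(core, config)
    table = 10.0 ** full
    if "WD" in table:
        table["WD"] = table["WD"].clip(upper=WD_MAX)
    if "SWC" in table:
        table["SWC"] = table["SWC"].clip(SWC_MIN, SWC_MAX)
    ordered = [c for c in ALL_TRAIT_CODES if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    return table[ordered + extra]


def _parent_lookup(tree: Phylogeny) -> dict[int, _Node]:
    lookup: dict[int, _Node] = {}
    for node in tree.preorder():
        for child in node.children:
            lookup[id(child)] = node
    return lookup


# ---------------------------------------------------------------------------
# measurement expansion
# ---------------------------------------------------------------------------

_IND_NOISE_TRAITS = [
    "SA", "ILA", "ILM", "IPM", "PA", "LI",
    "LT", "UET", "PT", "SP", "LET", "SS", "SD",
]
_STEM_NOISE_TRAITS = ["Dh", "VD", "WD", "SWC", "MOE", "SA_bend"]


def _lognoise(rng: np.random.Generator, sd: float, size=None):
    return 10.0 ** rng.normal(0.0, sd, size=size) if sd > 0 else (
        np.ones(size) if size is not None else 1.0
    )


def expand_to_measurements(
    species_means: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    tree: Phylogeny | None = None,
) -> SyntheticDataset:
    """Nested noisy measurement tables from a species-mean trait table.

    One stem per individual carries the vessel, gravimetric and bending
    measurements; three-to-five twigs per individual carry the architecture
    measurements.  With all noise terms zero (and fixed leaf/twig counts)
    re-deriving species means from the tables reproduces the input exactly.
    """
    required = set(CORE_TRAITS)
    missing = sorted(required - set(species_means.columns))
    if missing:
        raise ValueError(f"species_means missing required traits: {missing}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd_i, sd_t = config.noise_sd_individual, config.noise_sd_twig
    s = config.vessel_sigma

    twig_rows, vessel_rows, grav_rows, bend_rows = [], [], [], []
    for sp in sorted(species_means.index):
        mean = species_means.loc[sp]
        for j in range(1, config.n_individuals + 1):
            ind = f"i{j}"
            stem_id = f"{sp}_{ind}"
            im = {t: _lognoise(rng, sd_i) for t in _IND_NOISE_TRAITS}
            sm = {t: _lognoise(rng, sd_i) for t in _STEM_NOISE_TRAITS}

            # --- vessels ---------------------------------------------------
            dh_t = mean["Dh"] * sm["Dh"]
            vd_t = mean["VD"] * sm["VD"]
            # keep the stem's expected lumen fraction physically plausible
            vf_coef = (
                np.pi * _aspect_area_factor(config)
                * np.exp(-2.0 * s * s) * 1e-6 * vd_t
            )
            dh_t = min(dh_t, np.sqrt(VF_STEM_MAX / vf_coef))
            n_v = max(config.min_vessels,
                      int(round(vd_t * config.analyzed_area_mm2)))
            area_t = n_v / vd_t  # integer count at exactly the target density
            ln_med = np.log(dh_t) - 2.0 * s * s
            d = np.exp(rng.normal(ln_med, s, size=n_v)) if s > 0 else np.full(
                n_v, dh_t
            )
            q = rng.uniform(config.vessel_aspect_min, config.vessel_aspect_max,
                            size=n_v)
            a = d * ((1 + q * q) / (32.0 * q**3)) ** 0.25
            b = q * a
            for av, bv in zip(a, b):
                vessel_rows.append(
                    {
                        "stem_id": stem_id,
                        "species": sp,
                        "individual": ind,
                        "a_um": av,
                        "b_um": bv,
                        "analyzed_area_mm2": area_t,
                    }
                )

            # --- gravimetrics ---------------------------------------------
            wd_t = min(mean["WD"] * sm["WD"], WD_MAX)
            swc_t = float(np.clip(mean["SWC"] * sm["SWC"], SWC_MIN, SWC_MAX))
            vol = config.wood_volume_cm3
            dw = wd_t * vol
            sw = dw + vol * (1.0 - wd_t / 1.53) * 0.9982
            fw = dw + swc_t / 100.0 * (sw - dw)
            grav_rows.append(
                {
                    "stem_id": stem_id,
                    "species": sp,
                    "individual": ind,
                    "fw_g": fw,
                    "sw_g": sw,
                    "dw_g": dw,
                    "volume_cm3": vol,
                }
            )

            # --- bending ---------------------------------------------------
            moe_t = mean["MOE"] * sm["MOE"]
            d_bend = 2.0 * np.sqrt(mean["SA"] * sm["SA_bend"] / np.pi)
            span = 25.0 * d_bend
            second_moment = np.pi * d_bend**4 / 64.0
            slope = span**3 / (48.0 * moe_t * second_moment)
            loads = np.arange(1, config.n_load_steps + 1, dtype=float)
            defl = slope * loads
            if config.bending_noise > 0:
                defl = defl * (
                    1.0 + rng.normal(0.0, config.bending_noise, size=len(loads))
                )
            for load, de in zip(loads, defl):
                bend_rows.append(
                    {
                        "stem_id": stem_id,
                        "species": sp,
                        "individual": ind,
                        "span_mm": span,
                        "diameter_mm": d_bend,
                        "load_n": load,
                        "deflection_mm": de,
                    }
                )

            # --- twigs -----------------------------------------------------
            n_twigs = int(rng.integers(config.n_twigs_min, config.n_twigs_max + 1))
            for k in range(1, n_twigs + 1):
                tm = {t: _lognoise(rng, sd_t) for t in _IND_NOISE_TRAITS}
                n_leaf = int(rng.integers(config.n_leaf_min, config.n_leaf_max + 1))
                ila = mean["ILA"] * im["ILA"] * tm["ILA"]
                ilm = mean["ILM"] * im["ILM"] * tm["ILM"]
                ipm = mean["IPM"] * im["IPM"] * tm["IPM"]
                li = mean["LI"] * im["LI"] * tm["LI"]
                twig_rows.append(
                    {
                        "species": sp,
                        "individual": ind,
                        "twig": f"t{k}",
                        "stem_area_mm2": mean["SA"] * im["SA"] * tm["SA"],
                        "stem_mass_g": n_leaf / li,
                        "leaf_count": n_leaf,
                        "total_lamina_area_cm2": n_leaf * ila,
                        "total_lamina_mass_g": n_leaf * ilm,
                        "total_petiole_mass_g": n_leaf * ipm,
                        "petiole_area_mm2": mean["PA"] * im["PA"] * tm["PA"],
                        "lt_um": mean["LT"] * im["LT"] * tm["LT"],
                        "uet_um": mean["UET"] * im["UET"] * tm["UET"],
                        "pt_um": mean["PT"] * im["PT"] * tm["PT"],
                        "sp_um": mean["SP"] * im["SP"] * tm["SP"],
                        "let_um": mean["LET"] * im["LET"] * tm["LET"],
                        "ss_um": mean["SS"] * im["SS"] * tm["SS"],
                        "sd_per_mm2": mean["SD"] * im["SD"] * tm["SD"],
                    }
                )

    truth = {
        "config": config.to_dict(),
        "species_means": species_means.to_dict(orient="index"),
    }
    return SyntheticDataset(
        tree=tree if tree is not None else simulate_tree(
            max(len(species_means), 3), seed=config.seed
        ),
        species_means=species_means,
        twig_table=pd.DataFrame(twig_rows),
        vessel_table=pd.DataFrame(vessel_rows),
        gravimetric_table=pd.DataFrame(grav_rows),
        bending_table=pd.DataFrame(bend_rows),
        truth=truth,
    )


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full simulation: tree -> species means -> measurement tables.

    A single Generator seeded from ``config.seed`` drives every stage, so the
    same config reproduces the dataset bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, rng=rng)
    means = simulate_species_traits(tree, config, rng=rng)
    return expand_to_measurements(means, config, rng=rng, tree=tree)


def simulate_sma_dataset(
    n: int,
    slope: float,
    r2: float,
    rng: np.random.Generator,
    sd_x: float = 0.3,
    mean_x: float = 0.0,
    mean_y: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One log10-scale (x, y) sample whose SMA slope estimates ``slope``.

    The pair is bivariate normal with sd(y)/sd(x) = |slope| and squared
    correlation r^2 -- the population quantities the SMA estimator targets.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if not (0 < r2 <= 1):
        raise ValueError("r2 must be in (0, 1]")
    x = mean_x + sd_x * rng.standard_normal(n)
    y = mean_y + np.sign(slope) * np.sqrt(r2) * abs(slope) * (x - mean_x)
    if r2 < 1:
        y = y + abs(slope) * sd_x * np.sqrt(1.0 - r2) * rng.standard_normal(n)
    return x, y
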