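"""End-to-end orchestration: simulate/load -> derive -> analyze -> report.

Stages are pure functions over pandas tables; this module wires them
together, writes every intermediate product as CSV, and emits a JSON
manifest (config hash, seed, file list) plus a human-readable markdown
summary ordered allometry -> MFA -> trade-off correlations -> size-trait
correlations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, allometry, multivariate, phylo
from . import twig_architecture as twig
from . import xylem_mechanics as xylem
from .synthetic_data import SimulationConfig, default_config, generate_dataset

logger = logging.getLogger("twigscale")

#: default (Y, X) SMA pairs, shaped like a published slope table
DEFAULT_SMA_PAIRS = [
    ("TLA", "SM"), ("ILA", "SM"), ("LeM", "SM"), ("ILM", "SM"),
    ("TLA", "SA"), ("ILA", "SA"), ("LeM", "SA"), ("ILM", "SA"),
    ("ILA", "PA"), ("ILM", "PA"),
    ("ILA", "IPM"), ("ILM", "IPM"),
    ("TLA", "LI"), ("ILA", "LI"), ("LeM", "LI"), ("ILM", "LI"),
    ("LeM", "TLA"), ("ILM", "ILA"),
]

MFA_GROUPS = {
    "stem": ["SA", "SM", "Dh", "VD", "VF", "Ktheo", "WD", "SWC", "MOE",
             "PA", "IPM"],
    "leaf": ["TLA", "ILA", "LeM", "ILM", "SLA", "LI",
             "LT", "UET", "PT", "SP", "LET", "SS", "SD"],
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "twigscale_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    twig_csv: str | None = None
    vessel_csv: str | None = None
    gravimetric_csv: str | None = None
    bending_csv: str | None = None
    tree_path: str | None = None
    sma_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_SMA_PAIRS)
    )
    skip_stages: list[str] = field(default_factory=list)

    def b0_for(self, pair: tuple[str, str]) -> float:
        # inverse size relationships (leafing intensity) are tested vs -1
        return -1.0 if "LI" in pair else 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["sma_pairs"] = [list(p) for p in self.sma_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "sma_pairs" in d:
            d["sma_pairs"] = [tuple(p) for p in d["sma_pairs"]]
        return cls(**d)


@dataclass
class PipelineResult:
    species_table: pd.DataFrame
    sma_table: pd.DataFrame | None = None
    corr_r: pd.DataFrame | None = None
    corr_p: pd.DataFrame | None = None
    pic_r: pd.DataFrame | None = None
    pic_p: pd.DataFrame | None = None
    mfa: multivariate.MFAResult | None = None
    varcomp: pd.DataFrame | None = None
    manifest: dict | None = None


def _config_hash(config: PipelineConfig) -> str:
    # outdir is excluded: the same analysis written elsewhere is the same run
    d = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        ds = generate_dataset(sim)
        return ds.twig_table, ds.vessel_table, ds.gravimetric_table, \
            ds.bending_table, ds.tree
    if config.twig_csv is None:
        raise ValueError("config needs either a simulation block or input CSVs")
    twig_df = pd.read_csv(config.twig_csv)
    vessel_df = (
        pd.read_csv(config.vessel_csv) if config.vessel_csv else None
    )
    grav_df = (
        pd.read_csv(config.gravimetric_csv) if config.gravimetric_csv else None
    )
    bend_df = pd.read_csv(config.bending_csv) if config.bending_csv else None
    tree = None
    if config.tree_path:
        tree = phylo.read_newick(config.tree_path)
    return twig_df, vessel_df, grav_df, bend_df, tree


def derive_species_table(
    twig_df: pd.DataFrame,
    vessel_df: pd.DataFrame | None = None,
    grav_df: pd.DataFrame | None = None,
    bend_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Species x trait table from raw measurement tables."""
    derived = twig.derive_twig_traits(twig_df)
    table = twig.aggregate_species_means(derived)
    for df, fn in (
        (vessel_df, xylem.derive_vessel_table),
        (grav_df, xylem.derive_gravimetric_table),
        (bend_df, xylem.derive_bending_table),
    ):
        if df is None:
            continue
        per_stem = fn(df)
        cols = [
            c for c in per_stem.columns
            if c not in ("stem_id", "species", "individual", "EI")
        ]
        sp_means = (
            per_stem.groupby(["species", "individual"])[cols]
            .mean()
            .groupby("species")
            .mean()
        )
        table = table.join(sp_means, how="left")
    ordered = [c for c in twig.ALL_TRAIT_CODES if c in table.columns]
    return table[ordered]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(config.skip_stages)
    outputs: list[str] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        df.to_csv(path, index=index)
        outputs.append(name)

    try:
        twig_df, vessel_df, grav_df, bend_df, tree = _load_or_simulate(config)
    except (ValueError, FileNotFoundError) as exc:
        raise StageError("input", exc)

    try:
        derived_twigs = twig.derive_twig_traits(twig_df)
        table = derive_species_table(twig_df, vessel_df, grav_df, bend_df)
        save(table, "species_means.csv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("derive", exc)

    result = PipelineResult(species_table=table)
    log_table = allometry.log10_prepare(table)

    if "allometry" not in skip:
        try:
            pairs = [
                p for p in config.sma_pairs
                if p[0] in table.columns and p[1] in table.columns
            ]
            b0_map = {p: config.b0_for(p) for p in pairs}
            result.sma_table = allometry.fit_pairs(log_table, pairs, b0_map)
            save(result.sma_table, "sma_table.csv", index=False)
        except Exception as exc:
            raise StageError("allometry", exc)

    if "correlations" not in skip:
        try:
            result.corr_r, result.corr_p = multivariate.pearson_matrix(log_table)
            save(result.corr_r, "correlations_r.csv")
            save(result.corr_p, "correlations_p.csv")
        except Exception as exc:
            raise StageError("correlations", exc)

    if "pic" not in skip:
        if tree is None:
            logger.warning("no tree supplied; PIC stage skipped")
        else:
            try:
                contrasts = {
                    t: phylo.pic_contrasts(tree, log_table[t].to_dict(), t)
                    for t in log_table.columns
                    if log_table[t].notna().all()
                }
                result.pic_r, result.pic_p = multivariate.pic_pearson_matrix(
                    contrasts
                )
                save(result.pic_r, "pic_correlations_r.csv")
                save(result.pic_p, "pic_correlations_p.csv")
            except Exception as exc:
                raise StageError("pic", exc)

    if "mfa" not in skip:
        try:
            groups = {
                g: [t for t in cols if t in table.columns]
                for g, cols in MFA_GROUPS.items()
            }
            groups = {g: cols for g, cols in groups.items() if len(cols) >= 2}
            result.mfa = multivariate.mfa(log_table, groups)
            save(result.mfa.loadings, "mfa_loadings.csv")
            save(result.mfa.scores, "mfa_scores.csv")
            pct = pd.DataFrame(
                {"axis": result.mfa.loadings.columns,
                 "variance_pct": result.mfa.axis_variance_pct}
            )
            save(pct, "mfa_variance.csv", index=False)
        except Exception as exc:
            raise StageError("mfa", exc)

    if "varcomp" not in skip:
        try:
            rows = []
            for t in twig.TWIG_TRAIT_CODES:
                vc = multivariate.nested_varcomp(derived_twigs, t, log10=True)
                rows.append(dataclasses.asdict(vc))
            result.varcomp = pd.DataFrame(rows)
            save(result.varcomp, "varcomp.csv", index=False)
        except Exception as exc:
            raise StageError("varcomp", exc)

    manifest = {
        "package": "twigscale",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_species": int(len(table)),
        "outputs": outputs,
    }
    result.manifest = manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    report = write_report(result)
    with open(outdir / "report.md", "w") as fh:
        fh.write(report)
    return result


def _sig4(x: float) -> str:
    return f"{x:.4g}"


def write_report(result: PipelineResult) -> str:
    """Markdown summary of a pipeline run (4 significant digits)."""
    lines = ["# twigscale run report", ""]
    if result.manifest:
        lines += [
            f"- package version: {result.manifest['version']}",
            f"- seed: {result.manifest['seed']}",
            f"- config hash: {result.manifest['config_hash']}",
            f"- species analyzed: {result.manifest['n_species']}",
            "",
        ]

    if result.sma_table is not None and len(result.sma_table):
        lines += ["## Allometry (SMA)", "",
                  "| Y | X | n | R2 | slope | 95% CI | P(b0) | verdict |",
                  "|---|---|---|----|-------|--------|-------|---------|"]
        for _, row in result.sma_table.iterrows():
            verdict = (
                "isometric" if row["P"] > 0.05 else "allometric"
            )
            lines.append(
                f"| {row['Y']} | {row['X']} | {row['n']} | "
                f"{_sig4(row['R2'])} | {_sig4(row['slope'])} | "
                f"{_sig4(row['ci_low'])} to {_sig4(row['ci_high'])} | "
                f"{_sig4(row['P'])} | {verdict} |"
            )
        lines.append("")

    if result.mfa is not None:
        lines += ["## Multiple factor analysis", ""]
        for i, pct in enumerate(result.mfa.axis_variance_pct[:3], 1):
            lines.append(f"- axis {i}: {_sig4(pct)}% of variance")
        lines.append("")

    def corr_block(title, r_df, p_df, pairs):
        block = [f"## {title}", ""]
        for a, b in pairs:
            if r_df is None or a not in r_df.index or b not in r_df.columns:
                continue
            r, p = r_df.loc[a, b], p_df.loc[a, b]
            if np.isnan(r):
                continue
            block.append(f"- {a} vs {b}: r = {_sig4(r)} (p = {_sig4(p)})")
        block.append("")
        return block if len(block) > 2 else []

    tradeoff_pairs = [
        ("Dh", "VD"), ("Dh", "VF"), ("Dh", "Ktheo"),
        ("WD", "Ktheo"), ("WD", "MOE"), ("Ktheo", "MOE"),
    ]
    size_pairs = [
        ("SA", "Dh"), ("SA", "VD"), ("SA", "VF"), ("SA", "WD"),
        ("SA", "Ktheo"), ("SA", "MOE"),
        ("Ktheo", "PA"), ("Ktheo", "ILA"), ("Ktheo", "LI"),
        ("WD", "PA"), ("WD", "ILA"), ("WD", "LI"),
    ]
    lines += corr_block(
        "Hydraulics-mechanics trade-off (cross-species)",
        result.corr_r, result.corr_p, tradeoff_pairs,
    )
    lines += corr_block(
        "Size vs hydraulic/mechanical traits (cross-species)",
        result.corr_r, result.corr_p, size_pairs,
    )
    lines += corr_block(
        "Trade-off correlations (independent contrasts)",
        result.pic_r, result.pic_p, tradeoff_pairs,
    )

    if result.varcomp is not None and len(result.varcomp):
        lines += ["## Variance partitioning (species/individual/twig)", ""]
        for _, row in result.varcomp.iterrows():
            lines.append(
                f"- {row['trait']}: {_sig4(row['pct_species'])}% / "
                f"{_sig4(row['pct_individual'])}% / {_sig4(row['pct_twig'])}%"
            )
        lines.append("")

    return "\n".join(lines) + "\n"


def make_default_pipeline_config(seed: int = 0, outdir: str = "twigscale_out",
                                 **sim_overrides) -> PipelineConfig:
    sim = default_config(seed=seed, **sim_overrides)
    return PipelineConfig(outdir=outdir, seed=seed, simulation=sim)
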