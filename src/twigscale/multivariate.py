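"""Trait correlation matrices, multiple factor analysis, variance components.

MFA here is the grouped-variable PCA of Escofier & Pages: every variable is
standardized, each group block is divided by the square root of the first
eigenvalue of its own PCA (so no single group can dominate the global axes),
and a plain SVD of the concatenated blocks yields axes, loadings and scores.

Variance components for the species/individual/twig nesting use
method-of-moments estimators from the nested ANOVA mean squares, with
harmonic-mean group sizes in unbalanced designs and negative estimates
truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import ContrastSet, pic_correlation

__all__ = [
    "MFAResult",
    "VarianceComponents",
    "pearson_matrix",
    "pic_pearson_matrix",
    "mfa",
    "nested_varcomp",
]


def pearson_matrix(
    table: pd.DataFrame, traits: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation and p-value matrices.

    Cells with fewer than 3 complete pairs are NA.  p-values use the usual
    t approximation with n - 2 degrees of freedom.
    """
    cols = list(traits) if traits is not None else list(table.columns)
    data = table[cols].astype(float)
    k = len(cols)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    for i in range(k):
        r_mat[i, i], p_mat[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            sub = data.iloc[:, [i, j]].dropna()
            if len(sub) < 3:
                continue
            x, y = sub.iloc[:, 0].values, sub.iloc[:, 1].values
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
    return (
        pd.DataFrame(r_mat, index=cols, columns=cols),
        pd.DataFrame(p_mat, index=cols, columns=cols),
    )


def pic_pearson_matrix(
    contrasts: Mapping[str, ContrastSet]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Through-origin correlation matrix over a set of contrast sets."""
    names = list(contrasts)
    k = len(names)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    for i in range(k):
        r_mat[i, i], p_mat[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            r, p = pic_correlation(contrasts[names[i]], contrasts[names[j]])
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
    return (
        pd.DataFrame(r_mat, index=names, columns=names),
        pd.DataFrame(p_mat, index=names, columns=names),
    )


@dataclass(frozen=True)
class MFAResult:
    axis_variance_pct: np.ndarray  # percentages, sum to 100
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x axes (right singular vectors)
    scores: pd.DataFrame  # observations x axes
    group_weights: dict[str, float]  # 1/sqrt(lambda1) per group

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _standardize(block: np.ndarray, names, center: bool) -> np.ndarray:
    mean = block.mean(axis=0) if center else np.zeros(block.shape[1])
    centered = block - mean
    sd = np.sqrt((centered**2).mean(axis=0))
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"constant column(s) cannot enter MFA: {[names[z] for z in zero]}"
        )
    return centered / sd


def mfa(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    center: bool = True,
) -> MFAResult:
    """Multiple factor analysis over named variable groups.

    ``center=False`` is for contrast matrices, which are mean-zero by
    construction and must not be re-centered.
    """
    for gname, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {gname!r} needs >= 2 traits")
    all_cols: list[str] = [c for cols in groups.values() for c in cols]
    # duplicated trait codes across groups are allowed (block-duplication
    # scenarios); loading labels are disambiguated when that happens
    if len(set(all_cols)) != len(all_cols):
        labels = [f"{g}:{c}" for g, cols in groups.items() for c in cols]
    else:
        labels = list(all_cols)
    n = len(table)

    weighted_blocks = []
    group_weights: dict[str, float] = {}
    for gname, cols in groups.items():
        raw = table[list(cols)].astype(float)
        if raw.isna().any().any():
            raise ValueError(
                f"MFA requires complete rows; group {gname!r} has missing values"
            )
        block = _standardize(raw.values, list(cols), center)
        # first eigenvalue of the group's own PCA
        s1 = np.linalg.svd(block, compute_uv=False)[0]
        lam1 = s1**2 / n
        group_weights[gname] = 1.0 / np.sqrt(lam1)
        weighted_blocks.append(block / np.sqrt(lam1))

    X = np.hstack(weighted_blocks)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / n
    keep = eig > max(eig.max(), 1.0) * 1e-12
    eig, u, s, vt = eig[keep], u[:, keep], s[keep], vt[keep, :]
    pct = eig / eig.sum() * 100.0
    axes = [f"axis{i+1}" for i in range(len(eig))]
    return MFAResult(
        axis_variance_pct=pct,
        eigenvalues=eig,
        loadings=pd.DataFrame(vt.T, index=labels, columns=axes),
        scores=pd.DataFrame(u * s, index=table.index, columns=axes),
        group_weights=group_weights,
    )


@dataclass(frozen=True)
class VarianceComponents:
    trait: str
    sigma2_species: float
    sigma2_individual: float
    sigma2_twig: float
    pct_species: float
    pct_individual: float
    pct_twig: float
    degenerate: bool = False  # all values equal: percentages defined as 0

    def __post_init__(self):
        for v in (self.sigma2_species, self.sigma2_individual, self.sigma2_twig):
            if v < 0:
                raise ValueError("variance components must be nonnegative")


def _harmonic_mean(sizes: np.ndarray) -> float:
    sizes = np.asarray(sizes, dtype=float)
    return len(sizes) / np.sum(1.0 / sizes)


def nested_varcomp(
    twig_df: pd.DataFrame, trait: str, log10: bool = False
) -> VarianceComponents:
    """Species/individual/twig variance components for one trait column.

    ``twig_df`` must carry species and individual key columns.  With
    ``log10=True`` the partition is done on log10-transformed values, the
    scale on which multiplicative measurement noise is additive.
    """
    df = twig_df[["species", "individual", trait]].dropna().copy()
    if df["species"].nunique() < 2:
        raise ValueError("variance partitioning needs at least 2 species")
    y = df[trait].astype(float)
    if log10:
        if (y <= 0).any():
            raise ValueError(f"non-positive values in {trait!r}; cannot log10")
        y = np.log10(y)
    df["_y"] = y

    grand = df["_y"].mean()
    by_ind = df.groupby(["species", "individual"])["_y"].agg(["mean", "count"])
    by_sp = df.groupby("species")["_y"].agg(["mean", "count"])

    a = len(by_sp)
    ss_sp = float((by_sp["count"] * (by_sp["mean"] - grand) ** 2).sum())
    sp_of_ind = by_ind.index.get_level_values("species")
    sp_means = by_sp["mean"].reindex(sp_of_ind).values
    ss_ind = float((by_ind["count"] * (by_ind["mean"] - sp_means) ** 2).sum())
    ind_means = by_ind["mean"].reindex(
        pd.MultiIndex.from_frame(df[["species", "individual"]])
    ).values
    ss_twig = float(((df["_y"].values - ind_means) ** 2).sum())

    df_sp = a - 1
    df_ind = int((by_sp.index.map(
        lambda s: by_ind.loc[s].shape[0]).values - 1).sum())
    df_twig = int((by_ind["count"] - 1).sum())

    ms_sp = ss_sp / df_sp
    ms_ind = ss_ind / df_ind if df_ind > 0 else 0.0
    ms_twig = ss_twig / df_twig if df_twig > 0 else 0.0

    k_twig = _harmonic_mean(by_ind["count"].values)
    inds_per_sp = by_ind.groupby(level="species").size().values
    k_ind = _harmonic_mean(inds_per_sp)

    s2_twig = ms_twig
    s2_ind = (ms_ind - ms_twig) / k_twig if df_ind > 0 else 0.0
    s2_sp = (ms_sp - ms_ind) / (k_twig * k_ind)
    comps = np.maximum([s2_sp, s2_ind, s2_twig], 0.0)
    total = comps.sum()
    if total == 0:
        pct = np.zeros(3)
        degenerate = True
    else:
        pct = comps / total * 100.0
        degenerate = False
    return VarianceComponents(
        trait=trait,
        sigma2_species=float(comps[0]),
        sigma2_individual=float(comps[1]),
        sigma2_twig=float(comps[2]),
        pct_species=float(pct[0]),
        pct_individual=float(pct[1]),
        pct_twig=float(pct[2]),
        degenerate=degenerate,
    )
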