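"""Phylogenetic eigenvector regression and trait/phylogeny variance partition.

The variation of a proportion trait (e.g. molar sucrose share of nectar) is
split into three additive fractions: variation explained by floral traits
alone (a), by phylogeny alone (c), and by phylogenetically structured traits
— the overlap (b). Fractions come from likelihood-ratio pseudo-R² values of
four fractional-binomial fits (null, traits-only, phylogeny-only, full):

    a = R2_full - R2_phylo,  c = R2_full - R2_trait,
    b = R2_trait + R2_phylo - R2_full,

so a + b + c = R2_full identically. The "phylogeny" block is a set of PCoA
eigenvectors of the phylogenetic distance matrix, selected either by
stepwise AIC or by iterative reduction of residual Moran's I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm_engine import (
    GlmError,
    ModelSpec,
    all_subsets_select,
    fit_glm,
    pseudo_r2,
    stepwise_aic,
)
from .phylo import DistanceMatrix, EigenvectorBasis, morans_i

__all__ = [
    "VariancePartition",
    "pvr_select",
    "partition_variance",
    "pvr_pipeline",
    "PvrResult",
]


@dataclass
class VariancePartition:
    """Three-fraction split of explained variation in a proportion trait."""

    total: float  # R2 of the full (traits + eigenvectors) model
    pure_trait: float  # a
    shared: float  # b — phylogenetically structured traits
    pure_phylo: float  # c
    adjusted: bool

    def __post_init__(self) -> None:
        resid = self.pure_trait + self.shared + self.pure_phylo - self.total
        if abs(resid) > 1e-10:
            raise GlmError(f"partition fractions do not sum to the total (residual {resid})")
        if self.shared < 0:
            warnings.warn(
                "negative shared fraction: the trait and phylogeny blocks are "
                "jointly more informative than separately (suppression); "
                "reported as-is, not clipped"
            )

    @property
    def unexplained(self) -> float:
        return 1.0 - self.total

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "pure_trait": self.pure_trait,
            "shared": self.shared,
            "pure_phylo": self.pure_phylo,
            "unexplained": self.unexplained,
            "adjusted": self.adjusted,
        }


def _align(basis: EigenvectorBasis, y: pd.Series) -> pd.DataFrame:
    eig = basis.to_frame()
    unmatched = sorted(set(y.index).symmetric_difference(eig.index))
    if unmatched:
        raise GlmError(f"species labels do not match the eigenvector basis: {unmatched[:10]}")
    return eig.loc[y.index]


def pvr_select(
    basis: EigenvectorBasis,
    y: pd.Series,
    method: str = "aic",
    dm: DistanceMatrix | None = None,
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int = 0,
) -> list[str]:
    """Select phylogenetic eigenvectors explaining a proportion response.

    ``method="aic"``: stepwise AIC (direction "both") over all candidate
    eigenvector columns under the fractional-binomial GLM.

    ``method="moran"``: greedily add the eigenvector that most reduces the
    absolute Moran's I of the response residuals, until the permutation
    p-value of residual autocorrelation rises above ``alpha``; requires the
    distance matrix used to build the basis.
    """
    eig = _align(basis, y)
    data = eig.copy()
    data["_y"] = y
    candidates = list(eig.columns)
    if method == "aic":
        return stepwise_aic(candidates, data, ModelSpec("_y", family="binomial"))
    if method != "moran":
        raise GlmError(f"unknown selection method {method!r}")
    if dm is None:
        raise GlmError("method='moran' needs the distance matrix")
    order = [dm.labels.index(sp) for sp in y.index]
    sub_dm = DistanceMatrix(list(y.index), dm.D[np.ix_(order, order)])
    selected: list[str] = []
    while True:
        fit = fit_glm(ModelSpec("_y", selected, family="binomial"), data)
        resid = y.to_numpy(dtype=float) - fit.fitted
        if np.ptp(resid) == 0:
            break
        res = morans_i(resid, sub_dm, n_permutations=n_permutations, seed=seed)
        if res.p_value is not None and res.p_value >= alpha:
            break
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        best, best_abs_i = None, np.inf
        for c in remaining:
            f = fit_glm(ModelSpec("_y", selected + [c], family="binomial"), data)
            r = y.to_numpy(dtype=float) - f.fitted
            if np.ptp(r) == 0:
                abs_i = 0.0
            else:
                abs_i = abs(morans_i(r, sub_dm, n_permutations=0).I - (-1.0 / (len(y) - 1)))
            if abs_i < best_abs_i - 1e-12:
                best, best_abs_i = c, abs_i
        if best is None:
            break
        selected.append(best)
    return sorted(selected, key=candidates.index)


def partition_variance(
    y: pd.Series,
    traits: pd.DataFrame,
    eigenvectors: pd.DataFrame,
    adjusted: bool = False,
) -> VariancePartition:
    """Partition explained variation between traits, phylogeny, and overlap.

    ``traits`` and ``eigenvectors`` are species-aligned design blocks; an
    empty block contributes zero to its pure fraction. Unadjusted and
    adjusted pseudo-R² variants give the same additive structure.
    """
    data = pd.concat([traits, eigenvectors], axis=1)
    if data.isna().any().any():
        raise GlmError("missing values after aligning traits and eigenvectors")
    data = data.copy()
    data["_y"] = y
    t_cols = list(traits.columns)
    p_cols = list(eigenvectors.columns)
    null = fit_glm(ModelSpec("_y", [], family="binomial"), data)

    def r2_of(cols: list[str]) -> float:
        if not cols:
            return 0.0
        fit = fit_glm(ModelSpec("_y", cols, family="binomial"), data)
        return pseudo_r2(fit, null, adjusted=adjusted)

    r2_t = r2_of(t_cols)
    r2_p = r2_of(p_cols)
    r2_f = r2_of(t_cols + p_cols)
    a = r2_f - r2_p
    c = r2_f - r2_t
    b = r2_t + r2_p - r2_f
    return VariancePartition(r2_f, a, b, c, adjusted)


@dataclass
class PvrResult:
    """Full PVR flow: stage-1 eigenvectors, joint survivors, partitions."""

    stage1_eigenvectors: list[str]
    survivors: list[str]  # predictor union of the delta-AIC < 2 set
    partition_unadjusted: VariancePartition
    partition_adjusted: VariancePartition
    used_fallback: bool

    def to_dict(self) -> dict:
        return {
            "stage1_eigenvectors": self.stage1_eigenvectors,
            "survivors": self.survivors,
            "partition_unadjusted": self.partition_unadjusted.to_dict(),
            "partition_adjusted": self.partition_adjusted.to_dict(),
            "used_fallback": self.used_fallback,
        }


def pvr_pipeline(
    y: pd.Series,
    traits: pd.DataFrame,
    basis: EigenvectorBasis,
    selection_method: str = "aic",
    dm: DistanceMatrix | None = None,
    fallback_all_eigenvectors: bool = True,
    max_joint_candidates: int = 14,
    seed: int = 0,
) -> PvrResult:
    """Two-stage PVR flow ending in the three-fraction partition.

    Stage 1 selects eigenvectors on the response alone. Stage 2 runs
    all-subsets multimodel inference jointly over the selected eigenvectors
    and the trait columns, keeping the union of predictors of the
    delta-AIC < 2 model set. The partition then uses the surviving trait and
    eigenvector columns as its two blocks. When stage 1 retains nothing and
    ``fallback_all_eigenvectors`` is set, all eigenvectors enter stage 2
    (capped at ``max_joint_candidates`` together with the traits).
    """
    eig = _align(basis, y)
    stage1 = pvr_select(basis, y, method=selection_method, dm=dm, seed=seed)
    used_fallback = False
    eig_candidates = stage1
    if not eig_candidates and fallback_all_eigenvectors:
        used_fallback = True
        cap = max(max_joint_candidates - len(traits.columns), 0)
        eig_candidates = list(eig.columns[:cap])
    t_cols = list(traits.columns)
    candidates = eig_candidates + t_cols
    if len(candidates) > max_joint_candidates:
        # keep all traits; truncate eigenvectors beyond the guard
        keep_eig = max_joint_candidates - len(t_cols)
        candidates = eig_candidates[:keep_eig] + t_cols
    data = pd.concat([traits, eig], axis=1)
    data["_y"] = y
    sel = all_subsets_select(candidates, data, ModelSpec("_y", family="binomial"))
    survivors = sel.predictor_union
    surv_t = [c for c in survivors if c in t_cols]
    surv_e = [c for c in survivors if c not in t_cols]
    part_u = partition_variance(y, traits[surv_t], eig[surv_e], adjusted=False)
    part_a = partition_variance(y, traits[surv_t], eig[surv_e], adjusted=True)
    return PvrResult(stage1, survivors, part_u, part_a, used_fallback)
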