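"""Plant–pollinator meta-network aggregation and species-level specialisation.

Local visitation networks (one per site and sampling round) are standardised
by their own interaction totals, averaged cell-wise, and rescaled to the
grand total of observed interactions — the "meta-network". From it each
species' specialisation d (Blüthgen's Kullback–Leibler divergence of its
partner-use distribution from partner availability) and the rescaled
d' = (d - d_min)/(d_max - d_min) in [0, 1] are computed. Gaussian mixed
models then relate d' of pollinators to the visit-weighted nectar sucrose
of the plants they visit (and of plants to their own sucrose), with
taxonomic random intercepts and AICc-based multimodel inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "InteractionNetwork",
    "MetaNetwork",
    "SpecialisationResult",
    "build_meta_network",
    "d_prime",
    "kl_specialisation",
    "integer_d_bounds",
    "weighted_sucrose_exposure",
    "specialisation_models",
    "read_edge_lists",
    "GUILDS",
]

GUILDS = ("solitary_bee", "bumble_bee", "hoverfly", "honey_bee")


class NetworkError(ValueError):
    """Invalid network input."""


@dataclass
class InteractionNetwork:
    """Weighted plants x pollinators visitation matrix for one site & round."""

    site: str
    round: str
    counts: pd.DataFrame  # rows: plants, cols: pollinators
    guilds: dict[str, str] = field(default_factory=dict)  # pollinator -> guild

    def __post_init__(self) -> None:
        m = self.counts.to_numpy(dtype=float)
        if np.any(m < 0):
            raise NetworkError(f"negative counts in network {self.site}/{self.round}")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise NetworkError(f"duplicate labels in network {self.site}/{self.round}")
        bad = [p for p, g in self.guilds.items() if g not in GUILDS]
        if bad:
            raise NetworkError(f"unknown guild for pollinators {bad[:5]}; valid: {GUILDS}")

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())


@dataclass
class MetaNetwork:
    """Pooled, standardised, rescaled aggregate of local networks."""

    matrix: pd.DataFrame  # plants x pollinators, continuous weights
    n_total: float  # total observed interactions across all networks
    correction_factor: float
    guilds: dict[str, str] = field(default_factory=dict)

    def restrict_guild(self, guild: str) -> "MetaNetwork":
        """Sub-meta-network keeping only pollinators of one guild."""
        if guild not in GUILDS:
            raise NetworkError(f"unknown guild {guild!r}")
        cols = [c for c in self.matrix.columns if self.guilds.get(c) == guild]
        sub = self.matrix[cols]
        sub = sub.loc[sub.sum(axis=1) > 0]
        return MetaNetwork(sub, float(sub.to_numpy().sum()), 1.0,
                           {c: self.guilds[c] for c in cols})


@dataclass
class SpecialisationResult:
    species: str
    side: str  # "plants" | "pollinators"
    d: float
    d_min: float
    d_max: float

    @property
    def d_prime(self) -> float:
        if self.d_max > self.d_min:
            return (self.d - self.d_min) / (self.d_max - self.d_min)
        return 0.0


def build_meta_network(
    networks: list[InteractionNetwork],
    correction_factor: float = 1.0,
    pooling: str = "all",
) -> MetaNetwork:
    """Standardise, pool, and rescale local networks into a meta-network.

    Each network's counts are divided by its own total; the standardised
    matrices are averaged cell-wise over all K networks (``pooling="all"``,
    species absent from a network contributing zeros) or over only the
    networks where the cell's plant and pollinator both occur
    (``pooling="present"``); the average is rescaled by the grand total of
    interactions times ``correction_factor``. With ``correction_factor=1``
    the meta-network total equals the grand total exactly.
    """
    if not networks:
        raise NetworkError("need at least one network")
    seen = set()
    for nw in networks:
        key = (nw.site, nw.round)
        if key in seen:
            raise NetworkError(f"duplicate (site, round) pair {key}")
        seen.add(key)
    usable = []
    for nw in networks:
        if nw.total == 0:
            warnings.warn(f"network {nw.site}/{nw.round} has no interactions; excluded")
        else:
            usable.append(nw)
    if not usable:
        raise NetworkError("all networks are empty")
    plants = sorted({p for nw in usable for p in nw.counts.index})
    pols = sorted({c for nw in usable for c in nw.counts.columns})
    K = len(usable)
    acc = np.zeros((len(plants), len(pols)))
    present = np.zeros((len(plants), len(pols)))
    n_total = 0.0
    for nw in usable:
        n_total += nw.total
        s = nw.counts.reindex(index=plants, columns=pols, fill_value=0.0).to_numpy(dtype=float)
        acc += s / nw.total
        pr = np.outer(nw.counts.reindex(index=plants, fill_value=0.0).sum(axis=1) > 0,
                      nw.counts.reindex(columns=pols, fill_value=0.0).sum(axis=0) > 0)
        present += pr
    if pooling == "all":
        pooled = acc / K
    elif pooling == "present":
        # mean over only the networks where both partners were recorded
        pooled = np.where(present > 0, acc / np.maximum(present, 1), 0.0)
    else:
        raise NetworkError(f"unknown pooling {pooling!r}")
    final = pooled * n_total * correction_factor
    if pooling == "all":
        # conservation: mean of per-network proportions sums to 1
        assert abs(final.sum() - n_total * correction_factor) < 1e-6 * max(n_total, 1)
    guilds: dict[str, str] = {}
    for nw in usable:
        guilds.update(nw.guilds)
    return MetaNetwork(pd.DataFrame(final, index=plants, columns=pols),
                       n_total, correction_factor, guilds)


# ---------------------------------------------------------------------------
# Specialisation d and d'


def kl_specialisation(use: np.ndarray, availability: np.ndarray) -> float:
    """d = KL divergence of a partner-use distribution from availability.

    ``use`` is the focal species' interaction vector (any non-negative
    weights); ``availability`` the partner marginal distribution. Terms with
    zero use contribute zero (0 * ln 0 = 0).
    """
    use = np.asarray(use, dtype=float)
    q = np.asarray(availability, dtype=float)
    if use.sum() <= 0:
        raise NetworkError("zero-total species has no use distribution")
    p = use / use.sum()
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise NetworkError("used partner has zero availability")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def integer_d_bounds(total: int, availability: np.ndarray) -> tuple[float, float]:
    """Exact d_min and d_max over integer allocations of ``total`` units.

    d as a function of the allocation is separable convex, so the minimum is
    reached by the greedy marginal-increment rule (provably exact on the
    integer simplex) and the maximum at a vertex: all units on the partner
    with the smallest availability.
    """
    q = np.asarray(availability, dtype=float)
    total = int(total)
    if total <= 0:
        raise NetworkError("total must be a positive integer")
    if np.any(q <= 0):
        raise NetworkError("availabilities must be strictly positive")
    # greedy minimisation of sum c_j ln c_j - c_j ln(total * q_j)
    c = np.zeros(q.size, dtype=int)

    def marginal(j):
        cj = c[j]
        return (cj + 1) * np.log(cj + 1) - (cj * np.log(cj) if cj else 0.0) \
            - np.log(total * q[j])

    for _ in range(total):
        j = min(range(q.size), key=lambda jj: (marginal(jj), jj))
        c[j] += 1
    p = c / total
    mask = p > 0
    d_min = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    d_max = float(np.log(1.0 / q.min()))
    return d_min, d_max


def d_prime(
    meta: MetaNetwork,
    side: str = "pollinators",
    integer_bounds: str = "auto",
) -> list[SpecialisationResult]:
    """Species-level specialisation for every species on one side.

    Availabilities are the opposite side's marginal totals of the full
    (possibly guild-restricted) meta-network, including the focal species'
    own interactions. Continuous matrices use the analytic bounds d_min = 0
    and d_max = ln(1/q_min); integral matrices (``integer_bounds="auto"``,
    or forced with ``"always"``) use exact integer-allocation bounds.
    Zero-total species are omitted with a warning.
    """
    if side == "pollinators":
        M = meta.matrix.T
    elif side == "plants":
        M = meta.matrix
    else:
        raise NetworkError(f"side must be 'plants' or 'pollinators', got {side!r}")
    A = M.to_numpy(dtype=float)
    keep = A.sum(axis=0) > 0  # partners never interacted with are not resources
    A = A[:, keep]
    grand = A.sum()
    q = A.sum(axis=0) / grand  # availability of partners (columns of M)
    is_integer = np.allclose(A, np.round(A), atol=1e-9)
    use_integer = integer_bounds == "always" or (integer_bounds == "auto" and is_integer)
    results = []
    for i, speciez in enumerate(M.index):
        row = A[i]
        if row.sum() <= 0:
            warnings.warn(f"species {speciez!r} has no interactions; omitted from d'")
            continue
        d = kl_specialisation(row, q)
        if use_integer:
            d_min, d_max = integer_d_bounds(int(round(row.sum())), q)
        else:
            d_min, d_max = 0.0, float(np.log(1.0 / q[q > 0].min()))
        results.append(SpecialisationResult(str(speciez), side, d, d_min, d_max))
    return results


def weighted_sucrose_exposure(meta: MetaNetwork, traits: pd.DataFrame) -> pd.DataFrame:
    """Visit-weighted floral exposure per pollinator.

    For pollinator i with visit weights w_ij: the weighted mean sucrose
    proportion of the plants visited, the weighted mean corolla tube length,
    and the visit-weighted share of zygomorphic flowers. ``traits`` must be
    indexed by plant species with columns ``sucrose_proportion``,
    ``tube_length_mm``, ``symmetry`` (actinomorphic/zygomorphic).
    """
    visited = meta.matrix.index[meta.matrix.sum(axis=1) > 0]
    missing = [p for p in visited if p not in traits.index]
    if missing:
        raise NetworkError(f"visited plants missing trait values: {missing[:10]}")
    rows = {}
    for pol in meta.matrix.columns:
        w = meta.matrix[pol]
        w = w[w > 0]
        if w.empty:
            continue
        t = traits.loc[w.index]
        wsum = w.sum()
        rows[pol] = {
            "sucrose_exposure": float((w * t["sucrose_proportion"]).sum() / wsum),
            "tube_length_exposure": float((w * t["tube_length_mm"]).sum() / wsum),
            "zygomorphy_share": float(
                (w * (t["symmetry"] == "zygomorphic")).sum() / wsum
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Mixed models of d' against nectar sucrose


GUILD_SUBSETS = ("all", "solitary_bees", "bumble_bees", "hoverflies", "plants")
_GUILD_KEY = {"solitary_bees": "solitary_bee", "bumble_bees": "bumble_bee",
              "hoverflies": "hoverfly"}


@dataclass
class SpecialisationModel:
    guild_subset: str
    n: int
    selected_predictors: list[str]
    coefficients: dict[str, float]
    sucrose_slope: float
    sucrose_slope_se: float
    sucrose_ci: tuple[float, float]
    sucrose_p: float
    marginal_r2: float
    conditional_r2: float
    aicc_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "guild_subset": self.guild_subset,
            "n": self.n,
            "selected_predictors": self.selected_predictors,
            "coefficients": self.coefficients,
            "sucrose_slope": self.sucrose_slope,
            "sucrose_slope_se": self.sucrose_slope_se,
            "sucrose_ci": list(self.sucrose_ci),
            "sucrose_p": self.sucrose_p,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
        }


def _aicc(ll: float, k: int, n: int) -> float:
    aic = -2 * ll + 2 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _fit_gaussian(d: pd.DataFrame, predictors: list[str], group: str | None):
    """ML gaussian fit, mixed (random intercept) when a group is given.

    When the group variance sits on the boundary the MixedLM Hessian can be
    singular; the fit then falls back to the boundary solution (an OLS fit
    with zero group variance) while keeping the variance parameter in k.
    """
    rhs = " + ".join(predictors) if predictors else "1"
    if group is None:
        fit = smf.ols(f"dprime ~ {rhs}", data=d).fit()
        k = len(fit.params) + 1
        return fit, float(fit.llf), k, 0.0, float(np.var(fit.resid, ddof=0))
    try:
        md = smf.mixedlm(f"dprime ~ {rhs}", data=d, groups=d[group])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=False, method="lbfgs")
        k = len(fit.fe_params) + 2  # + group variance + residual variance
        gvar = float(fit.cov_re.iloc[0, 0])
        return fit, float(fit.llf), k, gvar, float(fit.scale)
    except np.linalg.LinAlgError:
        fit = smf.ols(f"dprime ~ {rhs}", data=d).fit()
        k = len(fit.params) + 2
        return fit, float(fit.llf), k, 0.0, float(np.var(fit.resid, ddof=0))


def specialisation_models(
    d_results: list[SpecialisationResult],
    exposures: pd.DataFrame | None,
    taxonomy: pd.DataFrame,
    guild_subset: str = "all",
    plant_traits: pd.DataFrame | None = None,
    delta: float = 2.0,
) -> SpecialisationModel:
    """Gaussian (mixed) models of d' against nectar sucrose.

    For pollinator subsets the sucrose predictor is the visit-weighted
    sucrose exposure (plus tube-length exposure and zygomorphy share); for
    ``"plants"`` it is the species' own sucrose proportion plus its floral
    traits. Random-intercept structure follows the guild rules: plain
    regression for bumble bees, genus random intercept for hoverflies,
    taxonomic family otherwise; a random level with fewer than three groups
    is dropped with a warning. Model choice is AICc-based all-subsets
    inference; the sucrose slope and its Wald CI are reported from the full
    model so that the inference is available even when the term is dropped.
    """
    if guild_subset not in GUILD_SUBSETS:
        raise NetworkError(f"guild_subset must be one of {GUILD_SUBSETS}")
    rows = []
    for r in d_results:
        rows.append({"species": r.species, "dprime": r.d_prime})
    d = pd.DataFrame(rows).set_index("species")
    if guild_subset == "plants":
        if plant_traits is None:
            raise NetworkError("plants subset needs the plant trait table")
        d = d.join(plant_traits[["sucrose_proportion", "tube_length_mm", "symmetry"]],
                   how="inner")
        d["zygomorphic"] = (d["symmetry"] == "zygomorphic").astype(float)
        predictors = ["sucrose_proportion", "tube_length_mm", "zygomorphic"]
        sucrose_term = "sucrose_proportion"
    else:
        if exposures is None:
            raise NetworkError("pollinator subsets need the exposure table")
        d = d.join(exposures, how="inner")
        predictors = ["sucrose_exposure", "tube_length_exposure", "zygomorphy_share"]
        sucrose_term = "sucrose_exposure"
    d = d.join(taxonomy, how="left")
    group = {"bumble_bees": None, "hoverflies": "genus"}.get(guild_subset, "taxon_family")
    if group is not None and (group not in d.columns or d[group].isna().any()):
        raise NetworkError(f"taxonomy table lacks a complete {group!r} column")
    if group is not None and d[group].nunique() < 3:
        warnings.warn(f"fewer than 3 groups at random level {group!r}; dropping it")
        group = None
    predictors = [p for p in predictors if d[p].nunique() > 1]  # drop constants
    if sucrose_term not in predictors:
        warnings.warn(f"{sucrose_term} is constant; its slope is not estimable")
    # all-subsets AICc table
    import itertools as it

    table_rows = []
    for rsize in range(len(predictors) + 1):
        for subset in it.combinations(predictors, rsize):
            _, ll, k, _, _ = _fit_gaussian(d, list(subset), group)
            table_rows.append({"predictors": subset, "k": k,
                               "loglik": ll, "aicc": _aicc(ll, k, len(d))})
    table = pd.DataFrame(table_rows)
    table["delta"] = table["aicc"] - table["aicc"].min()
    table = table.sort_values(["aicc", "k"], kind="mergesort").reset_index(drop=True)
    best_set = [tuple(p) for p in table.loc[table["delta"] < delta, "predictors"]]
    selected = sorted({p for s in best_set for p in s},
                      key=lambda p: predictors.index(p))
    # inference from the full model
    full_predictors = predictors if predictors else []
    fit, ll, k, gvar, rvar = _fit_gaussian(d, full_predictors, group)
    params = fit.fe_params if hasattr(fit, "fe_params") else fit.params
    bse = fit.bse_fe if hasattr(fit, "bse_fe") else fit.bse
    pvals = fit.pvalues
    if gvar <= 1e-8 and full_predictors:
        # at the variance boundary the mixed fit is an OLS fit; d' residuals
        # are strongly heteroskedastic (specialists are noisier), so report
        # a heteroskedasticity-robust (HC3) covariance there
        rhs = " + ".join(full_predictors)
        ols = smf.ols(f"dprime ~ {rhs}", data=d).fit()
        rob = ols.get_robustcov_results(cov_type="HC3")
        bse = pd.Series(rob.bse, index=ols.params.index)
        pvals = pd.Series(rob.pvalues, index=ols.params.index)
    if sucrose_term in params.index:
        slope = float(params[sucrose_term])
        se = float(bse[sucrose_term])
        ci = (slope - 1.96 * se, slope + 1.96 * se)
        p = float(pvals[sucrose_term])
    else:
        slope, se, ci, p = np.nan, np.nan, (np.nan, np.nan), np.nan
    X = pd.DataFrame({"Intercept": np.ones(len(d))}, index=d.index)
    for pr in full_predictors:
        X[pr] = d[pr].to_numpy(dtype=float)
    fixed_pred = X.to_numpy() @ params.reindex(X.columns).to_numpy()
    var_f = float(np.var(fixed_pred))
    denom = var_f + gvar + rvar
    marg = var_f / denom if denom > 0 else 0.0
    cond = (var_f + gvar) / denom if denom > 0 else 0.0
    coefs = {str(k_): float(v) for k_, v in params.items()}
    return SpecialisationModel(
        guild_subset, len(d), selected, coefs, slope, se, ci, p,
        marg, cond, table,
    )


# ---------------------------------------------------------------------------
# Edge-list I/O


def read_edge_lists(path) -> list[InteractionNetwork]:
    """Read a CSV of site,round,plant,pollinator,guild,count into networks."""
    df = pd.read_csv(path)
    required = {"site", "round", "plant", "pollinator", "guild", "count"}
    if not required.issubset(df.columns):
        raise NetworkError(f"edge-list CSV needs columns {sorted(required)}")
    networks = []
    for (site, rnd), sub in df.groupby(["site", "round"], sort=True):
        counts = sub.pivot_table(index="plant", columns="pollinator",
                                 values="count", aggfunc="sum", fill_value=0.0)
        guilds = dict(zip(sub["pollinator"], sub["guild"]))
        networks.append(InteractionNetwork(str(site), str(rnd), counts, guilds))
    return networks


def write_edge_lists(networks: list[InteractionNetwork], path) -> None:
    rows = []
    for nw in networks:
        for plant in nw.counts.index:
            for pol in nw.counts.columns:
                c = nw.counts.loc[plant, pol]
                if c > 0:
                    rows.append({"site": nw.site, "round": nw.round, "plant": plant,
                                 "pollinator": pol, "guild": nw.guilds.get(pol, ""),
                                 "count": c})
    pd.DataFrame(rows).to_csv(path, index=False)
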