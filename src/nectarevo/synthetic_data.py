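"""Synthetic phylogenies, traits, temperature series, and visitation networks.

The generator emulates the statistical structure the analysis assumes: a
dated ultrametric phylogeny with nested family/order clades; a nectar sugar
trait whose logit combines a paleotemperature effect at family origin with
Brownian motion along the tree (the phylogenetic-signal mechanism); a
smooth, noisy global-temperature decline from a Cretaceous greenhouse
(~33 degC) to the present (~13 degC); and site-by-round visitation networks
in which latently specialised pollinators are tilted toward sucrose-rich
plants with a controllable coupling strength gamma.

Every generator is fully deterministic under the configured seed. The
default scale (200 species, ~40 families, ~12 orders, 8 sites x 3 rounds)
keeps the full pipeline fast; a study-scale configuration (414 species,
16 sites) is available via :func:`study_scale_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .networks import InteractionNetwork
from .paleo import TemperatureSeries, interpolate_temperature
from .phylo import Phylogeny

__all__ = [
    "SimulationConfig",
    "study_scale_config",
    "simulate_tree",
    "simulate_temperature_series",
    "simulate_sucrose_trait",
    "simulate_networks",
    "simulate_dataset",
    "SyntheticDataset",
]

TEMP_CENTER_C = 23.0  # centring constant for the temperature effect
FLOWER_COLOURS = ("white", "yellow", "violet", "purple", "pink", "red", "blue")
FLOWER_TYPES = ("disk", "funnel", "bell", "lip", "flag", "head", "brush")
POLLINATION_TYPES = ("generalised", "hymenopteran", "bee", "bumble_bee",
                     "butterfly", "fly")
# guild composition anchored to the study system's species split
GUILD_PROBS = {"solitary_bee": 150 / 187, "bumble_bee": 13 / 187, "hoverfly": 24 / 187}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study system.

    Rates and standard deviations are non-negative; ``bm_sigma`` is the
    Brownian-motion sd per sqrt(My) on the logit scale (tip sd over a
    height-100 tree is ``bm_sigma * 10``); ``beta_temp`` the logit change
    per degC of GMST at family origin; ``gamma`` the sucrose-specialisation
    coupling of the network generator.
    """

    seed: int
    n_species: int = 200
    birth_rate: float = 1.0
    tree_height_ma: float = 100.0
    family_depth_ma: float = 25.0
    order_depth_ma: float = 50.0
    bm_sigma: float = 0.1
    beta_temp: float = 0.1
    logit_intercept: float = -0.5
    temp_start_c: float = 33.0
    temp_end_c: float = 13.0
    temp_step_my: float = 0.2
    temp_noise_sd: float = 1.5
    temp_ar1: float = 0.9
    n_sites: int = 8
    n_rounds: int = 3
    n_pollinators: int = 120
    n_network_plants: int = 123
    gamma: float = 1.0
    visits_per_network: int = 100
    base_concentration: float = 20.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("birth_rate", "bm_sigma", "temp_noise_sd", "base_concentration"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        if not (0 < self.family_depth_ma < self.tree_height_ma):
            raise ConfigError("family_depth_ma must lie inside (0, tree height)")
        if not (self.family_depth_ma < self.order_depth_ma < self.tree_height_ma):
            raise ConfigError("order_depth_ma must lie in (family depth, tree height)")


def study_scale_config(seed: int) -> SimulationConfig:
    """Configuration at the scale of the study system (414 species, 16 sites)."""
    return SimulationConfig(
        seed=seed, n_species=414, family_depth_ma=34.0, order_depth_ma=50.0,
        n_sites=16, n_rounds=3, n_pollinators=188, n_network_plants=123,
        visits_per_network=100,
    )


def _child_seed(config: SimulationConfig, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is salted per run)
    import zlib

    ss = np.random.SeedSequence([config.seed % (2**31), zlib.crc32(stream.encode())])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Phylogeny


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_species`` tips, scaled to the target height.

    Families and orders are the clades induced by cutting the tree at the
    configured depths: each edge spanning the cut depth roots one clade, so
    families nest within orders by construction. Single-lineage crossings
    yield monotypic clades.
    """
    rng = _child_seed(config, "tree")
    n = config.n_species
    # forward simulation: split a uniformly chosen lineage at exponential times
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (config.birth_rate * k))
        idx = rng.integers(k)
        parent = active.pop(idx)
        parent.edge.length = t - parent.birth_time
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (config.birth_rate * n))
    for i, leaf in enumerate(active):
        leaf.edge.length = t_end - leaf.birth_time
    # deterministic tip order: assign labels in ladderised preorder
    root.edge.length = None
    scale = config.tree_height_ma / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    i = 0
    for leaf in tree.leaf_node_iter():
        taxon = taxon_namespace.new_taxon(f"sp{i + 1:04d}")
        leaf.taxon = taxon
        i += 1
    clade_map = _cut_clades(tree, config.family_depth_ma, config.order_depth_ma,
                            config.tree_height_ma)
    return Phylogeny(tree, clade_map)


def _cut_clades(tree: dendropy.Tree, family_depth: float, order_depth: float,
                height: float) -> dict[str, tuple[str, str]]:
    """Assign each tip the clade rooted at the edge crossing each cut depth."""
    ages: dict = {}
    # node age = height - depth-from-root (tree is ultrametric by construction)
    depths: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + node.edge.length
    for node, d in depths.items():
        ages[node] = height - d

    def clade_index(depth_cut: float) -> dict[str, int]:
        assignment: dict[str, int] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            parent_age = ages[parent] if parent is not None else np.inf
            if ages[node] <= depth_cut < parent_age:
                counter += 1
                for leaf in node.leaf_iter():
                    assignment[leaf.taxon.label] = counter
        return assignment

    fams = clade_index(family_depth)
    orders = clade_index(order_depth)
    return {
        tip: (f"fam{fams[tip]:03d}", f"ord{orders[tip]:02d}")
        for tip in fams
    }


# ---------------------------------------------------------------------------
# Temperature series


# Monotone cooling profile: fraction of the total start-to-end range remaining
# at each age, anchored to the canonical shape of the last 100 My of climate
# (greenhouse plateau, gradual Cretaceous/Paleogene decline, sharp step at the
# Eocene-Oligocene transition ~34 Ma, icehouse descent to the present).
TREND_ANCHOR_AGES = np.array([100.0, 90.0, 66.0, 50.0, 35.0, 34.0, 15.0, 2.5, 0.0])
TREND_ANCHOR_FRACS = np.array([1.0, 0.97, 0.80, 0.75, 0.55, 0.30, 0.22, 0.05, 0.0])


def simulate_temperature_series(config: SimulationConfig) -> TemperatureSeries:
    """GMST series on a uniform grid from 100 Ma to the present.

    The trend declines monotonically from ``temp_start_c`` at the oldest
    point to ``temp_end_c`` today, following a piecewise-linear
    greenhouse-to-icehouse profile with a sharp Eocene-Oligocene step;
    stationary AR(1) wiggles of marginal sd ``temp_noise_sd`` are
    superimposed. Noise sd 0 gives the exact trend at every grid point.
    """
    rng = _child_seed(config, "temperature")
    t_max = config.tree_height_ma
    n_steps = round(t_max / config.temp_step_my)
    if abs(n_steps * config.temp_step_my - t_max) > 1e-9:
        raise ConfigError("temp_step_my must divide the series range")
    times = np.linspace(t_max, 0.0, n_steps + 1)
    frac = np.interp(times[::-1] / t_max * 100.0,
                     TREND_ANCHOR_AGES[::-1], TREND_ANCHOR_FRACS[::-1])[::-1]
    trend = config.temp_end_c + (config.temp_start_c - config.temp_end_c) * frac
    if config.temp_noise_sd > 0:
        phi = config.temp_ar1
        innov_sd = config.temp_noise_sd * np.sqrt(1 - phi**2)
        noise = np.empty(times.size)
        noise[0] = rng.normal(0, config.temp_noise_sd)
        for i in range(1, times.size):
            noise[i] = phi * noise[i - 1] + rng.normal(0, innov_sd)
    else:
        noise = np.zeros(times.size)
    return TemperatureSeries(times, trend + noise)


# ---------------------------------------------------------------------------
# Traits


def _brownian_tips(tree: dendropy.Tree, sigma: float, rng: np.random.Generator) -> pd.Series:
    """Brownian motion along the tree from a zero root state; tip values."""
    values: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        values[node] = values[node.parent_node] + rng.normal(0.0, sigma * np.sqrt(bl))
    return pd.Series({leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()})


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_sucrose_trait(
    phylo: Phylogeny, series: TemperatureSeries, config: SimulationConfig
) -> pd.DataFrame:
    """Species trait table with a phylogenetically structured sucrose trait.

    logit(sucrose) = intercept + beta_temp * (T(family crown age) - 23 degC)
    + BM(bm_sigma). The table also carries the fructose share of hexoses
    (weak-signal BM), corolla tube length (log-normal, positively linked to
    the sucrose latent), flower symmetry (thresholded latent BM), and
    uniform flower colour / flower type / pollination type categoricals —
    mirroring the covariates of the floral trait analysis.
    """
    from .phylo import clade_crown_ages

    rng = _child_seed(config, "traits")
    tree = phylo.tree
    tips = phylo.tip_labels
    fam_ages = clade_crown_ages(phylo, "family")
    fam_of = {sp: fo[0] for sp, fo in phylo.clade_map.items()}
    ages = np.array([fam_ages[fam_of[sp]] for sp in tips])
    temps = interpolate_temperature(series, np.minimum(ages, series.max_age))
    bm = _brownian_tips(tree, config.bm_sigma, rng)[tips].to_numpy()
    eta = config.logit_intercept + config.beta_temp * (temps - TEMP_CENTER_C) + bm
    sucrose = _inv_logit(eta)
    bm_fruct = _brownian_tips(tree, config.bm_sigma * 0.3, rng)[tips].to_numpy()
    fructose = _inv_logit(0.1 + bm_fruct + rng.normal(0, 0.5, len(tips)))
    tube_latent = _brownian_tips(tree, config.bm_sigma, rng)[tips].to_numpy()
    tube = np.exp(1.0 + 0.5 * tube_latent + 0.3 * (eta - eta.mean()))
    sym_latent = _brownian_tips(tree, config.bm_sigma, rng)[tips].to_numpy() \
        + 0.3 * (eta - eta.mean())
    symmetry = np.where(sym_latent > np.median(sym_latent), "zygomorphic", "actinomorphic")
    return pd.DataFrame(
        {
            "sucrose_proportion": sucrose,
            "fructose_within_hexoses": fructose,
            "tube_length_mm": tube,
            "symmetry": symmetry,
            "colour": rng.choice(FLOWER_COLOURS, len(tips)),
            "flower_type": rng.choice(FLOWER_TYPES, len(tips)),
            "pollination_type": rng.choice(POLLINATION_TYPES, len(tips)),
            "family": [phylo.clade_map[sp][0] for sp in tips],
            "order": [phylo.clade_map[sp][1] for sp in tips],
        },
        index=pd.Index(tips, name="species"),
    )


# ---------------------------------------------------------------------------
# Networks


def simulate_networks(
    traits: pd.DataFrame, config: SimulationConfig
) -> tuple[list[InteractionNetwork], pd.DataFrame]:
    """Site-by-round visitation networks with sucrose-linked specialisation.

    Each pollinator carries a latent specialisation s in (0, 1). Its plant
    preference is a Dirichlet draw whose concentration falls as s rises
    (specialists concentrate on few plants) and whose mean is tilted toward
    sucrose-rich plants with strength ``gamma * s``. Every network draws
    ``visits_per_network`` interactions from the joint activity-preference
    distribution. Returns the networks and a pollinator table (guild,
    genus, family, latent specialisation).
    """
    rng = _child_seed(config, "networks")
    n_plants = min(config.n_network_plants, len(traits))
    plant_idx = rng.choice(len(traits), size=n_plants, replace=False)
    plants = traits.index[np.sort(plant_idx)]
    z = traits.loc[plants, "sucrose_proportion"].to_numpy()
    z = (z - z.mean()) / max(z.std(), 1e-12)
    abundance = rng.lognormal(0.0, 0.3, n_plants)
    n_pol = config.n_pollinators
    s = rng.beta(2.0, 2.0, n_pol)
    guilds = _assign_guilds(n_pol, rng)
    n_genera = max(n_pol // 3, 1)
    n_families = max(n_pol // 8, 2)
    genus = [f"gen{g + 1:03d}" for g in rng.integers(0, n_genera, n_pol)]
    family = [f"pfam{f + 1:02d}" for f in rng.integers(0, n_families, n_pol)]
    # Sucrose-rich flowers are deep/exclusive: below-average specialists are
    # repelled and strong specialists attracted, in proportion to gamma. The
    # tilt is centred on s = 0.5 so that gamma = 0 leaves visitation entirely
    # unstructured by sucrose (a clean null), while gamma > 0 makes
    # sucrose-rich plants rare overall yet favoured by specialists.
    pref = np.empty((n_pol, n_plants))
    for i in range(n_pol):
        w = abundance * np.exp(config.gamma * (s[i] - 0.5) * 2.0 * z)
        base = w / w.sum()
        # concentration decays geometrically in s: generalists (s ~ 0) track
        # the base closely, specialists (s -> 1) concentrate on ~one plant
        alpha0 = config.base_concentration * (0.5 / config.base_concentration) ** s[i]
        pref[i] = rng.dirichlet(np.maximum(alpha0 * base, 1e-2))
    activity = rng.lognormal(0.0, 0.5, n_pol)
    joint = (activity[:, None] * pref).ravel()
    joint = joint / joint.sum()
    pol_names = [f"pol{i + 1:03d}" for i in range(n_pol)]
    networks = []
    for site in range(config.n_sites):
        for rnd in range(config.n_rounds):
            draw = rng.multinomial(config.visits_per_network, joint)
            counts = draw.reshape(n_pol, n_plants).T  # plants x pollinators
            df = pd.DataFrame(counts.astype(float), index=list(plants), columns=pol_names)
            networks.append(
                InteractionNetwork(f"site{site + 1:02d}", f"round{rnd + 1}", df,
                                   dict(zip(pol_names, guilds)))
            )
    pol_table = pd.DataFrame(
        {"guild": guilds, "genus": genus, "taxon_family": family,
         "latent_specialisation": s},
        index=pd.Index(pol_names, name="species"),
    )
    return networks, pol_table


def _assign_guilds(n_pol: int, rng: np.random.Generator) -> list[str]:
    """One honey bee; the rest split per the study's guild proportions."""
    guilds = ["honey_bee"]
    names = list(GUILD_PROBS)
    probs = np.array([GUILD_PROBS[g] for g in names])
    draws = rng.choice(names, size=max(n_pol - 1, 0), p=probs / probs.sum())
    guilds.extend(draws.tolist())
    return guilds[:n_pol]


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    phylogeny: Phylogeny
    temperature: TemperatureSeries
    traits: pd.DataFrame
    networks: list[InteractionNetwork]
    pollinators: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study: tree, temperatures, traits, networks."""
    phylo = simulate_tree(config)
    series = simulate_temperature_series(config)
    traits = simulate_sucrose_trait(phylo, series, config)
    networks, pol_table = simulate_networks(traits, config)
    return SyntheticDataset(config, phylo, series, traits, networks, pol_table)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
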