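"""Meta-network pooling, specialisation d', exposures, and the d' models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nectarevo.networks import (
    GUILDS,
    InteractionNetwork,
    MetaNetwork,
    NetworkError,
    build_meta_network,
    d_prime,
    integer_d_bounds,
    kl_specialisation,
    read_edge_lists,
    specialisation_models,
    weighted_sucrose_exposure,
    write_edge_lists,
)
from nectarevo.synthetic_data import SimulationConfig, simulate_dataset


def net(site, rnd, rows, plants, pols, guild="solitary_bee"):
    counts = pd.DataFrame(np.asarray(rows, dtype=float), index=plants, columns=pols)
    return InteractionNetwork(site, rnd, counts, {p: guild for p in pols})


class TestBuildMetaNetwork:
    def test_single_network_identity(self):
        n1 = net("s", "r", [[3, 1], [0, 2]], ["P1", "P2"], ["a", "b"])
        meta = build_meta_network([n1])
        assert np.allclose(meta.matrix.to_numpy(), [[3, 1], [0, 2]])

    def test_two_network_worked_arithmetic(self):
        """N1=10 with a=5, N2=30 with a=0: pooled 0.25, rescaled 10."""
        n1 = net("s1", "r", [[5, 5]], ["P1"], ["a", "b"])
        n2 = net("s2", "r", [[0, 30]], ["P1"], ["a", "b"])
        meta = build_meta_network([n1, n2])
        assert meta.n_total == pytest.approx(40.0)
        assert meta.matrix.loc["P1", "a"] == pytest.approx(10.0)

    def test_total_conserved_for_any_inputs(self, rng):
        nets = []
        for k in range(6):
            m = rng.integers(0, 5, size=(4, 3)).astype(float)
            m[0, 0] += 1  # ensure non-empty
            nets.append(net(f"s{k}", "r", m, list("WXYZ"), list("abc")))
        meta = build_meta_network(nets)
        assert meta.matrix.to_numpy().sum() == pytest.approx(meta.n_total, abs=1e-9)

    def test_correction_factor_scales_total(self):
        n1 = net("s", "r", [[4]], ["P1"], ["a"])
        meta = build_meta_network([n1], correction_factor=0.5)
        assert meta.matrix.to_numpy().sum() == pytest.approx(2.0)

    def test_empty_network_excluded_with_warning(self):
        n1 = net("s1", "r", [[2]], ["P1"], ["a"])
        n0 = net("s2", "r", [[0]], ["P1"], ["a"])
        with pytest.warns(UserWarning, match="no interactions"):
            meta = build_meta_network([n1, n0])
        assert meta.n_total == pytest.approx(2.0)

    def test_duplicate_site_round_rejected(self):
        n1 = net("s", "r", [[1]], ["P1"], ["a"])
        n2 = net("s", "r", [[2]], ["P1"], ["a"])
        with pytest.raises(NetworkError, match="duplicate"):
            build_meta_network([n1, n2])


class TestDPrime:
    def test_use_proportional_to_availability_gives_zero(self):
        # every plant uses pollinators in proportion to their overall share
        m = MetaNetwork(pd.DataFrame([[6.0, 2.0], [3.0, 1.0]],
                                     index=["P1", "P2"], columns=["a", "b"]),
                        12.0, 1.0, {})
        for r in d_prime(m, side="plants", integer_bounds="never"):
            assert r.d == pytest.approx(0.0, abs=1e-12)
            assert r.d_prime == pytest.approx(0.0, abs=1e-9)

    def test_full_concentration_on_scarcest_partner(self):
        m = MetaNetwork(pd.DataFrame([[2.0, 0.0], [0.0, 2.0]],
                                     index=["P1", "P2"], columns=["a", "b"]),
                        4.0, 1.0, {})
        res = d_prime(m, side="plants")
        for r in res:
            assert r.d == pytest.approx(np.log(2))
            assert r.d_max == pytest.approx(np.log(2))
            assert r.d_prime == pytest.approx(1.0)

    def test_worked_integer_bounds_case(self):
        """Row total 3 against availabilities (0.75, 0.25)."""
        d_min, d_max = integer_d_bounds(3, np.array([0.75, 0.25]))
        assert d_max == pytest.approx(np.log(4.0))
        # allocation (2,1): (2/3)ln(8/9) + (1/3)ln(4/3)
        expected = (2 / 3) * np.log((2 / 3) / 0.75) + (1 / 3) * np.log((1 / 3) / 0.25)
        assert d_min == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0174, abs=5e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_bounds_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.integers(0, 5, size=(3, 3)).astype(float)
        A += np.eye(3)  # keep margins positive
        q = A.sum(axis=0) / A.sum()
        for i in range(3):
            total = int(A[i].sum())
            if total == 0:
                continue
            g_min, g_max = integer_d_bounds(total, q)
            best_lo, best_hi = np.inf, -np.inf
            for c in itertools.product(range(total + 1), repeat=3):
                if sum(c) != total:
                    continue
                p = np.array(c) / total
                mask = p > 0
                d = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
                best_lo, best_hi = min(best_lo, d), max(best_hi, d)
            assert g_min == pytest.approx(best_lo, abs=1e-12)
            assert g_max == pytest.approx(best_hi, abs=1e-12)

    def test_zero_total_species_omitted_with_warning(self):
        m = MetaNetwork(pd.DataFrame([[1.0, 1.0], [0.0, 0.0]],
                                     index=["P1", "P2"], columns=["a", "b"]),
                        2.0, 1.0, {})
        with pytest.warns(UserWarning, match="omitted"):
            res = d_prime(m, side="plants")
        assert [r.species for r in res] == ["P1"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10**6))
    def test_d_prime_in_unit_interval(self, n_plants, n_pols, seed):
        rng = np.random.default_rng(seed)
        A = rng.integers(0, 6, size=(n_plants, n_pols)).astype(float)
        if A.sum() == 0:
            A[0, 0] = 1.0
        m = MetaNetwork(pd.DataFrame(A), float(A.sum()), 1.0, {})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for side in ("plants", "pollinators"):
                for r in d_prime(m, side=side):
                    assert -1e-12 <= r.d_prime <= 1.0 + 1e-12
                    assert r.d_min - 1e-9 <= r.d <= r.d_max + 1e-9

    def test_moving_use_toward_scarce_partner_never_decreases_d(self):
        q = np.array([0.6, 0.3, 0.1])
        use = np.array([6.0, 3.0, 1.0])
        prev = kl_specialisation(use, q)
        for _ in range(5):
            use[0] -= 1.0
            use[2] += 1.0
            cur = kl_specialisation(use, q)
            assert cur >= prev - 1e-12
            prev = cur


class TestExposures:
    @pytest.fixture
    def traits(self):
        return pd.DataFrame(
            {
                "sucrose_proportion": [0.8, 0.4],
                "tube_length_mm": [5.0, 2.0],
                "symmetry": ["zygomorphic", "actinomorphic"],
            },
            index=["P1", "P2"],
        )

    def test_weighted_mean_arithmetic(self, traits):
        m = MetaNetwork(pd.DataFrame([[3.0], [1.0]], index=["P1", "P2"],
                                     columns=["a"]), 4.0, 1.0, {})
        e = weighted_sucrose_exposure(m, traits)
        assert e.loc["a", "sucrose_exposure"] == pytest.approx(0.7)
        assert e.loc["a", "tube_length_exposure"] == pytest.approx(4.25)
        assert e.loc["a", "zygomorphy_share"] == pytest.approx(0.75)

    def test_single_plant_degenerate_weights(self, traits):
        m = MetaNetwork(pd.DataFrame([[2.0], [0.0]], index=["P1", "P2"],
                                     columns=["a"]), 2.0, 1.0, {})
        e = weighted_sucrose_exposure(m, traits)
        assert e.loc["a", "sucrose_exposure"] == pytest.approx(0.8)

    def test_constant_sucrose_gives_constant_exposure(self, traits):
        traits = traits.assign(sucrose_proportion=0.5)
        m = MetaNetwork(pd.DataFrame([[3.0, 1.0], [1.0, 5.0]],
                                     index=["P1", "P2"], columns=["a", "b"]),
                        10.0, 1.0, {})
        e = weighted_sucrose_exposure(m, traits)
        assert np.allclose(e["sucrose_exposure"], 0.5)

    def test_missing_trait_reported(self, traits):
        m = MetaNetwork(pd.DataFrame([[1.0], [1.0], [1.0]],
                                     index=["P1", "P2", "P3"], columns=["a"]),
                        3.0, 1.0, {})
        with pytest.raises(NetworkError, match="P3"):
            weighted_sucrose_exposure(m, traits)


class TestGuildRestriction:
    def test_restrict_guild_keeps_only_that_guild(self, small_dataset):
        meta = build_meta_network(small_dataset.networks)
        sub = meta.restrict_guild("solitary_bee")
        assert all(meta.guilds[c] == "solitary_bee" for c in sub.matrix.columns)
        assert sub.n_total == pytest.approx(sub.matrix.to_numpy().sum())

    def test_all_guilds_partition_the_pollinators(self, small_dataset):
        meta = build_meta_network(small_dataset.networks)
        counts = sum(len(meta.restrict_guild(g).matrix.columns) for g in GUILDS)
        assert counts == len(meta.matrix.columns)


class TestSpecialisationModels:
    def _pipeline(self, seed, gamma):
        ds = simulate_dataset(SimulationConfig(
            seed=seed, gamma=gamma, n_species=80, n_pollinators=60,
            n_network_plants=80, n_sites=6))
        meta = build_meta_network(ds.networks)
        dres = d_prime(meta, "pollinators")
        exposures = weighted_sucrose_exposure(meta, ds.traits)
        return ds, dres, exposures

    def test_positive_coupling_detected_in_most_sims(self):
        hits, reps = 0, 10
        for seed in range(reps):
            ds, dres, exposures = self._pipeline(seed, gamma=1.0)
            m = specialisation_models(dres, exposures, ds.pollinators, "all")
            hits += m.sucrose_slope > 0
        assert hits >= 8

    def test_constant_exposure_drops_sucrose_term(self, small_dataset):
        meta = build_meta_network(small_dataset.networks)
        dres = d_prime(meta, "pollinators")
        exposures = weighted_sucrose_exposure(meta, small_dataset.traits)
        exposures["sucrose_exposure"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            m = specialisation_models(dres, exposures,
                                      small_dataset.pollinators, "all")
        assert "sucrose_exposure" not in m.selected_predictors
        assert np.isnan(m.sucrose_slope)

    def test_plants_subset_uses_own_traits(self, small_dataset):
        meta = build_meta_network(small_dataset.networks)
        dres = d_prime(meta, "plants")
        plant_tax = pd.DataFrame(
            {"taxon_family": [s[:4] for s in small_dataset.traits.index],
             "genus": [s[:5] for s in small_dataset.traits.index]},
            index=small_dataset.traits.index)
        m = specialisation_models(dres, None, plant_tax, "plants",
                                  plant_traits=small_dataset.traits)
        assert m.guild_subset == "plants"
        assert m.n > 0

    def test_bumble_bee_rule_has_no_random_effect(self):
        ds = simulate_dataset(SimulationConfig(
            seed=17, n_species=60, n_pollinators=80, n_network_plants=40,
            n_sites=4))
        meta = build_meta_network(ds.networks).restrict_guild("bumble_bee")
        assert meta.matrix.shape[1] >= 4
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dres = d_prime(meta, "pollinators")
            exposures = weighted_sucrose_exposure(meta, ds.traits)
            m = specialisation_models(dres, exposures, ds.pollinators,
                                      "bumble_bees")
        assert m.n == len(dres)

    def test_invalid_guild_subset_rejected(self, small_dataset):
        with pytest.raises(NetworkError, match="guild_subset"):
            specialisation_models([], None, small_dataset.pollinators, "wasps")


class TestEdgeListIO:
    def test_round_trip(self, tmp_path, small_dataset):
        p = tmp_path / "nets.csv"
        write_edge_lists(small_dataset.networks, p)
        back = read_edge_lists(p)
        assert len(back) == len(small_dataset.networks)
        orig_total = sum(n.total for n in small_dataset.networks)
        assert sum(n.total for n in back) == pytest.approx(orig_total)
        m0 = build_meta_network(small_dataset.networks)
        m1 = build_meta_network(back)
        assert np.allclose(
            m0.matrix.loc[m1.matrix.index, m1.matrix.columns].to_numpy(),
            m1.matrix.to_numpy())
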