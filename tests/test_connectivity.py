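"""Habitat-weighted indices: kernel, max-product paths, ECA, GBC, dECA/dA."""

import math

import numpy as np
import pytest

from reservenet import (
    ConnectivityIndices,
    DistanceMatrix,
    ProbabilityKernel,
    connectivity_indices,
    d_metrics,
    eca,
    gbc,
    max_product_paths,
    pairwise_distances,
)

from .conftest import make_sites, random_sites
from .oracles import brute_gbc, brute_max_product


class TestKernel:
    def test_half_distance_anchor(self):
        k = ProbabilityKernel(44.0)
        assert k.probability(0.0) == pytest.approx(1.0)
        assert k.probability(44.0) == pytest.approx(0.5)
        assert k.probability(88.0) == pytest.approx(0.25)

    def test_strictly_decreasing(self):
        k = ProbabilityKernel(90.0)
        d = np.linspace(0, 500, 100)
        p = k.probability(d)
        assert np.all(np.diff(p) < 0)

    def test_invalid_half_distance(self):
        with pytest.raises(ValueError):
            ProbabilityKernel(0.0)


class TestMaxProductPaths:
    def test_two_sites_direct_probability(self):
        sites = make_sites([(0, 0), (44, 0)])
        dm = pairwise_distances(sites)
        p = max_product_paths(dm, ProbabilityKernel(44.0))
        assert p[0, 1] == pytest.approx(0.5)
        assert p[0, 0] == 1.0

    def test_stepping_stone_beats_weak_direct_link(self):
        # synthetic (non-Euclidean) distances: direct p=0.4, two-step 0.7*0.7
        k = ProbabilityKernel(1.0)
        decay = k.decay_per_km
        d_ab = -math.log(0.7) / decay
        d_ac = -math.log(0.4) / decay
        d = np.array([[0, d_ab, d_ac], [d_ab, 0, d_ab], [d_ac, d_ab, 0]])
        dm = DistanceMatrix(ids=("A", "B", "C"), d=d)
        p = max_product_paths(dm, k)
        assert p[0, 2] == pytest.approx(0.49)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_path_enumeration(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(3, 9))
        sites = random_sites(rng, n, box_km=150.0)
        dm = pairwise_distances(sites)
        kernel = ProbabilityKernel(float(rng.uniform(20, 120)))
        p = max_product_paths(dm, kernel)
        expected = brute_max_product(dm.d.tolist(), kernel.decay_per_km)
        assert p == pytest.approx(np.array(expected), rel=1e-9)

    def test_symmetric_and_at_least_direct(self, rng):
        sites = random_sites(rng, 15)
        dm = pairwise_distances(sites)
        k = ProbabilityKernel(30.0)
        p = max_product_paths(dm, k)
        assert p == pytest.approx(p.T)
        assert np.all(p >= np.asarray(k.probability(dm.d)) - 1e-12)


class TestECA:
    def test_single_patch_identity(self):
        sites = make_sites([(0, 0)], areas=[100.0])
        idx = connectivity_indices(sites, ProbabilityKernel(44.0))
        assert idx.eca_ha == pytest.approx(100.0, abs=1e-9)

    def test_isolated_patches_lower_bound(self):
        sites = make_sites([(0, 0), (10, 0)], areas=[100.0, 100.0])
        p_star = np.eye(2)  # no exchange at all
        idx = eca(sites, p_star, ("s0", "s1"))
        assert idx.eca_ha == pytest.approx(math.sqrt(2 * 100.0**2), abs=1e-9)

    def test_full_connectivity_upper_bound(self):
        sites = make_sites([(0, 0), (10, 0)], areas=[100.0, 100.0])
        idx = eca(sites, np.ones((2, 2)), ("s0", "s1"))
        assert idx.eca_ha == pytest.approx(200.0, abs=1e-9)

    def test_bounds_hold_on_random_networks(self, rng):
        for _ in range(20):
            sites = random_sites(rng, 12)
            idx = connectivity_indices(sites, ProbabilityKernel(40.0), with_gbc=False)
            areas = np.array([s.area_ha for s in sites])
            assert math.sqrt((areas**2).sum()) - 1e-9 <= idx.eca_ha <= areas.sum() + 1e-9

    def test_empty_site_list(self):
        idx = connectivity_indices([], ProbabilityKernel(44.0))
        assert idx.eca_ha == 0.0

    def test_site_removal_never_increases_pc_numerator(self, rng):
        sites = random_sites(rng, 10)
        k = ProbabilityKernel(50.0)
        full = connectivity_indices(sites, k, with_gbc=False)
        for drop in range(len(sites)):
            reduced = connectivity_indices(sites[:drop] + sites[drop + 1:], k, with_gbc=False)
            assert reduced.pc_numerator_ha2 <= full.pc_numerator_ha2 + 1e-9

    def test_kernel_growth_never_decreases_eca(self, rng):
        sites = random_sites(rng, 10)
        ecas = [
            connectivity_indices(sites, ProbabilityKernel(h), with_gbc=False).eca_ha
            for h in (10.0, 30.0, 90.0, 270.0)
        ]
        assert ecas == sorted(ecas)


class TestGBC:
    def test_isolated_node_zero(self):
        # far-flung sites: no optimal path crosses anyone
        sites = make_sites([(0, 0), (5000, 0), (10000, 0)])
        dm = pairwise_distances(sites)
        g = gbc(sites, dm, ProbabilityKernel(44.0))
        # middle site lies on the optimal end-to-end path (collinear tie)
        assert g["s0"] == 0.0
        assert g["s2"] == 0.0

    def test_collinear_tie_rule(self):
        # on a line the through-path product equals the direct probability:
        # the tie rule credits the middle site with the full pair weight
        sites = make_sites([(0, 0), (40, 0), (80, 0)], areas=[1.0, 1.0, 1.0])
        dm = pairwise_distances(sites)
        k = ProbabilityKernel(44.0)
        g = gbc(sites, dm, k)
        p_ac = float(k.probability(80.0))
        assert g["s1"] == pytest.approx(1.0 * 1.0 * p_ac)
        assert g["s0"] == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_optimal_path_oracle(self, trial):
        rng = np.random.default_rng(3000 + trial)
        n = int(rng.integers(3, 9))
        sites = random_sites(rng, n, box_km=120.0)
        dm = pairwise_distances(sites)
        kernel = ProbabilityKernel(float(rng.uniform(20, 100)))
        got = gbc(sites, dm, kernel)
        expected = brute_gbc(
            [s.area_ha for s in sites], dm.d.tolist(), kernel.decay_per_km
        )
        assert [got[sid] for sid in dm.ids] == pytest.approx(expected, rel=1e-7, abs=1e-7)


class TestDMetrics:
    def _idx(self, eca_val, area):
        return ConnectivityIndices(eca_val**2, eca_val, area, {})

    def test_relative_change_worked_row(self):
        # ECA 6348903 -> 5592091 ha; area 13381774 -> 11631070 ha
        change = d_metrics(
            self._idx(6348903.0, 13381774.0), self._idx(5592091.0, 11631070.0)
        )
        assert change["dECA_pct"] == pytest.approx(-11.92, abs=0.005)
        assert change["dA_pct"] == pytest.approx(-13.08, abs=0.005)
        assert change["weaker_impact"] is True

    def test_connectivity_gain_despite_area_loss(self):
        change = d_metrics(
            self._idx(8234347.0, 25678502.0), self._idx(8282544.0, 24968535.0)
        )
        assert change["dECA_pct"] == pytest.approx(0.59, abs=0.005)
        assert change["dA_pct"] < 0
        assert change["weaker_impact"] is True

    def test_identical_indices_no_change(self):
        idx = self._idx(1000.0, 2000.0)
        change = d_metrics(idx, idx)
        assert change["dA_pct"] == 0.0
        assert change["dECA_pct"] == 0.0
        assert change["weaker_impact"] is False

    def test_zero_current_area_errors(self):
        with pytest.raises(ValueError):
            d_metrics(self._idx(0.0, 0.0), self._idx(10.0, 10.0))
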