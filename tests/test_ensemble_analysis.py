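"""Ensemble statistics against brute-force oracles and closed-form cases."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dimes
from dimes import ensemble_analysis as ea
from dimes import fixtures
from dimes.exceptions import ValidationError


# ---------------------------------------------------------------------------
# brute-force oracles (independent loop implementations)
# ---------------------------------------------------------------------------

def brute_pi(coords, a):
    m, n, _ = coords.shape
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                cnt = 0
                for c in range(m):
                    dij = np.linalg.norm(coords[c, i] - coords[c, j])
                    dik = np.linalg.norm(coords[c, i] - coords[c, k])
                    djk = np.linalg.norm(coords[c, j] - coords[c, k])
                    if dij < a and dik < a and djk < a:
                        cnt += 1
                out[(i, j, k)] = cnt / m
    return out


def brute_z(pis):
    keys = {}
    for (i, j, k), v in pis.items():
        keys.setdefault((j - i) * (k - j), []).append(((i, j, k), v))
    out = {}
    for _, members in keys.items():
        vals = np.array([v for _, v in members])
        sd = vals.std()
        for (trip, v) in members:
            out[trip] = 0.0 if sd == 0 else (v - vals.mean()) / sd
    return out


def brute_qk(coords, labels, k):
    m, n, _ = coords.shape
    n_a = sum(1 for l in labels if l == "A")
    n_b = sum(1 for l in labels if l == "B")
    na_t, nb_t = k * n_a / n, k * n_b / n
    out = []
    for c in range(m):
        tot = 0.0
        for i in range(n):
            d = [(np.linalg.norm(coords[c, i] - coords[c, j]), j) for j in range(n) if j != i]
            d.sort()  # ties resolved by the lower index (second sort key)
            nn = [j for _, j in d[:k]]
            ca = sum(1 for j in nn if labels[j] == "A")
            cb = sum(1 for j in nn if labels[j] == "B")
            tot += abs(ca / na_t - cb / nb_t)
        out.append(tot / n)
    return np.array(out)


def brute_fk(coords, k):
    m, n, _ = coords.shape
    f0 = 0.5 * (1 + k / 2)
    out = []
    for c in range(m):
        tot = 0
        for i in range(n):
            d = [(np.linalg.norm(coords[c, i] - coords[c, j]), j) for j in range(n) if j != i]
            d.sort()
            tot += sum(abs(j - i) for _, j in d[:k])
        out.append(tot / (k * n * f0))
    return np.array(out)


@pytest.fixture(scope="module")
def tiny_ensemble():
    rng = np.random.default_rng(7)
    coords = rng.normal(0, 1.0, size=(8, 6, 3))
    return dimes.ConformationEnsemble(coords=coords, source="experimental")


def straight_line(n):
    coords = np.zeros((1, n, 3))
    coords[0, :, 0] = np.arange(n, dtype=float)
    return coords


# ---------------------------------------------------------------------------
# distributions and JSD
# ---------------------------------------------------------------------------

class TestDistributionsAndJSD:
    def test_constant_distance_is_single_bin(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 1.0
        h = dimes.distance_distributions(coords)
        assert len(h.probabilities) == 1
        assert h.probabilities[0].sum() == pytest.approx(1.0)
        assert h.probabilities[0].max() == pytest.approx(1.0)

    def test_identical_histograms_zero_jsd(self, tiny_ensemble):
        J = dimes.ensemble_jsd(tiny_ensemble, tiny_ensemble)
        iu = np.triu_indices(6, 1)
        assert np.nanmax(J[iu]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_gives_unit_jsd(self):
        p = np.array([1.0, 0.0, 0.0])
        q = np.array([0.0, 0.0, 1.0])
        assert ea.jsd(p, q) == pytest.approx(1.0)

    def test_mismatched_bins_rejected(self, tiny_ensemble):
        h1 = dimes.distance_distributions(tiny_ensemble, bins=5)
        h2 = dimes.distance_distributions(tiny_ensemble, bins=7)
        with pytest.raises(ValidationError):
            dimes.jsd_matrix(h1, h2)

    def test_dumbbell_matches_gaussian_separation_law(self, dumbbell_half):
        """P(r) for a Gaussian pair follows the 3D Maxwell-type density."""
        ens = dimes.sample_conformations(dumbbell_half, 40_000, seed=2)
        r = np.linalg.norm(ens.coords[:, 0] - ens.coords[:, 1], axis=1)
        edges = np.linspace(0, r.max(), 60)
        hist, _ = np.histogram(r, bins=edges, density=True)
        mid = 0.5 * (edges[1:] + edges[:-1])
        s2 = 2.0  # per-axis separation variance: ⟨r²⟩/3
        density = (mid**2 / (2 * np.pi * s2) ** 1.5) * 4 * np.pi * np.exp(-(mid**2) / (2 * s2))
        assert np.abs(hist - density).max() < 0.05 * density.max()


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

class TestTriplets:
    def test_matches_brute_force(self, tiny_ensemble):
        a = 2.0
        stats = dimes.triplet_colocalization(tiny_ensemble, a)
        oracle = brute_pi(tiny_ensemble.coords, a)
        for trip, pi in zip(map(tuple, stats.triplets), stats.pi):
            assert pi == pytest.approx(oracle[trip])

    def test_threshold_extremes(self, tiny_ensemble):
        assert np.all(dimes.triplet_colocalization(tiny_ensemble, 1e9).pi == 1.0)
        assert np.all(dimes.triplet_colocalization(tiny_ensemble, 0.0).pi == 0.0)

    def test_monotone_in_threshold(self, tiny_ensemble):
        lo = dimes.triplet_colocalization(tiny_ensemble, 1.0).pi
        hi = dimes.triplet_colocalization(tiny_ensemble, 2.0).pi
        assert np.all(hi >= lo)

    def test_hand_case_half(self):
        # two conformations: mutual distances 1, then 10; a = 2 → π = 0.5
        c1 = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        coords = np.stack([c1, 10 * c1])
        stats = dimes.triplet_colocalization(
            dimes.ConformationEnsemble(coords=coords, source="experimental"), 2.0
        )
        assert stats.pi[0] == pytest.approx(0.5)

    def test_zscores_match_brute_force(self, tiny_ensemble):
        stats = dimes.triplet_zscore(dimes.triplet_colocalization(tiny_ensemble, 2.0))
        oracle = brute_z(brute_pi(tiny_ensemble.coords, 2.0))
        for trip, z in zip(map(tuple, stats.triplets), stats.z):
            assert z == pytest.approx(oracle[trip])

    def test_equal_pis_give_zero_z(self):
        coords = np.zeros((2, 4, 3))
        coords[:, :, 0] = np.arange(4) * 100.0
        stats = dimes.triplet_zscore(dimes.triplet_colocalization(
            dimes.ConformationEnsemble(coords=coords, source="experimental"), 1e9))
        assert np.all(stats.pi == 1.0)
        assert np.all(stats.z == 0.0)

    def test_hand_group_of_two(self):
        """π = {0.2, 0.4} in one gap-product group → Z = {−1, +1} (population σ)."""
        stats = dimes.TripletStats(
            threshold_a=1.0,
            triplets=np.array([[0, 1, 2], [1, 2, 3]]),
            pi=np.array([0.2, 0.4]),
            grouping_key=np.array([1, 1]),
        )
        z = dimes.triplet_zscore(stats).z
        assert z == pytest.approx([-1.0, 1.0])

    def test_colocalized_subset(self):
        c1 = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        coords = np.stack([c1, 10 * c1])
        ens = dimes.ConformationEnsemble(coords=coords, source="experimental")
        kept = dimes.colocalized_subset(ens, (0, 1, 2), 2.0)
        assert kept.n_conformations == 1
        assert dimes.colocalized_subset(ens, (0, 1, 2), 1e9).n_conformations == 2
        with pytest.warns(UserWarning):
            empty = dimes.colocalized_subset(ens, (0, 1, 2), 0.0)
        assert empty.coords.shape[0] == 0


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

class TestShape:
    def test_two_loci_rg_is_half_separation(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 4.0
        s = dimes.shape_stats(coords)
        assert s.rg[0] == pytest.approx(2.0)

    def test_collinear_kappa_one(self):
        s = dimes.shape_stats(straight_line(5))
        assert s.kappa2[0] == pytest.approx(1.0)

    def test_equilateral_triangle_kappa_quarter(self):
        coords = np.array([[[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]])
        s = dimes.shape_stats(coords)
        assert s.kappa2[0] == pytest.approx(0.25)

    def test_segment_restriction(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0.0, 1.0, 2.0, 100.0]
        full = dimes.shape_stats(coords)
        seg = dimes.shape_stats(coords, segment=(0, 2))
        assert seg.rg[0] < full.rg[0]
        with pytest.raises(ValidationError):
            dimes.shape_stats(coords, segment=(3, 3))

    def test_kappa_in_unit_interval(self, tiny_ensemble):
        s = dimes.shape_stats(tiny_ensemble)
        assert np.all((s.kappa2 >= 0) & (s.kappa2 <= 1))
        assert np.all(s.rg >= 0)


# ---------------------------------------------------------------------------
# boundary probability
# ---------------------------------------------------------------------------

class TestBoundaryProbability:
    def rigid_two_blocks(self, m=40, sep=3000.0, noise=5.0, seed=0):
        """Two co-located compact blocks far apart, locus 10 midway between them.

        Within a block all loci sit at (almost) one point, so inter/intra window
        distance ratios hover near 1; only the midpoint locus separates its two
        flanking windows by ~sep and is a certain boundary.
        """
        rng = np.random.default_rng(seed)
        n = 21
        template = np.zeros((n, 3))
        template[10, 0] = sep / 2
        template[11:, 0] = sep
        coords = template[None] + rng.normal(0, noise, size=(m, n, 3))
        return coords

    def test_interface_found_with_certainty(self):
        coords = self.rigid_two_blocks()
        dm = ea.pairwise_distance_matrices(coords)
        prob = dimes.boundary_probability(dm, window=3)
        assert prob[10] == pytest.approx(1.0)
        # block interiors only see isotropic localization noise: like ideal
        # homopolymers they show weak fluctuation-driven boundaries, far below
        # the deterministic interface
        interior = np.concatenate([prob[3:10], prob[11:18]])
        assert np.all(interior < 0.35)
        assert np.all(np.isnan(prob[:3])) and np.all(np.isnan(prob[-3:]))

    def test_rigid_motion_invariance(self):
        coords = self.rigid_two_blocks(m=10)
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.4]).as_matrix()
        moved = coords @ rot.T + np.array([100.0, -50.0, 7.0])
        dm_a = ea.pairwise_distance_matrices(coords)
        dm_b = ea.pairwise_distance_matrices(moved)
        a = dimes.boundary_probability(dm_a, window=3)
        b = dimes.boundary_probability(dm_b, window=3)
        assert np.allclose(np.nan_to_num(a), np.nan_to_num(b))

    def test_homopolymer_has_flat_nonzero_profile(self):
        K = fixtures.make_rouse_chain(30, fixtures.DEFAULT_BACKBONE_K)
        ens = dimes.sample_conformations(K, 150, seed=4)
        prob = dimes.boundary_probability(ea.pairwise_distance_matrices(ens), window=5)
        interior = prob[5:-5]
        assert np.nanmean(interior) > 0.02  # fluctuation-driven domains exist
        assert np.nanmax(interior) < 0.8    # but no deterministic boundary

    def test_window_too_large_rejected(self):
        dm = ea.pairwise_distance_matrices(np.zeros((2, 8, 3)))
        with pytest.raises(ValidationError):
            dimes.boundary_probability(dm, window=4)


# ---------------------------------------------------------------------------
# conformation metric and clustering
# ---------------------------------------------------------------------------

class TestConformationMetric:
    def test_identical_conformations_zero(self):
        c = np.random.default_rng(0).normal(size=(5, 3))
        assert dimes.conformation_distance(c, c) == 0.0

    def test_two_locus_hand_value(self):
        a = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        b = np.array([[0, 0, 0], [3, 0, 0]], dtype=float)
        # ordered pairs: (0,1) and (1,0) each contribute (1−3)² → √((1/4)·8) = √2
        assert dimes.conformation_distance(a, b) == pytest.approx(np.sqrt(2.0))

    def test_symmetry_and_matrix_agreement(self, tiny_ensemble):
        D = dimes.conformation_distance_matrix(tiny_ensemble)
        assert np.allclose(D, D.T)
        d01 = dimes.conformation_distance(tiny_ensemble.coords[0], tiny_ensemble.coords[1])
        assert D[0, 1] == pytest.approx(d01)


class TestClustering:
    def make_two_populations(self):
        kb = fixtures.DEFAULT_BACKBONE_K
        n = 20
        compact = fixtures.make_rouse_chain(n, kb).offdiag.copy()
        iu = np.triu_indices(n, 1)
        compact[iu] += 0.3 * kb
        compact = np.triu(compact, 1) + np.triu(compact, 1).T
        dumbbell = fixtures.make_rouse_chain(n, kb).offdiag.copy()
        for blk in (range(0, 10), range(10, 20)):
            for i in blk:
                for j in blk:
                    if abs(i - j) > 1:
                        dumbbell[i, j] = 0.5 * kb
        e1 = dimes.sample_conformations(dimes.assemble_connectivity(compact), 120, seed=1)
        e2 = dimes.sample_conformations(dimes.assemble_connectivity(dumbbell), 80, seed=2)
        coords = np.concatenate([e1.coords, e2.coords])
        return dimes.ConformationEnsemble(coords=coords), np.array([0] * 120 + [1] * 80)

    def test_planted_fractions_recovered(self):
        ens, truth = self.make_two_populations()
        res = dimes.cluster_ensemble(ens, n_clusters=2, seed=0)
        assert res.fractions.sum() == pytest.approx(1.0)
        assert min(abs(res.fractions[0] - 0.6), abs(res.fractions[0] - 0.4)) <= 0.05

    def test_representative_belongs_to_its_cluster(self):
        ens, _ = self.make_two_populations()
        res = dimes.cluster_ensemble(ens, n_clusters=2, seed=0)
        for c, rep in enumerate(res.representatives):
            assert res.labels[rep] == c
        assert len(res.mean_distance_maps) == 2
        assert res.mean_distance_maps[0].shape == (20, 20)


# ---------------------------------------------------------------------------
# Q_k and F_k
# ---------------------------------------------------------------------------

class TestMixingAndLongRange:
    def test_qk_matches_brute_force(self, tiny_ensemble):
        labels = np.array(["A", "B", "A", "B", "B", "A"], dtype=object)
        got = dimes.mixing_metric(tiny_ensemble, labels, k=2)
        want = brute_qk(tiny_ensemble.coords, labels, 2)
        assert np.allclose(got, want)

    def test_fk_matches_brute_force(self, tiny_ensemble):
        got = dimes.longrange_metric(tiny_ensemble, k=3)
        want = brute_fk(tiny_ensemble.coords, 3)
        assert np.allclose(got, want)

    def test_perfectly_mixed_chain_zero(self):
        """AABB-periodic line: every locus's 2 nearest neighbors are one A, one B."""
        labels = np.array(["A", "A", "B", "B"] * 5, dtype=object)
        q = dimes.mixing_metric(
            dimes.ConformationEnsemble(coords=straight_line(20), source="experimental"),
            labels, k=2,
        )
        assert q[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_demixed_blocks_two(self):
        # two well-separated spatial clusters: every locus's k neighbors share its type
        coords = np.zeros((1, 20, 3))
        coords[0, :10, 0] = np.arange(10) * 1.0
        coords[0, 10:, 0] = 1000.0 + np.arange(10) * 1.0
        labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        q = dimes.mixing_metric(
            dimes.ConformationEnsemble(coords=coords, source="experimental"), labels, k=2
        )
        assert q[0] == pytest.approx(2.0)

    def test_rotation_invariance(self, tiny_ensemble):
        labels = np.array(["A", "B", "A", "B", "B", "A"], dtype=object)
        rot = Rotation.from_euler("zyx", [0.5, -0.2, 1.4]).as_matrix()
        moved = dimes.ConformationEnsemble(
            coords=tiny_ensemble.coords @ rot.T + 5.0, source="experimental"
        )
        assert np.allclose(
            dimes.mixing_metric(tiny_ensemble, labels, 2),
            dimes.mixing_metric(moved, labels, 2),
        )
        assert np.allclose(
            dimes.longrange_metric(tiny_ensemble, 2), dimes.longrange_metric(moved, 2)
        )

    def test_single_class_rejected(self, tiny_ensemble):
        labels = np.array(["A"] * 6, dtype=object)
        with pytest.raises(ValidationError):
            dimes.mixing_metric(tiny_ensemble, labels, 2)

    def test_straight_chain_fk_is_one(self):
        f = dimes.longrange_metric(
            dimes.ConformationEnsemble(coords=straight_line(100), source="experimental"), k=2
        )
        # interior loci contribute exactly 1; chain ends deflate it slightly
        assert f[0] == pytest.approx(1.0, abs=0.02)

    def test_hairpin_exceeds_one(self):
        n = 40
        coords = np.zeros((1, n, 3))
        coords[0, :20, 0] = np.arange(20)
        coords[0, 20:, 0] = np.arange(19, -1, -1)
        coords[0, 20:, 1] = 0.4  # folded back alongside the first arm
        f = dimes.longrange_metric(dimes.ConformationEnsemble(coords=coords, source="experimental"), k=2)
        assert f[0] > 1.0
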