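"""The five restraint-selection methods and their supporting statistics."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

import fretrest as fr
from fretrest.selection import (
    CandidatePool,
    NoDiscriminantError,
    ResiduePair,
    build_candidate_pool,
    chi_squared_deviation,
    ensemble_weighted_rmsd,
    fit_lda,
    pair_probability,
    select_largest_delta,
    select_largest_separation,
    select_lda,
    select_nma,
    select_random,
)
from fretrest.structures import Ensemble, ca_rmsd

from conftest import toy_structure


def manual_pool(s, pairs):
    """CandidatePool restricted to hand-picked pairs (for engineered tests)."""
    import pandas as pd

    idx = np.array([[s.index_of(p.beta), s.index_of(p.delta)] for p in pairs])
    return CandidatePool(
        pairs=list(pairs),
        indices=idx,
        structure=s,
        provenance=pd.DataFrame(),
        n_total_pairs=s.n_residues * (s.n_residues - 1) // 2,
    )


class TestCandidatePool:
    def test_all_buried_gives_empty_pool(self):
        s = toy_structure(np.random.default_rng(0).normal(0, 10, (8, 3)), rsasa=[0.0] * 8)
        assert len(build_candidate_pool(s)) == 0

    def test_two_residue_toy(self):
        s = toy_structure([[0, 0, 0], [3, 0, 0]], rsasa=[1.0, 1.0])
        pool = build_candidate_pool(s)  # Rg = 1.5 < separation 3
        assert len(pool) == 1
        assert pool.pairs[0] == ResiduePair(("A", 1), ("A", 2))

    def test_filters_audited_in_pool(self, hinge_pair):
        s0 = hinge_pair[0]
        spec = fr.HingeSpec(seed=0, rsasa_annotation=("core-buried", 0.3))
        s_buried, _ = fr.make_hinge_pair(spec)
        pool = build_candidate_pool(s_buried)
        rg = fr.radius_of_gyration(s_buried)
        assert len(pool) > 0
        assert (pool.provenance["separation_A"] >= rg).all()
        assert (pool.provenance[["rsasa_beta", "rsasa_delta"]] >= 0.1).all().all()
        # burial shrinks the pool relative to the all-exposed fixture
        assert len(pool) < len(build_candidate_pool(s0))


class TestRandomSelection:
    def test_full_pool_draw(self, hinge_pool):
        sets = select_random(hinge_pool, nr=len(hinge_pool), n_sets=2, seed=1)
        for chosen in sets:
            assert sorted(chosen) == sorted(hinge_pool.pairs)

    def test_deterministic_given_seed(self, hinge_pool):
        a = select_random(hinge_pool, 5, n_sets=10, seed=3)
        b = select_random(hinge_pool, 5, n_sets=10, seed=3)
        c = select_random(hinge_pool, 5, n_sets=10, seed=4)
        assert a == b
        assert a != c

    def test_uniform_inclusion_frequency(self):
        s = toy_structure(np.random.default_rng(2).normal(0, 20, (20, 3)), rsasa=[1.0] * 20)
        pairs = [ResiduePair(("A", 2 * i + 1), ("A", 2 * i + 2)) for i in range(10)]
        pool = manual_pool(s, pairs)
        draws = select_random(pool, 1, n_sets=10_000, seed=0)
        counts = {p: 0 for p in pairs}
        for d in draws:
            counts[d[0]] += 1
        sigma = np.sqrt(0.1 * 0.9 / 10_000)
        for p in pairs:
            assert abs(counts[p] / 10_000 - 0.1) < 3 * sigma + 1e-9

    def test_oversized_request_raises(self, hinge_pool):
        with pytest.raises(ValueError):
            select_random(hinge_pool, len(hinge_pool) + 1, seed=0)


class TestChiSquared:
    def test_identical_structures_zero(self, hinge_pair):
        s = hinge_pair[0]
        pairs = [ResiduePair(("A", 1), ("A", 50))]
        assert chi_squared_deviation(s, s, pairs) == 0.0

    def test_hand_value_fractional(self):
        si = toy_structure([[0, 0, 0], [3, 0, 0]])
        sj = toy_structure([[0, 0, 0], [5, 0, 0]])
        pairs = [ResiduePair(("A", 1), ("A", 2))]
        # (dR / mean)^2 = (2 / 4)^2
        assert chi_squared_deviation(si, sj, pairs) == pytest.approx(0.25)
        # alternative reading: dR^2 / (Ri + Rj)^2, a factor 4 smaller
        assert chi_squared_deviation(si, sj, pairs, convention="sum") == pytest.approx(0.0625)

    def test_additive_over_pairs(self, hinge_pair):
        s0, s1 = hinge_pair
        p1 = ResiduePair(("A", 1), ("A", 60))
        p2 = ResiduePair(("A", 10), ("A", 70))
        assert chi_squared_deviation(s0, s1, [p1, p2]) == pytest.approx(
            chi_squared_deviation(s0, s1, [p1]) + chi_squared_deviation(s0, s1, [p2])
        )


class TestPairProbability:
    def test_zero_deviation_certain(self):
        assert pair_probability(0.0, 3) == pytest.approx(1.0)

    def test_two_dof_closed_form(self):
        # chi-squared upper tail with 2 dof is exp(-x/2)
        assert pair_probability(2.0, 2) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_strictly_decreasing(self):
        vals = [pair_probability(x, 4) for x in np.linspace(0, 10, 25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestEnsembleWeightedRmsd:
    def test_identical_members_zero(self, hinge_pair):
        s = hinge_pair[0]
        ens = Ensemble([s.with_coords(s.ca_coords) for _ in range(3)])
        pairs = [ResiduePair(("A", 1), ("A", 40))]
        assert ensemble_weighted_rmsd(ens, pairs) == pytest.approx(0.0, abs=1e-12)

    def test_two_member_hand_formula(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 6, (5, 3))
        a = toy_structure(base, identifier="a")
        b = toy_structure(base + rng.normal(0, 1.0, base.shape), identifier="b")
        ens = Ensemble([a, b])
        pairs = [ResiduePair(("A", 1), ("A", 4))]
        chi2 = chi_squared_deviation(a, b, pairs)
        P = chi2_dist.sf(chi2, df=1)
        R = ca_rmsd(a, b, align=True)
        # <RMSD> = mean_i sum_j P_ij R_ij / sum_j P_ij with self terms P=1, R=0
        expected = (P * R) / (1 + P)
        assert ensemble_weighted_rmsd(ens, pairs) == pytest.approx(expected, rel=1e-10)

    def test_bounded_by_max_pairwise(self, hinge_pair):
        s = hinge_pair[0]
        ens = fr.make_bundle(s, 4, noise_scale=1.0, seed=2)
        pairs = [ResiduePair(("A", 3), ("A", 55))]
        val = ensemble_weighted_rmsd(ens, pairs)
        mx = max(
            ca_rmsd(ens[i], ens[j]) for i in range(4) for j in range(4) if i != j
        )
        assert 0 <= val <= mx


@pytest.fixture(scope="module")
def toy_ensemble_and_pool():
    rng = np.random.default_rng(11)
    base = rng.normal(0, 5, (6, 3))
    members = [
        toy_structure(base + rng.normal(0, 1.2, base.shape), identifier=f"m{i}")
        for i in range(5)
    ]
    ens = Ensemble(members)
    pairs = [
        ResiduePair(("A", i + 1), ("A", j + 1))
        for i in range(6)
        for j in range(i + 1, 6)
    ]
    return ens, manual_pool(members[0], pairs)


class TestGreedyNmaSelection:
    def test_empty_request(self, toy_ensemble_and_pool):
        ens, pool = toy_ensemble_and_pool
        res = select_nma(ens, pool, 0)
        assert res.ordered_pairs == []

    def test_matches_exhaustive_greedy(self, toy_ensemble_and_pool):
        """Greedy steps 1 and 2 equal brute-force minimisation of the
        weighted ensemble RMSD over every candidate."""
        ens, pool = toy_ensemble_and_pool
        res = select_nma(ens, pool, 2, subsample=10, seed=0)

        scores1 = [ensemble_weighted_rmsd(ens, [p]) for p in pool.pairs]
        best1 = pool.pairs[int(np.argmin(scores1))]
        assert res.ordered_pairs[0] == best1
        assert res.scores[0] == pytest.approx(min(scores1), rel=1e-10)

        scores2 = [
            ensemble_weighted_rmsd(ens, [best1, p])
            for p in pool.pairs
            if p != best1
        ]
        candidates2 = [p for p in pool.pairs if p != best1]
        best2 = candidates2[int(np.argmin(scores2))]
        assert res.ordered_pairs[1] == best2
        assert res.scores[1] == pytest.approx(min(scores2), rel=1e-10)

    def test_nested_and_deterministic(self, toy_ensemble_and_pool):
        ens, pool = toy_ensemble_and_pool
        a = select_nma(ens, pool, 3, subsample=10, seed=5)
        b = select_nma(ens, pool, 3, subsample=10, seed=5)
        assert a.ordered_pairs == b.ordered_pairs
        shorter = select_nma(ens, pool, 2, subsample=10, seed=5)
        assert a.ordered_pairs[:2] == shorter.ordered_pairs  # nested-set property


class TestLargestSeparation:
    def test_single_pair_is_global_maximum(self, hinge_pair, hinge_pool):
        s0 = hinge_pair[0]
        traj = fr.make_bundle(s0, 5, noise_scale=0.5, seed=1)
        res = select_largest_separation(s0, traj, hinge_pool, 1)
        static = hinge_pool.pair_distances(s0)
        assert res.ordered_pairs[0] == hinge_pool.pairs[int(np.argmax(static))]

    def test_correlated_candidate_pruned(self, hinge_pair):
        """A candidate whose distance series is perfectly correlated with an
        already-selected pair is skipped in favour of an uncorrelated one."""
        s0 = hinge_pair[0]
        static = fr.build_candidate_pool(s0)
        order = np.argsort(-static.pair_distances(s0))
        # pick three residue-disjoint pairs in descending separation
        chosen = []
        for m in order:
            p = static.pairs[m]
            if any(p.shares_residue(q) for q in chosen):
                continue
            chosen.append(p)
            if len(chosen) == 3:
                break
        a, b, c = chosen
        pool = manual_pool(s0, [a, b, c])
        corr = [(a, [1.0, 1.0, 0.0]), (b, [1.0, 1.0, 0.0]), (c, [0.0, 0.0, 1.0])]
        traj = fr.make_correlated_trajectory(s0, corr, n_frames=400, seed=3)
        res = select_largest_separation(s0, traj, pool, 2, rho_max=0.9)
        assert res.ordered_pairs == [a, c]  # b pruned as redundant with a

    def test_shared_residue_skipped_regardless_of_correlation(self, hinge_pair):
        s0 = hinge_pair[0]
        d = fr.distance_matrix(s0).values
        far = np.unravel_index(np.argmax(d), d.shape)
        a = ResiduePair(s0.residues[far[0]].key, s0.residues[far[1]].key)
        # shares residue beta with a; well separated but slightly less than a
        other = ResiduePair(s0.residues[far[0]].key, s0.residues[70].key)
        third = ResiduePair(s0.residues[5].key, s0.residues[60].key)
        pool = manual_pool(s0, [a, other, third])
        traj = fr.make_bundle(s0, 6, noise_scale=0.5, seed=9)
        res = select_largest_separation(s0, traj, pool, 2)
        assert a in res.ordered_pairs
        assert other not in res.ordered_pairs

    def test_audit_retained_correlations(self, hinge_pair, hinge_pool):
        s0 = hinge_pair[0]
        traj = fr.make_bundle(s0, 30, noise_scale=1.0, seed=4)
        res = select_largest_separation(s0, traj, hinge_pool, 4, rho_max=0.9)
        series = hinge_pool.ensemble_pair_distances(traj)
        idx = {p: m for m, p in enumerate(hinge_pool.pairs)}
        for i, p in enumerate(res.ordered_pairs):
            for q in res.ordered_pairs[:i]:
                rho = np.corrcoef(series[:, idx[p]], series[:, idx[q]])[0, 1]
                assert abs(rho) < 0.9


class QuiescentEngine:
    """Engine stub returning a frozen 2-frame ensemble of the start structure."""

    def __init__(self, s):
        self.s = s
        self.calls = []

    def __call__(self, restraints):
        self.calls.append(list(restraints))
        return Ensemble([self.s.with_coords(self.s.ca_coords) for _ in range(2)])


class TestLargestDelta:
    def test_first_pair_is_bruteforce_argmax(self, hinge_pair, hinge_pool):
        s0, s1 = hinge_pair
        engine = QuiescentEngine(s0)
        res = select_largest_delta(s0, s1, engine, hinge_pool, 1)
        dev = np.abs(hinge_pool.pair_distances(s0) - hinge_pool.pair_distances(s1))
        assert res.ordered_pairs[0] == hinge_pool.pairs[int(np.argmax(dev))]
        # ground truth of the fixture: the top pair spans the two domains
        beta, delta = res.ordered_pairs[0].beta, res.ordered_pairs[0].delta
        assert beta[1] <= 40 < delta[1]

    def test_no_residue_reuse(self, hinge_pair, hinge_pool):
        s0, s1 = hinge_pair
        res = select_largest_delta(s0, s1, QuiescentEngine(s0), hinge_pool, 3)
        used = set()
        for p in res.ordered_pairs:
            assert not (p.residues & used)
            used |= p.residues

    def test_restraints_carry_target_distances(self, hinge_pair, hinge_pool):
        s0, s1 = hinge_pair
        engine = QuiescentEngine(s0)
        select_largest_delta(s0, s1, engine, hinge_pool, 2)
        # second call receives the first selected pair restrained to target
        assert len(engine.calls[1]) == 1
        term = engine.calls[1][0]
        bi, di = s1.index_of(term.pair.beta), s1.index_of(term.pair.delta)
        assert term.target_distance == pytest.approx(
            float(np.linalg.norm(s1.ca_coords[bi] - s1.ca_coords[di]))
        )

    def test_degenerate_identical_structures(self, hinge_pair, hinge_pool):
        s0 = hinge_pair[0]
        res = select_largest_delta(s0, s0, QuiescentEngine(s0), hinge_pool, 1)
        assert len(res.ordered_pairs) == 1
        assert res.scores[0] == pytest.approx(0.0, abs=1e-9)


def _feature_ensembles(base, pairs, mean_shift, cov_scale, n_frames, seed):
    """Ensembles whose pool-pair distances follow prescribed Gaussians."""
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_frames):
        coords = base.ca_coords.copy()
        for k, p in enumerate(pairs):
            bi, di = base.index_of(p.beta), base.index_of(p.delta)
            axis = coords[di] - coords[bi]
            axis /= np.linalg.norm(axis)
            coords[di] = coords[di] + (mean_shift[k] + cov_scale[k] * rng.standard_normal()) * axis
        frames.append(base.with_coords(coords, identifier=f"f{t}"))
    return Ensemble(frames)


@pytest.fixture(scope="module")
def disjoint_pairs_base():
    rng = np.random.default_rng(21)
    base = toy_structure(rng.normal(0, 15, (10, 3)))
    pairs = [ResiduePair(("A", 2 * i + 1), ("A", 2 * i + 2)) for i in range(5)]
    return base, pairs


class TestLda:
    def test_identical_ensembles_raise(self, disjoint_pairs_base):
        base, pairs = disjoint_pairs_base
        pool = manual_pool(base, pairs)
        ens = _feature_ensembles(base, pairs, np.zeros(5), np.ones(5), 30, seed=1)
        with pytest.raises(NoDiscriminantError):
            fit_lda(ens, ens, pool)

    def test_axis_aligned_mean_difference(self, disjoint_pairs_base):
        base, pairs = disjoint_pairs_base
        pool = manual_pool(base, pairs[:2])
        a = _feature_ensembles(base, pairs[:2], [0.0, 0.0], [0.5, 0.5], 400, seed=2)
        b = _feature_ensembles(base, pairs[:2], [1.0, 0.0], [0.5, 0.5], 400, seed=3)
        model = fit_lda(a, b, pool)
        # isotropic within-scatter, mean difference along feature 1
        assert abs(model.direction[0]) > 0.95

    def test_rayleigh_ratio_beats_random_directions(self, disjoint_pairs_base):
        base, pairs = disjoint_pairs_base
        pool = manual_pool(base, pairs)
        rng = np.random.default_rng(7)
        a = _feature_ensembles(base, pairs, rng.normal(0, 0.5, 5), rng.uniform(0.3, 1, 5), 60, seed=4)
        b = _feature_ensembles(base, pairs, rng.normal(1, 0.5, 5), rng.uniform(0.3, 1, 5), 60, seed=5)
        model = fit_lda(a, b, pool)
        diff = model.mean_A - model.mean_B

        def rayleigh(U):
            num = (U @ diff) ** 2
            den = np.einsum("ij,jk,ik->i", U, model.Sw, U)
            return num / den

        U = rng.standard_normal((100_000, 5))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        best_random = rayleigh(U).max()
        assert rayleigh(model.direction[None, :])[0] >= best_random

    def test_matches_generalized_eigensolver(self, disjoint_pairs_base):
        base, pairs = disjoint_pairs_base
        pool = manual_pool(base, pairs)
        rng = np.random.default_rng(9)
        a = _feature_ensembles(base, pairs, np.zeros(5), rng.uniform(0.4, 1, 5), 80, seed=6)
        b = _feature_ensembles(base, pairs, rng.normal(0.8, 0.3, 5), rng.uniform(0.4, 1, 5), 80, seed=7)
        model = fit_lda(a, b, pool, regularization=1e-12)
        import scipy.linalg

        evals, evecs = scipy.linalg.eigh(model.Sb, model.Sw)
        lam = evals[-1]
        v = evecs[:, -1]
        v /= np.linalg.norm(v)
        assert model.eigenvalue == pytest.approx(lam, rel=1e-8)
        assert abs(v @ model.direction) == pytest.approx(1.0, abs=1e-6)

    def test_direction_collinear_with_sklearn(self, disjoint_pairs_base):
        """Independent cross-check against scikit-learn's LDA coefficient."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        base, pairs = disjoint_pairs_base
        pool = manual_pool(base, pairs)
        a = _feature_ensembles(base, pairs, np.zeros(5), 0.5 * np.ones(5), 120, seed=8)
        b = _feature_ensembles(base, pairs, np.full(5, 0.7), 0.5 * np.ones(5), 120, seed=9)
        model = fit_lda(a, b, pool, regularization=1e-10)
        X = np.vstack([pool.ensemble_pair_distances(a), pool.ensemble_pair_distances(b)])
        y = np.array([0] * 120 + [1] * 120)
        skl = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        w = skl.coef_[0] / np.linalg.norm(skl.coef_[0])
        assert abs(w @ model.direction) > 0.99

    def test_select_lda_ranking(self, disjoint_pairs_base):
        base, pairs = disjoint_pairs_base
        pool = manual_pool(base, pairs[:3])
        from fretrest.selection import LdaModel

        model = LdaModel(
            feature_pairs=pool.pairs,
            mean_A=np.zeros(3),
            mean_B=np.ones(3),
            Sw=np.eye(3),
            direction=np.array([0.8, -0.6, 0.0]),
            eigenvalue=1.0,
            regularization=0.0,
        )
        res = select_lda(model, 3)
        assert res.ordered_pairs == [pool.pairs[0], pool.pairs[1], pool.pairs[2]]
        assert res.scores == pytest.approx([0.8, 0.6, 0.0])
        with pytest.raises(ValueError):
            select_lda(model, 4)


class TestSelectionContracts:
    def test_all_methods_select_from_pool_and_nest(self, hinge_pair, hinge_pool):
        s0, s1 = hinge_pair
        traj = fr.make_bundle(s0, 8, noise_scale=0.8, seed=6)
        results = [
            select_largest_separation(s0, traj, hinge_pool, 3),
            select_largest_delta(s0, s1, QuiescentEngine(s0), hinge_pool, 3),
        ]
        pool_set = set(hinge_pool.pairs)
        for res in results:
            assert all(p in pool_set for p in res.ordered_pairs)
            assert len(res.ordered_pairs) == 3
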