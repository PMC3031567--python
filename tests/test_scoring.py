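import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbmap import (
    GeneSignature,
    NullModel,
    ReferenceSet,
    connection_strength,
    make_null_db,
    null_distribution,
    p_value,
    query,
    setscore,
)
from perturbmap.refdb import GeneUniverse, ReferenceProfile


class TestConnectionStrength:
    def test_maximal_concordance(self, profile5, sig_up_down):
        assert connection_strength(profile5, sig_up_down) == pytest.approx(1.0)

    def test_antisymmetry(self, profile5, sig_up_down):
        assert connection_strength(profile5, sig_up_down.flipped()) == pytest.approx(
            -1.0
        )

    def test_hand_computed_partial(self, profile5):
        sig = GeneSignature((("g3", 1), ("g5", -1)))
        assert connection_strength(profile5, sig) == pytest.approx(2 / 9)

    def test_missing_probe_error_and_drop(self, profile5):
        sig = GeneSignature((("g1", 1), ("nope", -1)))
        with pytest.raises(KeyError, match="nope"):
            connection_strength(profile5, sig)
        # dropped: reduced to the single probe g1 at top rank -> 5/5
        assert connection_strength(profile5, sig, missing="drop") == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_bounded_and_sign_flip_negates(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        universe = GeneUniverse(tuple(f"g{i}" for i in range(n)))
        ranks = (rng.permutation(n) + 1) * (rng.integers(0, 2, n) * 2 - 1)
        prof = ReferenceProfile("p", "c", universe, ranks)
        m = data.draw(st.integers(min_value=1, max_value=n))
        picks = rng.choice(n, m, replace=False)
        sig = GeneSignature(
            tuple((f"g{i}", int(rng.integers(0, 2) * 2 - 1)) for i in picks)
        )
        c = connection_strength(prof, sig)
        assert -1.0 <= c <= 1.0
        assert connection_strength(prof, sig.flipped()) == pytest.approx(-c)


class TestSetscore:
    def test_cancellation(self, universe5, sig_up_down):
        up = ReferenceProfile("a", "c", universe5, np.array([5, -4, 3, -2, 1]))
        down = ReferenceProfile("b", "c", universe5, np.array([-5, 4, 3, -2, 1]))
        rs = ReferenceSet("c", (up, down))
        assert setscore(rs, sig_up_down) == pytest.approx(0.0)

    def test_singleton_equals_profile_score(self, refset5, profile5, sig_up_down):
        assert setscore(refset5, sig_up_down) == pytest.approx(
            connection_strength(profile5, sig_up_down)
        )

    def test_mean_of_equal_scores(self, universe5):
        sig = GeneSignature((("g3", 1), ("g5", -1)))
        prof = ReferenceProfile("a", "c", universe5, np.array([5, -4, 3, -2, 1]))
        rs = ReferenceSet(
            "c",
            tuple(
                ReferenceProfile(f"p{i}", "c", universe5, prof.ranks.copy())
                for i in range(3)
            ),
        )
        assert setscore(rs, sig) == pytest.approx(2 / 9)

    def test_entry_order_never_matters(self, refset5):
        rng = np.random.default_rng(8)
        entries = (("g2", -1), ("g4", 1), ("g1", 1))
        base = setscore(refset5, GeneSignature(entries))
        for _ in range(5):
            perm = tuple(rng.permutation(len(entries)))
            shuffled = GeneSignature(tuple(entries[i] for i in perm))
            assert setscore(refset5, shuffled) == pytest.approx(base)


class TestNullDistribution:
    def test_exhaustive_singleton_enumeration(self, universe5):
        """N=4, m=1: 8 signed singletons; |setscore| uniform on k/4."""
        u4 = GeneUniverse(("a", "b", "c", "d"))
        prof = ReferenceProfile("p", "c", u4, np.array([4, -3, 2, -1]))
        rs = ReferenceSet("c", (prof,))
        nd = null_distribution(rs, 1, NullModel(mode="exhaustive"))
        assert len(nd) == 8
        assert sorted(np.abs(nd).tolist()) == [
            0.25, 0.25, 0.5, 0.5, 0.75, 0.75, 1.0, 1.0,
        ]
        assert np.mean(nd) == pytest.approx(0.0)

    def test_monte_carlo_mean_near_zero(self, refset5):
        nd = null_distribution(refset5, 2, NullModel(K=20_000, seed=4))
        se = nd.std() / np.sqrt(len(nd))
        assert abs(nd.mean()) < 3 * se

    def test_fixed_seed_reproducible(self, refset5):
        a = null_distribution(refset5, 2, NullModel(K=5000, seed=9))
        b = null_distribution(refset5, 2, NullModel(K=5000, seed=9))
        assert np.array_equal(a, b)

    def test_m_exceeding_universe_rejected(self, refset5):
        with pytest.raises(ValueError, match="exceeds"):
            null_distribution(refset5, 6, NullModel(K=10, seed=0))

    def test_exhaustive_cap_enforced(self):
        n = 40
        universe = GeneUniverse(tuple(f"g{i}" for i in range(n)))
        ranks = np.arange(1, n + 1)
        rs = ReferenceSet("c", (ReferenceProfile("p", "c", universe, ranks),))
        with pytest.raises(ValueError, match="monte_carlo"):
            null_distribution(rs, 20, NullModel(mode="exhaustive"))


class TestPValue:
    def test_pseudocount_floor(self):
        nd = np.zeros(999)
        assert p_value(0.5, nd) == pytest.approx(1 / 1000)

    def test_zero_observed_is_never_significant(self):
        nd = np.linspace(-1, 1, 999)
        assert p_value(0.0, nd) == pytest.approx(1.0)

    def test_exhaustive_exact_proportion(self, universe5):
        u4 = GeneUniverse(("a", "b", "c", "d"))
        prof = ReferenceProfile("p", "c", u4, np.array([4, -3, 2, -1]))
        rs = ReferenceSet("c", (prof,))
        nd = null_distribution(rs, 1, NullModel(mode="exhaustive"))
        assert p_value(1.0, nd, exhaustive=True) == pytest.approx(2 / 8)

    def test_monte_carlo_matches_exhaustive_small_instance(self):
        rng = np.random.default_rng(21)
        n, m, K = 6, 2, 50_000
        universe = GeneUniverse(tuple(f"g{i}" for i in range(n)))
        ranks = (rng.permutation(n) + 1) * (rng.integers(0, 2, n) * 2 - 1)
        rs = ReferenceSet("c", (ReferenceProfile("p", "c", universe, ranks),))
        exact = null_distribution(rs, m, NullModel(mode="exhaustive"))
        mc = null_distribution(rs, m, NullModel(K=K, seed=13))
        for obs in (0.2, 0.5, 0.8):
            pe = p_value(obs, exact, exhaustive=True)
            pm = p_value(obs, mc)
            se = np.sqrt(pe * (1 - pe) / K)
            assert abs(pm - pe) < 3 * se + 2 / (K + 1)


class TestQuery:
    def test_threshold_override_one_makes_all_significant(self, tiny_db):
        sig = GeneSignature((("g1", 1), ("g2", -1)))
        res = query(tiny_db, sig, NullModel(K=500, seed=1), threshold_override=1.0)
        assert all(r.significant for r in res)
        assert len(res) == tiny_db.n_sets

    def test_results_sorted_by_p_value(self):
        db = make_null_db(10, 2, 50, seed=3)
        sig = GeneSignature(tuple((p, 1) for p in db.universe.probe_ids[:5]))
        res = query(db, sig, NullModel(K=2000, seed=5))
        assert [r.p_value for r in res] == sorted(r.p_value for r in res)

    def test_flipping_signature_preserves_p_values(self):
        db = make_null_db(8, 2, 40, seed=6)
        sig = GeneSignature(
            tuple((p, s) for p, s in zip(db.universe.probe_ids[:6], [1, -1] * 3))
        )
        null = NullModel(K=3000, seed=7)
        res_a = {r.compound: r for r in query(db, sig, null)}
        res_b = {r.compound: r for r in query(db, sig.flipped(), null)}
        for c in res_a:
            assert res_a[c].setscore == pytest.approx(-res_b[c].setscore)
            assert res_a[c].p_value == res_b[c].p_value

    def test_identical_seed_identical_results(self):
        db = make_null_db(5, 1, 30, seed=2)
        sig = GeneSignature(tuple((p, 1) for p in db.universe.probe_ids[:4]))
        a = query(db, sig, NullModel(K=1000, seed=42))
        b = query(db, sig, NullModel(K=1000, seed=42))
        assert a == b
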