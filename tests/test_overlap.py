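from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import crossplast as cp
from crossplast.containers import ValidationError
from crossplast.orthomap import OrthologMap


def _instance(n_univ_a, n_univ_b, n_map, deg_a=(), deg_b=()):
    ua = [f"a{i}" for i in range(n_univ_a)]
    ub = [f"b{i}" for i in range(n_univ_b)]
    pairs = OrthologMap(pairs=tuple((ua[i], ub[i]) for i in range(n_map)))
    return cp.OverlapInput(ua, ub, deg_a, deg_b, pairs)


def _random_instance(rng, max_n=12):
    na = int(rng.integers(2, max_n))
    nb = int(rng.integers(2, max_n))
    m = int(rng.integers(0, min(na, nb) + 1))
    ka = int(rng.integers(0, na + 1))
    kb = int(rng.integers(0, nb + 1))
    ua = [f"a{i}" for i in range(na)]
    ub = [f"b{i}" for i in range(nb)]
    deg_a = list(rng.choice(ua, size=ka, replace=False))
    deg_b = list(rng.choice(ub, size=kb, replace=False))
    pairs = OrthologMap(pairs=tuple((ua[i], ub[i]) for i in range(m)))
    return cp.OverlapInput(ua, ub, deg_a, deg_b, pairs)


def _exact_null(inp):
    """Exhaustive enumeration of the permutation null distribution."""
    ua, ub = sorted(inp.universe_a), sorted(inp.universe_b)
    pair_set = set(inp.pairs.pairs)
    dist: dict[int, int] = {}
    total = 0
    for da in combinations(ua, inp.n_a):
        sa = set(da)
        for db in combinations(ub, inp.n_b):
            sb = set(db)
            k = sum(1 for a, b in pair_set if a in sa and b in sb)
            dist[k] = dist.get(k, 0) + 1
            total += 1
    return {k: v / total for k, v in dist.items()}


class TestOverlapCount:
    def test_disjoint_from_map_is_zero(self):
        inp = _instance(6, 6, 3, deg_a=["a4", "a5"], deg_b=["b4", "b5"])
        assert cp.overlap_count(inp.deg_a, inp.deg_b, inp.pairs) == 0

    def test_full_universes_count_all_pairs(self):
        inp = _instance(6, 7, 4, deg_a=[f"a{i}" for i in range(6)],
                        deg_b=[f"b{i}" for i in range(7)])
        assert cp.overlap_count(inp.deg_a, inp.deg_b, inp.pairs) == 4

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            inp = _random_instance(rng)
            brute = sum(
                1
                for a, b in inp.pairs.pairs
                if a in inp.deg_a and b in inp.deg_b
            )
            assert cp.overlap_count(inp.deg_a, inp.deg_b, inp.pairs) == brute


class TestClassifyDegs:
    def test_empty_map_makes_all_unaligned(self):
        inp = _instance(5, 5, 0, deg_a=["a0", "a1"])
        rep = cp.classify_degs(inp, tested_b=[f"b{i}" for i in range(5)])
        assert rep.class_unaligned == {"a0", "a1"}
        assert not rep.class_shared and not rep.class_not_sig

    def test_everything_shared_when_all_b_de(self):
        inp = _instance(5, 5, 5, deg_a=["a0", "a1"], deg_b=[f"b{i}" for i in range(5)])
        rep = cp.classify_degs(inp, tested_b=[f"b{i}" for i in range(5)])
        assert rep.class_shared == {"a0", "a1"}

    def test_untested_orthologs_form_their_own_class(self):
        inp = _instance(4, 4, 4, deg_a=["a0", "a1"], deg_b=["b1"])
        rep = cp.classify_degs(inp, tested_b=["b1"])  # b0 mapped but untested
        assert rep.class_untested == {"a0"}
        assert rep.class_shared == {"a1"}

    def test_classes_partition_deg_a(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            inp = _random_instance(rng)
            rep = cp.classify_degs(inp, tested_b=sorted(inp.universe_b))
            classes = [rep.class_shared, rep.class_not_sig, rep.class_unaligned,
                       rep.class_untested]
            assert sum(len(c) for c in classes) == inp.n_a
            union = set().union(*classes)
            assert union == inp.deg_a

    def test_deg_outside_universe_rejected(self):
        ua = ["a0", "a1"]
        with pytest.raises(ValidationError):
            cp.OverlapInput(ua, ["b0"], ["zz"], [], OrthologMap(pairs=()))


class TestPermutationTest:
    def test_saturated_draw_gives_p_one(self):
        inp = _instance(4, 4, 3, deg_a=[f"a{i}" for i in range(4)],
                        deg_b=[f"b{i}" for i in range(4)])
        perm, p = cp.permutation_test(inp, n_perm=50, seed=0)
        assert (perm == 3).all()
        assert p == 1.0

    def test_empty_deg_a_gives_p_one(self):
        inp = _instance(4, 4, 3, deg_a=[], deg_b=["b0"])
        perm, p = cp.permutation_test(inp, n_perm=50, seed=0)
        assert (perm == 0).all()
        assert p == 1.0

    def test_seed_reproducibility(self):
        inp = _instance(30, 30, 20, deg_a=[f"a{i}" for i in range(8)],
                        deg_b=[f"b{i}" for i in range(8)])
        perm1, _ = cp.permutation_test(inp, n_perm=100, seed=42)
        perm2, _ = cp.permutation_test(inp, n_perm=100, seed=42)
        perm3, _ = cp.permutation_test(inp, n_perm=100, seed=43)
        assert (perm1 == perm2).all()
        assert (perm1 != perm3).any()

    def test_invalid_n_perm_rejected(self):
        inp = _instance(4, 4, 2, deg_a=["a0"], deg_b=["b0"])
        with pytest.raises(ValidationError):
            cp.permutation_test(inp, n_perm=0)

    def test_null_p_values_are_not_anticonservative(self):
        # drawing deg sets by the very scheme the null assumes, p <= 0.05
        # should occur for at most ~5% of replicates
        rng = np.random.default_rng(123)
        ua = [f"a{i}" for i in range(200)]
        ub = [f"b{i}" for i in range(200)]
        pairs = OrthologMap(pairs=tuple((ua[i], ub[i]) for i in range(120)))
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            deg_a = rng.choice(ua, size=30, replace=False)
            deg_b = rng.choice(ub, size=30, replace=False)
            inp = cp.OverlapInput(ua, ub, deg_a, deg_b, pairs)
            _, p = cp.permutation_test(inp, n_perm=200, seed=int(rng.integers(2**31)))
            hits += p <= 0.05
        assert hits / n_rep <= 0.08


class TestExpectedOverlap:
    def test_saturated_mean_equals_map_size(self):
        inp = _instance(5, 5, 4, deg_a=[f"a{i}" for i in range(5)],
                        deg_b=[f"b{i}" for i in range(5)])
        mean, var = cp.expected_overlap(inp)
        assert mean == pytest.approx(4.0)
        assert var == pytest.approx(0.0)

    def test_empty_map_zero_moments(self):
        inp = _instance(5, 5, 0, deg_a=["a0"], deg_b=["b0"])
        assert cp.expected_overlap(inp) == (0.0, 0.0)

    def test_moments_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            na, nb = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            m = int(rng.integers(1, min(na, nb) + 1))
            ka, kb = int(rng.integers(1, na)), int(rng.integers(1, nb))
            ua = [f"a{i}" for i in range(na)]
            ub = [f"b{i}" for i in range(nb)]
            inp = cp.OverlapInput(ua, ub, ua[:ka], ub[:kb],
                                  OrthologMap(pairs=tuple(zip(ua[:m], ub[:m]))))
            dist = _exact_null(inp)
            mean_exact = sum(k * p for k, p in dist.items())
            var_exact = sum((k - mean_exact) ** 2 * p for k, p in dist.items())
            mean, var = cp.expected_overlap(inp)
            assert mean == pytest.approx(mean_exact, abs=1e-9)
            assert var == pytest.approx(var_exact, abs=1e-9)

    def test_permutation_mean_within_four_se_of_closed_form(self):
        rng = np.random.default_rng(29)
        n_perm = 10_000
        for _ in range(5):
            inp = _random_instance(rng, max_n=30)
            if inp.n_mapped == 0 or inp.n_a == 0 or inp.n_b == 0:
                continue
            perm, _ = cp.permutation_test(inp, n_perm=n_perm, seed=int(rng.integers(2**31)))
            mean, var = cp.expected_overlap(inp)
            se = np.sqrt(var / n_perm)
            assert abs(perm.mean() - mean) <= 4 * se + 1e-12


class TestConcordance:
    @staticmethod
    def _de(index, logfc):
        return pd.DataFrame({"logFC": logfc, "p_value": 0.001}, index=index)

    def test_same_sign_is_concordant_under_positive_correspondence(self):
        pairs = OrthologMap(pairs=(("a0", "b0"),))
        tbl = cp.concordance_table(
            ["a0"], self._de(["a0"], [1.5]), self._de(["b0"], [2.0]), pairs, "t1",
            correspondence=1,
        )
        assert tbl.loc[0, "concordant"]

    def test_flipping_one_contrast_flips_all_flags(self):
        pairs = OrthologMap(pairs=(("a0", "b0"), ("a1", "b1")))
        de_a = self._de(["a0", "a1"], [1.0, -2.0])
        de_b = self._de(["b0", "b1"], [0.5, 1.2])
        fwd = cp.concordance_table(["a0", "a1"], de_a, de_b, pairs, "t", correspondence=1)
        de_b_flipped = self._de(["b0", "b1"], [-0.5, -1.2])
        rev = cp.concordance_table(["a0", "a1"], de_a, de_b_flipped, pairs, "t", correspondence=1)
        assert list(fwd["concordant"]) == [not x for x in rev["concordant"]]

    def test_missing_logfc_flagged_incomplete(self):
        pairs = OrthologMap(pairs=(("a0", "b0"),))
        tbl = cp.concordance_table(
            ["a0"], self._de(["a0"], [1.0]), self._de([], []), pairs, "t",
        )
        assert tbl.loc[0, "incomplete"]
        assert tbl.loc[0, "concordant"] is None
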