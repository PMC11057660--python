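"""Rarefaction and the diversity/clonality statistic suite vs independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonodyn import (
    common_depth,
    gini,
    gini_evenness,
    large_clones,
    rank_abundance,
    rarefy,
    renyi_profile,
    shannon,
)
from clonodyn.diversity import DEFAULT_ALPHAS, diversity_profile

counts_strategy = st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# brute-force oracles: direct evaluation of the defining sums
# ---------------------------------------------------------------------------

def brute_shannon(counts):
    p = [c / sum(counts) for c in counts]
    return -sum(pi * math.log(pi) for pi in p)


def brute_renyi(counts, alpha):
    p = [c / sum(counts) for c in counts]
    if math.isinf(alpha):
        return -math.log(max(p))
    if alpha == 1.0:
        return brute_shannon(counts)
    if alpha == 0.0:
        return math.log(len(p))
    return math.log(sum(pi**alpha for pi in p)) / (1.0 - alpha)


def brute_gini(counts):
    x = list(map(float, counts))
    s = len(x)
    if s < 2:
        return 0.0
    num = sum(abs(a - b) for a in x for b in x)
    return num / (2.0 * s * s * (sum(x) / s))


class TestShannon:
    def test_hand_computed_three_clone_case(self, make_sample):
        h, norm = shannon(make_sample([50, 25, 25]))
        assert h == pytest.approx(1.0397208, abs=1e-6)
        assert norm == pytest.approx(0.9463946, abs=1e-6)

    def test_uniform_repertoire_has_unit_evenness(self, make_sample):
        _, norm = shannon(make_sample([10] * 17))
        assert norm == pytest.approx(1.0, abs=1e-12)

    def test_single_clone_is_zero_by_convention(self, make_sample):
        h, norm = shannon(make_sample([42]))
        assert h == 0.0
        assert norm == 0.0

    @given(counts_strategy)
    def test_matches_bruteforce(self, counts):
        h, _ = shannon(_sample(counts))
        assert h == pytest.approx(brute_shannon(counts), abs=1e-10)

    @given(counts_strategy.filter(lambda c: len(c) >= 2), st.integers(0, 100))
    def test_merging_two_clones_never_increases_entropy(self, counts, pick):
        # merging clones at fixed total reduces Shannon entropy
        s = _sample(counts)
        i = pick % len(counts)
        j = (pick + 1) % len(counts)
        merged = [c for k, c in enumerate(counts) if k not in (i, j)]
        merged.append(counts[i] + counts[j])
        h_before, _ = shannon(s)
        h_after, _ = shannon(_sample(merged))
        assert h_after <= h_before + 1e-12


def _sample(counts):
    """Module-local sample builder (hypothesis cannot call function fixtures)."""
    from clonodyn import Clonotype, RepertoireSample, SampleMeta

    def encode(i):
        letters = "ACDEFGHIKL"
        return "CAS" + "".join(letters[int(d)] for d in f"{i:04d}") + "F"

    clonotypes = [
        Clonotype(cdr3_aa=encode(i), count=int(n)) for i, n in enumerate(counts)
    ]
    return RepertoireSample(SampleMeta("s"), clonotypes)


class TestRenyi:
    def test_hand_computed_two_clone_case(self, make_sample):
        prof = dict(renyi_profile(make_sample([75, 25]), alphas=(2.0, math.inf)))
        assert prof[2.0] == pytest.approx(-math.log(0.625), abs=1e-10)
        assert prof[math.inf] == pytest.approx(-math.log(0.75), abs=1e-10)

    def test_uniform_profile_is_flat_at_log_richness(self, make_sample):
        prof = renyi_profile(make_sample([4] * 9))
        for _, h in prof:
            assert h == pytest.approx(math.log(9), abs=1e-10)

    @given(counts_strategy)
    def test_profile_non_increasing_in_alpha(self, counts):
        prof = renyi_profile(_sample(counts), alphas=DEFAULT_ALPHAS)
        values = [h for _, h in prof]
        for a, b in zip(values, values[1:]):
            assert b <= a + 1e-10

    @given(counts_strategy)
    def test_matches_bruteforce_all_orders(self, counts):
        s = _sample(counts)
        for alpha, h in renyi_profile(s, alphas=DEFAULT_ALPHAS):
            assert h == pytest.approx(brute_renyi(counts, alpha), abs=1e-10)


class TestGini:
    def test_even_counts_give_zero(self, make_sample):
        assert gini(make_sample([5] * 8)) == pytest.approx(0.0, abs=1e-12)
        assert gini_evenness(make_sample([5] * 8)) == pytest.approx(1.0, abs=1e-12)

    def test_skewed_case_matches_double_sum(self, make_sample):
        counts = [97, 1, 1, 1]
        assert gini(make_sample(counts)) == pytest.approx(brute_gini(counts), abs=1e-12)

    def test_single_clone_convention(self, make_sample):
        assert gini(make_sample([99])) == 0.0
        prof = diversity_profile(make_sample([99]))
        assert prof.degenerate

    @given(counts_strategy)
    def test_matches_bruteforce(self, counts):
        assert gini(_sample(counts)) == pytest.approx(brute_gini(counts), abs=1e-10)


class TestRankAbundance:
    def test_hand_computed_band_masses(self, make_sample):
        s = make_sample([60, 20, 10, 5, 5])
        masses = rank_abundance(s, bands=((1, 1), (2, 5)))
        assert masses["1-1"] == pytest.approx(0.6)
        assert masses["2-5"] == pytest.approx(0.4)

    def test_small_repertoire_in_first_band(self, make_sample):
        masses = rank_abundance(make_sample([3] * 5))
        assert masses["1-10"] == pytest.approx(1.0)

    @given(counts_strategy)
    def test_band_masses_sum_to_one(self, counts):
        masses = rank_abundance(_sample(counts))
        assert sum(masses.values()) == pytest.approx(1.0, abs=1e-9)


class TestLargeClones:
    def test_uniform_hundred_clones_all_large(self, make_sample):
        n, keys = large_clones(make_sample([1] * 100))
        assert n == 100

    def test_threshold_is_strict(self, make_sample):
        # depth 1000: count 5 is exactly 0.5% -> excluded; count 6 passes
        s = make_sample([989, 6, 5])
        n, keys = large_clones(s)
        assert n == 2

    def test_depth_dependence(self, make_sample):
        # at depth 100 every singleton is 1% > 0.5%; all clones are large
        s100 = make_sample([50, 3] + [1] * 47)
        n, _ = large_clones(s100)
        assert n == 49


class TestRarefaction:
    def test_full_depth_is_identity(self, make_sample):
        s = make_sample([10, 20, 30])
        r = rarefy(s, 60, seed=0)
        assert sorted(zip(r.keys(), r.counts())) == sorted(zip(s.keys(), s.counts()))

    def test_single_clone_any_depth(self, make_sample):
        r = rarefy(make_sample([500]), 17, seed=0)
        assert r.richness == 1
        assert r.total_count == 17

    def test_total_equals_requested_depth(self, make_sample, rng):
        s = make_sample((rng.integers(1, 60, size=25)).tolist())
        for depth in (1, 7, s.total_count // 2):
            assert rarefy(s, depth, seed=3).total_count == depth

    def test_never_upsamples(self, make_sample):
        with pytest.raises(ValueError, match="up-sample"):
            rarefy(make_sample([5, 5]), 11, seed=0)

    def test_deterministic_given_seed(self, make_sample):
        s = make_sample([40, 25, 30, 5])
        a = rarefy(s, 20, seed=7)
        b = rarefy(s, 20, seed=7)
        assert a.clonotypes == b.clonotypes

    def test_expected_frequency_matches_hypergeometric(self, make_sample):
        # E[count_1]/depth = p_1; Monte-Carlo mean vs closed form within 3 sigma
        s = make_sample([90, 10])
        big_key = s.keys()[0]  # canonical order puts the count-90 clone first
        depth, n_draws = 10, 2000
        rng = np.random.default_rng(11)
        draws = []
        for _ in range(n_draws):
            r = rarefy(s, depth, rng=rng)
            draws.append(dict(zip(r.keys(), r.counts())).get(big_key, 0))
        draws = np.array(draws, dtype=float)
        # hypergeometric variance with finite-population correction
        p = 0.9
        var = depth * p * (1 - p) * (100 - depth) / (100 - 1)
        assert abs(draws.mean() - 9.0) < 3 * math.sqrt(var / n_draws)


class TestCommonDepth:
    def test_minimum_total(self, make_sample):
        samples = [make_sample([1200]), make_sample([800]), make_sample([950])]
        assert common_depth(samples) == 800

    def test_single_sample(self, make_sample):
        assert common_depth([make_sample([5, 5])]) == 10

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            common_depth([])


class TestInvariance:
    def test_row_order_and_relabeling_invariance(self, make_sample, rng):
        counts = rng.integers(1, 50, size=30).tolist()
        s1 = make_sample(counts)
        perm = rng.permutation(30)
        s2 = make_sample([counts[i] for i in perm],
                         keys=[f"CWWW{chr(65 + i % 20)}{chr(65 + i // 20)}AAF" for i in range(30)])
        assert shannon(s1)[0] == pytest.approx(shannon(s2)[0], abs=1e-12)
        assert gini(s1) == pytest.approx(gini(s2), abs=1e-12)
        r1 = [h for _, h in renyi_profile(s1)]
        r2 = [h for _, h in renyi_profile(s2)]
        assert r1 == pytest.approx(r2, abs=1e-12)
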