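"""Connectivity scoring: KS statistic, permutation p, FDR, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sigreverse.connectivity import (
    concordant_inverse,
    connectivity_score,
    ks_enrichment,
    percentile_rank,
    permutation_significance,
    score_library,
)
from sigreverse.errors import (
    ConfigurationError,
    CoverageError,
    DegenerateSetError,
    IncompleteEvidenceError,
    ScoringError,
    TargetNotFoundError,
)
from sigreverse.signatures import ConditionKey, GeneSetPair

from conftest import make_ranked
from test_signatures import brute_force_bh


def oracle_ks(positions, n):
    """Exhaustive running-difference evaluation of the signed KS statistic.

    Walks every list position comparing the tag ECDF with the uniform CDF,
    independently of the closed-form implementation.
    """
    hits = set(positions)
    t = len(hits)
    best_up = -np.inf
    best_down = -np.inf
    count = 0
    for i in range(1, n + 1):
        before = count
        if i in hits:
            count += 1
        best_up = max(best_up, count / t - i / n)
        best_down = max(best_down, i / n - before / t)
    return best_up if best_up >= best_down else -best_down


def tags_at(positions, ranked):
    return [ranked.genes[p - 1] for p in positions]


class TestKsEnrichment:
    def test_top_concentration(self):
        ranked = make_ranked(10)
        assert ks_enrichment(tags_at([1, 2], ranked), ranked) == pytest.approx(0.8)

    def test_bottom_concentration(self):
        ranked = make_ranked(10)
        assert ks_enrichment(tags_at([9, 10], ranked), ranked) == pytest.approx(-0.9)

    def test_uniform_interleaving_is_small(self):
        ranked = make_ranked(50)
        positions = [5, 15, 25, 35, 45]
        es = ks_enrichment(tags_at(positions, ranked), ranked)
        assert abs(es) <= 1 / 5 + 1 / 50

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 51))
            t = int(rng.integers(1, n))
            positions = np.sort(rng.choice(n, size=t, replace=False)) + 1
            ranked = make_ranked(n)
            es = ks_enrichment(tags_at(positions, ranked), ranked)
            assert es == pytest.approx(oracle_ks(positions, n), abs=1e-12)

    def test_list_reversal_near_antisymmetry(self, rng):
        # Reversing the list maps the two KS deviations (a, b) to
        # (b - 1/n, a + 1/n): the magnitude is preserved to within 1/n
        # always, and whenever the reversal flips the sign of the score the
        # forward and reversed values cancel to within 1/t + 1/n. (When a
        # and b are within 2/n of each other both directions take the same
        # branch and only the magnitude statement applies.)
        for _ in range(300):
            n = int(rng.integers(4, 60))
            t = int(rng.integers(1, n))
            positions = np.sort(rng.choice(n, size=t, replace=False)) + 1
            ranked = make_ranked(n)
            tags = tags_at(positions, ranked)
            fwd = ks_enrichment(tags, ranked)
            rev = ks_enrichment(tags, ranked.reversed())
            assert abs(abs(fwd) - abs(rev)) <= 1 / n + 1e-12
            if fwd * rev < 0:
                assert abs(fwd + rev) <= 1 / t + 1 / n + 1e-12

    def test_absent_tags_dropped_and_errors(self):
        ranked = make_ranked(20)
        with pytest.raises(ScoringError):
            ks_enrichment(["zz1", "zz2"], ranked)
        with pytest.raises(CoverageError):
            ks_enrichment(["g1", "x1", "x2", "x3", "x4"], ranked)  # 1/5 retained
        with pytest.raises(DegenerateSetError):
            ks_enrichment(list(ranked.genes), ranked)


class TestConnectivityScore:
    def test_opposed_tag_sets(self):
        ranked = make_ranked(10)
        pair = GeneSetPair(
            frozenset(tags_at([1, 2], ranked)), frozenset(tags_at([9, 10], ranked))
        )
        res = connectivity_score(pair, ranked)
        assert res.es_up == pytest.approx(0.8)
        assert res.es_down == pytest.approx(-0.9)
        assert res.score == pytest.approx(0.85)

    def test_swap_antisymmetry(self, rng):
        for _ in range(200):
            n = int(rng.integers(8, 80))
            k = int(rng.integers(2, min(n - 1, 20)))
            ranked = make_ranked(n)
            pos = rng.choice(n, size=k, replace=False) + 1
            split = int(rng.integers(1, k))
            pair = GeneSetPair(
                frozenset(tags_at(pos[:split], ranked)),
                frozenset(tags_at(pos[split:], ranked)),
            )
            fwd = connectivity_score(pair, ranked).score
            rev = connectivity_score(pair.swapped(), ranked).score
            assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_same_sign_scores_zero(self):
        ranked = make_ranked(20)
        pair = GeneSetPair(
            frozenset(tags_at([1, 2], ranked)), frozenset(tags_at([3, 4], ranked))
        )
        assert connectivity_score(pair, ranked).score == 0.0


class TestPermutation:
    def test_zero_score_has_p_one(self):
        ranked = make_ranked(20)
        pair = GeneSetPair(
            frozenset(tags_at([1, 2], ranked)), frozenset(tags_at([3, 4], ranked))
        )
        p, _ = permutation_significance(pair, ranked, n_perm=200, seed=0)
        assert p == 1.0

    def test_agrees_with_exhaustive_enumeration(self):
        # n = 8, single up tag and single down tag: the null has exactly
        # 8 x 7 equally likely disjoint placements.
        n = 8
        ranked = make_ranked(n)
        null = []
        for up, down in itertools.permutations(range(1, n + 1), 2):
            es_u = oracle_ks([up], n)
            es_d = oracle_ks([down], n)
            opposite = es_u != 0 and es_d != 0 and np.sign(es_u) != np.sign(es_d)
            null.append((es_u - es_d) / 2 if opposite else 0.0)
        pair = GeneSetPair(frozenset([ranked.genes[0]]), frozenset([ranked.genes[7]]))
        obs = connectivity_score(pair, ranked).score
        exact = np.mean(np.abs(null) >= abs(obs))
        n_perm = 1000
        p_mc, _ = permutation_significance(pair, ranked, n_perm=n_perm, seed=5)
        half_width = 2.576 * np.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
        assert abs(p_mc - exact) <= half_width

    def test_p_floor(self):
        ranked = make_ranked(300)
        pair = GeneSetPair(
            frozenset(tags_at(range(1, 6), ranked)),
            frozenset(tags_at(range(296, 301), ranked)),
        )
        p, null = permutation_significance(pair, ranked, n_perm=500, seed=1)
        assert p >= 1 / 501
        assert p == pytest.approx(1 / 501)  # obs beats every null at this seed
        assert len(null) == 500

    def test_too_few_permutations_rejected(self):
        ranked = make_ranked(20)
        pair = GeneSetPair(frozenset(["g1"]), frozenset(["g20"]))
        with pytest.raises(ConfigurationError):
            permutation_significance(pair, ranked, n_perm=50, seed=0)


class TestScoreLibrary:
    def _pairs(self, ranked, specs):
        out = {}
        for i, (up, down) in enumerate(specs):
            key = ConditionKey(f"c{i}", "cellA", "high")
            out[key] = GeneSetPair(
                frozenset(tags_at(up, ranked)), frozenset(tags_at(down, ranked))
            )
        return out

    def test_singleton_family_q_equals_p(self):
        ranked = make_ranked(40)
        pairs = self._pairs(ranked, [([1, 2, 3], [38, 39, 40])])
        table = score_library(pairs, {"d0": ranked}, n_perm=200, seed=3)
        assert len(table) == 1
        assert table.loc[0, "q"] == table.loc[0, "p"]

    def test_bh_over_all_rows(self):
        ranked = make_ranked(40)
        other = make_ranked(40)
        pairs = self._pairs(
            ranked,
            [([1, 2, 3], [38, 39, 40]), ([5, 9, 12], [20, 25, 30]),
             ([2, 4, 6], [30, 35, 39]), ([10, 20, 30], [4, 15, 26])],
        )
        table = score_library(pairs, {"dA": ranked, "dB": other}, n_perm=200, seed=3)
        assert len(table) == 8
        assert np.allclose(table["q"], brute_force_bh(list(table["p"])))

    def test_coverage_failures_flagged_and_excluded(self):
        ranked = make_ranked(40)
        pairs = self._pairs(ranked, [([1, 2, 3], [38, 39, 40])])
        bad_key = ConditionKey("bad", "cellA", "high")
        pairs[bad_key] = GeneSetPair(
            frozenset(["x1", "x2", "x3", "x4"]), frozenset(tags_at([30, 31], ranked))
        )
        table = score_library(pairs, {"d0": ranked}, n_perm=200, seed=3)
        bad = table[table["compound"] == "bad"].iloc[0]
        good = table[table["compound"] == "c0"].iloc[0]
        assert bad["flag"] == "ScoringError"
        assert np.isnan(bad["q"])
        assert good["q"] == good["p"]  # BH family excludes the flagged row

    def test_shared_and_per_pair_nulls_agree(self):
        ranked = make_ranked(100)
        pairs = self._pairs(ranked, [([1, 2, 3, 4], [97, 98, 99, 100])])
        a = score_library(pairs, {"d": ranked}, n_perm=2000, seed=9, share_null=True)
        b = score_library(pairs, {"d": ranked}, n_perm=2000, seed=9, share_null=False)
        assert a.loc[0, "score"] == b.loc[0, "score"]
        assert a.loc[0, "p"] == pytest.approx(b.loc[0, "p"], abs=0.02)


class TestConcordance:
    def _results(self, scores, qs):
        rows = []
        for i, (s, q) in enumerate(zip(scores, qs)):
            rows.append(
                {
                    "compound": "drug", "cell": ["cellA", "cellA", "cellB", "cellB"][i],
                    "dose": ["high", "low", "high", "low"][i], "disease": "nash",
                    "es_up": -0.5, "es_down": 0.5, "score": s, "p": q, "q": q,
                    "n_perm": 1000,
                }
            )
        return pd.DataFrame(rows)

    def test_all_conditions_pass(self):
        call = concordant_inverse(self._results([-0.5] * 4, [0.001] * 4))
        assert call.inverse_concordant

    def test_single_failure_rule(self):
        call = concordant_inverse(self._results([-0.5] * 4, [0.001] * 3 + [0.02]))
        assert not call.inverse_concordant

    def test_threshold_is_strict(self):
        call = concordant_inverse(self._results([-0.5] * 4, [0.001] * 3 + [0.01]))
        assert not call.inverse_concordant

    def test_positive_score_fails(self):
        call = concordant_inverse(self._results([-0.5] * 3 + [0.2], [0.001] * 4))
        assert not call.inverse_concordant

    def test_missing_condition_is_not_false(self):
        with pytest.raises(IncompleteEvidenceError):
            concordant_inverse(self._results([-0.5] * 4, [0.001] * 4).iloc[:3])


class TestPercentile:
    def test_best_of_fifty_is_top_two_percent(self):
        scores = [-0.9] + [0.01 * i for i in range(49)]
        assert percentile_rank(-0.9, scores) == pytest.approx(2.0)

    def test_worst_of_fifty(self):
        scores = [0.9] + [-0.01 * i for i in range(49)]
        assert percentile_rank(0.9, scores) == pytest.approx(100.0)

    def test_ties_share_best_rank(self):
        scores = [-1.0, -1.0] + [0.0] * 98
        assert percentile_rank(-1.0, scores) == pytest.approx(1.0)

    def test_target_must_be_member(self):
        with pytest.raises(TargetNotFoundError):
            percentile_rank(-0.5, [0.1, 0.2])
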