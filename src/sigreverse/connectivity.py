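"""Rank-based connectivity scoring of drug tag sets against disease profiles.

The statistic is the classic two-sided Kolmogorov–Smirnov tag-set enrichment
used in connectivity mapping. For the ``t`` retained tag genes at sorted
1-based positions ``V(1) < … < V(t)`` in a ranked list of length ``n``::

    a = max_j ( j/t   - V(j)/n )
    b = max_j ( V(j)/n - (j-1)/t )

and the enrichment score is ``a`` if ``a ≥ b`` else ``-b`` (positive when the
tags concentrate near the top of the list). The composite connectivity score
of an up/down tag-set pair queried against a disease-ranked list is
``(es_up - es_down)/2`` when the two enrichments have strictly opposite
signs, and 0 otherwise: a compound only counts as connected when its
up-regulated genes and down-regulated genes fall on opposite ends of the
disease profile. A negative score means the compound's transcriptional
effect opposes — is predicted to "normalize" — the disease signature.

Significance comes from a gene-label permutation null: both tag sets are
redrawn as disjoint uniform random gene sets of the same retained sizes and
rescored; the two-sided permutation p is ``(1 + #{|s_null| ≥ |s_obs|}) /
(n_perm + 1)``. Because the null depends on the instance only through
``(n, t_up, t_down)``, a library run can share one Monte-Carlo null across
all pairs of the same shape, which makes very deep nulls (hence small
attainable FDR) affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    CoverageError,
    DegenerateSetError,
    IncompleteEvidenceError,
    ScoringError,
    TargetNotFoundError,
)
from .signatures import ConditionKey, GeneSetPair, RankedList, bh_adjust

MIN_TAG_COVERAGE = 0.25
_NULL_CHUNK = 2000


class ConnectivityScore(NamedTuple):
    es_up: float
    es_down: float
    score: float


@dataclass(frozen=True)
class ConnectivityResult:
    """Score and significance for one compound-condition / disease pair."""

    compound_condition: ConditionKey
    disease_id: str
    es_up: float
    es_down: float
    score: float
    p: float
    q: float
    n_perm: int


@dataclass(frozen=True)
class ConcordanceCall:
    """Cross-condition inverse-concordance verdict for one compound/disease."""

    compound: str
    disease_id: str
    results: tuple
    inverse_concordant: bool


def _es_from_sorted_positions(pos: np.ndarray, n: int) -> float:
    t = len(pos)
    j = np.arange(1, t + 1)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a) if a >= b else float(-b)


def _retained_positions(tags: Iterable, ranked: RankedList) -> np.ndarray:
    tags = list(tags)
    if not tags:
        raise ScoringError("empty tag set")
    pos = ranked.positions(tags)
    if len(pos) == 0:
        raise ScoringError("no tag genes present in the ranked list")
    if len(pos) < MIN_TAG_COVERAGE * len(tags):
        raise CoverageError(
            f"only {len(pos)}/{len(tags)} tag genes retained "
            f"(< {MIN_TAG_COVERAGE:.0%} coverage)"
        )
    if len(pos) == len(ranked):
        raise DegenerateSetError("tag set covers the entire ranked list")
    return pos


def ks_enrichment(tags: Iterable, ranked: RankedList) -> float:
    """Signed KS enrichment of a tag set in a ranked list, in [-1, 1].

    Tag genes absent from the list are dropped; fewer than 25% retained is a
    coverage error. A tie ``a == b`` returns the positive branch (documented,
    arbitrary but fixed).
    """
    pos = _retained_positions(tags, ranked)
    return _es_from_sorted_positions(pos, len(ranked))


def _combine(es_up: float, es_down: float) -> float:
    if es_up == 0.0 or es_down == 0.0 or np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(drug_sets: GeneSetPair, disease_ranked: RankedList) -> ConnectivityScore:
    """Composite signed connectivity of an up/down pair against a ranked list."""
    es_up = ks_enrichment(drug_sets.up_tags, disease_ranked)
    es_down = ks_enrichment(drug_sets.down_tags, disease_ranked)
    return ConnectivityScore(es_up, es_down, _combine(es_up, es_down))


def _sample_tag_positions(
    rng: np.random.Generator, n: int, k: int, n_draws: int
) -> np.ndarray:
    """``n_draws`` uniform samples of ``k`` distinct 1-based positions from 1..n.

    Columns are ordered by the random keys, so any prefix/suffix split of a
    row is itself a uniform split of the sampled set (argpartition's own
    ordering correlates with original positions and must not be used).
    """
    keys = rng.random((n_draws, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    sel_keys = np.take_along_axis(keys, idx, axis=1)
    order = np.argsort(sel_keys, axis=1)
    return np.take_along_axis(idx, order, axis=1) + 1


def _null_scores(
    rng: np.random.Generator, n: int, t_up: int, t_down: int, n_perm: int
) -> np.ndarray:
    """Null composite scores for random disjoint up/down tag sets."""
    out = np.empty(n_perm)
    k = t_up + t_down
    done = 0
    while done < n_perm:
        m = min(_NULL_CHUNK, n_perm - done)
        pos = _sample_tag_positions(rng, n, k, m)
        up = np.sort(pos[:, :t_up], axis=1)
        down = np.sort(pos[:, t_up:], axis=1)
        es_u = _es_matrix(up, n)
        es_d = _es_matrix(down, n)
        opposite = (np.sign(es_u) != np.sign(es_d)) & (es_u != 0) & (es_d != 0)
        out[done : done + m] = np.where(opposite, (es_u - es_d) / 2.0, 0.0)
        done += m
    return out


def _es_matrix(pos: np.ndarray, n: int) -> np.ndarray:
    """Vectorised KS enrichment over rows of sorted 1-based positions."""
    t = pos.shape[1]
    j = np.arange(1, t + 1)
    a = np.max(j / t - pos / n, axis=1)
    b = np.max(pos / n - (j - 1) / t, axis=1)
    return np.where(a >= b, a, -b)


def permutation_significance(
    drug_sets: GeneSetPair,
    disease_ranked: RankedList,
    n_perm: int,
    seed: int | np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Two-sided permutation p for the composite score, plus the null sample."""
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    up_pos = _retained_positions(drug_sets.up_tags, disease_ranked)
    down_pos = _retained_positions(drug_sets.down_tags, disease_ranked)
    n = len(disease_ranked)
    obs = _combine(
        _es_from_sorted_positions(up_pos, n), _es_from_sorted_positions(down_pos, n)
    )
    null = _null_scores(rng, n, len(up_pos), len(down_pos), n_perm)
    p = (1.0 + int(np.sum(np.abs(null) >= abs(obs)))) / (n_perm + 1.0)
    return p, null


def score_library(
    drug_signatures: Mapping[ConditionKey, GeneSetPair],
    disease_profiles: Mapping[str, RankedList],
    *,
    n_perm: int = 1000,
    seed: int = 0,
    share_null: bool = True,
) -> pd.DataFrame:
    """Score every signature × disease pair with permutation p and BH q.

    Returns one row per pair with columns compound, cell, dose, disease,
    es_up, es_down, score, p, q, n_perm, flag. BH is applied once across all
    successfully scored rows of the run (a single family). Pairs failing
    coverage are flagged by exception name, carry NaN score/p/q, and are
    excluded from the family.

    With ``share_null`` (default) one permutation null sample is drawn per
    unique (list length, retained up size, retained down size) shape and
    reused for every pair of that shape — the standard shared Monte-Carlo
    null, which makes 10^5-scale permutation depths tractable on one CPU.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    if not drug_signatures or not disease_profiles:
        raise ConfigurationError("need at least one signature and one disease")
    base = np.random.SeedSequence(seed & 0x7FFFFFFF)
    shared: dict[tuple[int, int, int], np.ndarray] = {}
    rows = []
    pair_rng = np.random.default_rng(base.spawn(1)[0])
    for key, pair in drug_signatures.items():
        for disease_id, ranked in disease_profiles.items():
            row = {
                "compound": key.compound,
                "cell": key.cell,
                "dose": key.dose,
                "disease": disease_id,
                "es_up": np.nan,
                "es_down": np.nan,
                "score": np.nan,
                "p": np.nan,
                "q": np.nan,
                "n_perm": n_perm,
                "flag": "",
            }
            try:
                up_pos = _retained_positions(pair.up_tags, ranked)
                down_pos = _retained_positions(pair.down_tags, ranked)
            except ScoringError as exc:
                row["flag"] = type(exc).__name__
                rows.append(row)
                continue
            n = len(ranked)
            es_u = _es_from_sorted_positions(up_pos, n)
            es_d = _es_from_sorted_positions(down_pos, n)
            obs = _combine(es_u, es_d)
            shape = (n, len(up_pos), len(down_pos))
            if share_null:
                if shape not in shared:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([seed & 0x7FFFFFFF, *shape])
                    )
                    shared[shape] = np.sort(np.abs(_null_scores(rng, *shape, n_perm)))
                null_abs = shared[shape]
                exceed = len(null_abs) - np.searchsorted(null_abs, abs(obs), side="left")
                p = (1.0 + float(exceed)) / (n_perm + 1.0)
            else:
                null = _null_scores(pair_rng, *shape, n_perm)
                p = (1.0 + int(np.sum(np.abs(null) >= abs(obs)))) / (n_perm + 1.0)
            row.update(es_up=es_u, es_down=es_d, score=obs, p=p)
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["flag"] == ""
    if ok.any():
        table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def concordant_inverse(
    results: Sequence[ConnectivityResult] | pd.DataFrame,
    *,
    q_threshold: float = 0.01,
    expected_conditions: int = 4,
) -> ConcordanceCall:
    """Call cross-condition inverse concordance for one compound/disease.

    True iff every expected condition is present with score < 0 and q
    strictly below ``q_threshold`` (q == threshold exactly does not pass).
    Missing conditions raise :class:`IncompleteEvidenceError` rather than
    returning False: absence of evidence is not counted as a negative call.
    """
    if isinstance(results, pd.DataFrame):
        results = tuple(
            ConnectivityResult(
                compound_condition=ConditionKey(r.compound, r.cell, r.dose),
                disease_id=r.disease,
                es_up=r.es_up,
                es_down=r.es_down,
                score=r.score,
                p=r.p,
                q=r.q,
                n_perm=int(r.n_perm),
            )
            for r in results.itertuples()
        )
    if not results:
        raise IncompleteEvidenceError("no condition results supplied")
    compounds = {r.compound_condition.compound for r in results}
    diseases = {r.disease_id for r in results}
    if len(compounds) != 1 or len(diseases) != 1:
        raise ConfigurationError("results must cover exactly one compound and one disease")
    conditions = {(r.compound_condition.cell, r.compound_condition.dose) for r in results}
    if len(conditions) < expected_conditions:
        raise IncompleteEvidenceError(
            f"{len(conditions)} of {expected_conditions} expected conditions present"
        )
    ok = all(r.score < 0 and r.q < q_threshold for r in results)
    return ConcordanceCall(
        compound=compounds.pop(),
        disease_id=diseases.pop(),
        results=tuple(results),
        inverse_concordant=ok,
    )


def percentile_rank(target_score: float, library_scores: Sequence[float]) -> float:
    """Percentile of a score within a library, most negative = percentile → 0.

    Scores are sorted ascending (strongest reversal first); the percentile is
    ``100 · rank / N`` with tied scores sharing the best (smallest) rank. The
    target must be a member of the library.
    """
    scores = np.asarray(list(library_scores), dtype=float)
    if scores.size == 0:
        raise ConfigurationError("empty score library")
    if not np.any(scores == target_score):
        raise TargetNotFoundError(f"score {target_score!r} not in library")
    rank = int(np.sum(scores < target_score)) + 1
    return 100.0 * rank / scores.size
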