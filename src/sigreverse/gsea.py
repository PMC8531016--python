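"""Weighted gene-set enrichment of tag sets in ranked expression profiles.

The running-sum enrichment score walks the ranked list top to bottom: hitting
a tag gene adds its weight ``|r|^exponent`` (normalised by the total tag
weight), missing one subtracts ``1/(n - t)``. The enrichment score (ES) is
the running-sum value of maximum absolute deviation from zero, signed:
positive when tags concentrate near the top (up-regulated end), negative
near the bottom. ``exponent = 0`` gives the classic unweighted statistic;
``exponent = 1`` (the default) weights hits by the ranking statistic.

Significance uses a gene-set permutation null — random gene sets of the same
retained size drawn from the ranked universe — appropriate when only
summary-level ranked profiles (not sample-level expression) are available.
NES rescales ES by the mean magnitude of null scores sharing its sign; p is
the two-sided permutation tail; q is Benjamini–Hochberg across all sets
tested in one call.

The direction panel reproduces the repositioning validation logic: a drug's
signature is *inversely* enriched in a disease profile when its up-tags
score negative and its down-tags positive (both significant), *concordant*
when the signs are reversed, and *null* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateWeightError
from .signatures import GeneSetPair, RankedList, bh_adjust
from .connectivity import _retained_positions


@dataclass(frozen=True)
class EnrichmentResult:
    """ES/NES/p/q of one gene set against one ranked list."""

    set_id: str
    es: float
    nes: float  # NaN when no null score shares the observed sign
    p: float
    q: float
    direction_call: str  # inverse | concordant | null


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Signed maximum running-sum deviation from sorted hit positions.

    ``pos`` are sorted 1-based hit positions, ``weights`` the (non-negative)
    hit weights aligned to them. The running-sum extrema can only occur just
    after a hit (candidate maxima) or just before one (candidate minima), so
    the scan is O(t). A tie in magnitude returns the positive branch.
    """
    t = len(pos)
    total = float(weights.sum())
    if total <= 0:
        raise DegenerateWeightError("all tag weights are zero")
    miss = 1.0 / (n - t)
    cum = np.cumsum(weights) / total
    misses_before = pos - np.arange(1, t + 1)  # misses strictly before hit j
    after_hit = cum - misses_before * miss
    before_hit = np.concatenate(([0.0], cum[:-1])) - misses_before * miss
    top = float(np.max(after_hit))
    bottom = float(np.min(before_hit))
    # magnitude ties resolve to the positive branch; the 1e-12 guard keeps
    # the rule stable against accumulation rounding
    if max(top, 0.0) >= abs(min(bottom, 0.0)) - 1e-12:
        return max(top, 0.0)
    return bottom


def gsea_es(ranked: RankedList, tags: Iterable, exponent: float = 1.0) -> float:
    """Weighted running-sum enrichment score of ``tags`` in ``ranked``."""
    if exponent < 0:
        raise ConfigurationError("exponent must be non-negative")
    pos = _retained_positions(tags, ranked)
    w = _hit_weights(ranked, pos, exponent)
    return _es_from_positions(pos, w, len(ranked))


def _hit_weights(ranked: RankedList, pos: np.ndarray, exponent: float) -> np.ndarray:
    if exponent == 0:
        return np.ones(len(pos))
    return np.abs(ranked.stats[pos - 1]) ** exponent


def _null_es(
    rng: np.random.Generator,
    ranked: RankedList,
    t: int,
    exponent: float,
    n_perm: int,
) -> np.ndarray:
    n = len(ranked)
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=t, replace=False)) + 1
        out[i] = _es_from_positions(pos, _hit_weights(ranked, pos, exponent), n)
    return out


def _direction(es: float, q: float, q_threshold: float) -> str:
    if es < 0 and q < q_threshold:
        return "inverse"
    if es > 0 and q < q_threshold:
        return "concordant"
    return "null"


def gsea_significance(
    ranked: RankedList,
    tags: Iterable,
    *,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    q_threshold: float = 0.05,
    set_id: str = "",
) -> EnrichmentResult:
    """Permutation significance for one gene set (singleton BH family: q = p)."""
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = _retained_positions(tags, ranked)
    es = _es_from_positions(pos, _hit_weights(ranked, pos, exponent), len(ranked))
    null = _null_es(rng, ranked, len(pos), exponent, n_perm)
    if es == 0.0:
        return EnrichmentResult(set_id, 0.0, np.nan, 1.0, 1.0, "null")
    p = (1.0 + int(np.sum(np.abs(null) >= abs(es)))) / (n_perm + 1.0)
    same_sign = null[np.sign(null) == np.sign(es)]
    nes = es / float(np.mean(np.abs(same_sign))) if same_sign.size else np.nan
    return EnrichmentResult(set_id, es, nes, p, p, _direction(es, p, q_threshold))


def enrich_sets(
    ranked: RankedList,
    sets: Mapping[str, Iterable],
    *,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score several gene sets against one list; BH across the whole call."""
    rng = np.random.default_rng(seed)
    rows = []
    for set_id, tags in sets.items():
        res = gsea_significance(
            ranked,
            tags,
            exponent=exponent,
            n_perm=n_perm,
            seed=rng,
            q_threshold=q_threshold,
            set_id=set_id,
        )
        rows.append(
            {"set": set_id, "es": res.es, "nes": res.nes, "p": res.p, "q": np.nan}
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["call"] = [
        _direction(es, q, q_threshold) for es, q in zip(table["es"], table["q"])
    ]
    return table


def signature_direction_panel(
    drug_sets: GeneSetPair,
    disease_ranked_lists: Mapping[str, RankedList],
    *,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-list direction calls for one drug's up/down tag sets.

    ``inverse``: up-tags enriched at the bottom (es < 0) and down-tags at the
    top (es > 0), both with q below threshold — the drug opposes the profile.
    ``concordant``: both signs reversed. ``null`` otherwise. BH is applied
    across all 2 × n_lists tests of the call (one family).
    """
    rng = np.random.default_rng(seed)
    records = []
    for list_id, ranked in disease_ranked_lists.items():
        r_up = gsea_significance(
            ranked, drug_sets.up_tags, exponent=exponent, n_perm=n_perm, seed=rng
        )
        r_down = gsea_significance(
            ranked, drug_sets.down_tags, exponent=exponent, n_perm=n_perm, seed=rng
        )
        records.append((list_id, r_up, r_down))
    p_all = np.array([p for _, u, d in records for p in (u.p, d.p)])
    q_all = bh_adjust(p_all)
    rows = []
    for i, (list_id, r_up, r_down) in enumerate(records):
        q_up, q_down = q_all[2 * i], q_all[2 * i + 1]
        significant = q_up < q_threshold and q_down < q_threshold
        if significant and r_up.es < 0 and r_down.es > 0:
            call = "inverse"
        elif significant and r_up.es > 0 and r_down.es < 0:
            call = "concordant"
        else:
            call = "null"
        rows.append(
            {
                "list": list_id,
                "es_up": r_up.es,
                "es_down": r_down.es,
                "nes_up": r_up.nes,
                "nes_down": r_down.nes,
                "p_up": r_up.p,
                "p_down": r_down.p,
                "q_up": q_up,
                "q_down": q_down,
                "call": call,
            }
        )
    return pd.DataFrame(rows)
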