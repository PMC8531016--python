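"""Differential expression signatures, tag sets, and ranked lists.

A *signature* is the per-gene differential profile of one treated-vs-control
(or case-vs-control) contrast. Counts are normalised to counts-per-million,
log2-transformed with a pseudocount, and tested gene-by-gene with a moderated
t statistic: the pooled two-arm variance of each gene is shrunk toward the
across-gene mean variance with a prior weight of ``d0`` degrees of freedom
(an empirical-Bayes stabilisation appropriate for small-replicate RNA-seq
contrasts), and the statistic is referred to a t distribution with
``n1 + n2 - 2 + d0`` degrees of freedom. Multiplicity is controlled with
Benjamini–Hochberg across the gene universe.

Downstream scoring consumes two derived objects: the :class:`GeneSetPair`
(top up- and down-regulated "tag" gene sets) and the :class:`RankedList`
(all genes ordered by the moderated statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptyTagSetError,
)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_PRIOR_DF = 10.0


class ConditionKey(NamedTuple):
    """Identifies one compound-condition: (compound, cell context, dose level)."""

    compound: str
    cell: str
    dose: str

    def label(self) -> str:
        return f"{self.compound}|{self.cell}|{self.dose}"

    @classmethod
    def from_label(cls, label: str) -> "ConditionKey":
        parts = label.split("|")
        if len(parts) != 3:
            raise ValueError(f"not a compound|cell|dose label: {label!r}")
        return cls(*parts)


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values for one arm (or one labelled cohort).

    ``data`` is indexed by gene identifier with sample identifiers as columns.
    ``groups`` optionally maps each sample to a group label ('treated' /
    'control'); arm-level matrices may omit it. ``is_log`` flags values already
    on the log scale (counts otherwise, and must be non-negative).
    """

    data: pd.DataFrame
    groups: pd.Series | None = None
    is_log: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ConfigurationError("duplicate gene identifiers in expression matrix")
        if self.data.columns.has_duplicates:
            raise ConfigurationError("duplicate sample identifiers in expression matrix")
        if not self.is_log and (self.data.to_numpy() < 0).any():
            raise ConfigurationError("negative values in a count-flagged matrix")
        if self.groups is not None:
            missing = set(self.data.columns) - set(self.groups.index)
            if missing:
                raise ConfigurationError(f"samples without group labels: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class DifferentialSignature:
    """Per-gene log2fc / moderated-t / p / q table for one contrast.

    ``table`` columns: ``log2fc``, ``stat``, ``p``, ``q`` (the latter three are
    NaN when either arm had a single sample). ``origin`` names the contrast.
    """

    table: pd.DataFrame
    origin: str = ""

    @property
    def has_pvalues(self) -> bool:
        return bool(np.isfinite(self.table["p"].to_numpy()).all())

    def significant_genes(self, q_cutoff: float) -> pd.Index:
        """Genes with BH-adjusted q strictly below ``q_cutoff``."""
        return self.table.index[self.table["q"] < q_cutoff]


@dataclass(frozen=True)
class GeneSetPair:
    """Up- and down-regulated tag gene sets of one signature."""

    up_tags: frozenset
    down_tags: frozenset
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.up_tags or not self.down_tags:
            raise EmptyTagSetError(f"empty tag set in pair {self.origin!r}")
        if self.up_tags & self.down_tags:
            raise ConfigurationError(f"up/down tag sets overlap in pair {self.origin!r}")

    def swapped(self) -> "GeneSetPair":
        return GeneSetPair(self.down_tags, self.up_tags, origin=self.origin)


@dataclass
class RankedList:
    """Genes ordered most-up-regulated first, with their ranking statistic.

    Positions are 1-based. Construction does not re-sort; use
    :func:`ranked_list` to build one from a signature with the documented
    deterministic tie rule.
    """

    genes: np.ndarray
    stats: np.ndarray
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        if self.genes.shape != self.stats.shape:
            raise ConfigurationError("genes and stats differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError("duplicate genes in ranked list")
        self._pos = {g: i + 1 for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, tags: Sequence) -> np.ndarray:
        """Sorted 1-based positions of the tag genes present in the list."""
        pos = [self._pos[g] for g in tags if g in self._pos]
        return np.sort(np.asarray(pos, dtype=np.int64))

    def reversed(self) -> "RankedList":
        return RankedList(self.genes[::-1].copy(), self.stats[::-1].copy())


def _log_expression(mat: ExpressionMatrix, pseudocount: float) -> np.ndarray:
    if mat.is_log:
        return mat.data.to_numpy(dtype=float)
    counts = mat.data.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ConfigurationError("sample with zero total counts")
    cpm = counts / libsize * 1e6
    return np.log2(cpm + pseudocount)


def differential_signature(
    treated: ExpressionMatrix,
    control: ExpressionMatrix,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float = DEFAULT_PRIOR_DF,
    origin: str = "",
) -> DifferentialSignature:
    """Moderated-t contrast of treated vs control on log2-CPM values.

    Both matrices must cover the same gene universe (any order). With a single
    sample in either arm only ``log2fc`` is available; ``stat``/``p``/``q``
    are NaN. Zero-variance genes with zero difference get stat 0 / p 1; a
    nonzero difference over an exactly-zero standard error gets p 0.
    """
    if set(treated.gene_ids) != set(control.gene_ids):
        raise AlignmentError("treated and control matrices cover different gene universes")
    genes = treated.gene_ids
    control = ExpressionMatrix(control.data.loc[genes], control.groups, control.is_log)

    x1 = _log_expression(treated, pseudocount)
    x2 = _log_expression(control, pseudocount)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m1 - m2

    if n1 < 2 or n2 < 2:
        nan = np.full(len(genes), np.nan)
        table = pd.DataFrame(
            {"log2fc": log2fc, "stat": nan, "p": nan, "q": nan}, index=genes
        )
        return DifferentialSignature(table, origin=origin)

    df_resid = n1 + n2 - 2
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    prior_var = float(pooled.mean())
    shrunk = (prior_df * prior_var + df_resid * pooled) / (prior_df + df_resid)
    se = np.sqrt(shrunk * (1.0 / n1 + 1.0 / n2))

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        stat = np.where((se == 0) & (log2fc != 0), np.sign(log2fc) * np.inf, stat)
    df_total = df_resid + prior_df
    p = np.where(
        np.isinf(stat), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(stat), 0.0, stat)), df_total)
    )
    q = bh_adjust(p)
    table = pd.DataFrame({"log2fc": log2fc, "stat": stat, "p": p, "q": q}, index=genes)
    return DifferentialSignature(table, origin=origin)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values over one family."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _ordered_by_stat(sig: DifferentialSignature) -> pd.DataFrame:
    """Rows sorted by stat descending, ties broken by ascending gene id."""
    tab = sig.table.copy()
    tab["_gene"] = tab.index
    tab = tab.sort_values(["stat", "_gene"], ascending=[False, True], kind="mergesort")
    return tab.drop(columns="_gene")


def signature_gene_sets(
    sig: DifferentialSignature,
    *,
    n_top: int | None = None,
    q_cutoff: float | None = None,
) -> GeneSetPair:
    """Extract the up/down tag sets, by size or by FDR cutoff.

    Size mode takes the ``n_top`` genes with the largest moderated statistic
    as up-tags and the ``n_top`` smallest as down-tags (``n_top`` may not
    exceed half the universe, so the sets are disjoint by construction).
    Cutoff mode takes genes with q strictly below ``q_cutoff``, split by the
    sign of log2fc; an empty side raises :class:`EmptyTagSetError` so the
    caller decides the fallback.
    """
    if (n_top is None) == (q_cutoff is None):
        raise ConfigurationError("specify exactly one of n_top / q_cutoff")
    if n_top is not None:
        n = len(sig.table)
        if n_top < 1 or n_top > n // 2:
            raise ConfigurationError(f"n_top must be in [1, {n // 2}] for {n} genes")
        ordered = _ordered_by_stat(sig)
        up = frozenset(ordered.index[:n_top])
        down = frozenset(ordered.index[-n_top:])
        return GeneSetPair(up, down, origin=sig.origin)
    hits = sig.table[sig.table["q"] < q_cutoff]
    up = frozenset(hits.index[hits["log2fc"] > 0])
    down = frozenset(hits.index[hits["log2fc"] < 0])
    if not up or not down:
        raise EmptyTagSetError(
            f"q < {q_cutoff} leaves an empty tag side "
            f"(up={len(up)}, down={len(down)}) for {sig.origin!r}"
        )
    return GeneSetPair(up, down, origin=sig.origin)


def ranked_list(sig: DifferentialSignature) -> RankedList:
    """All genes sorted by moderated statistic descending.

    Ties are broken by ascending gene identifier — a stable, documented rule
    so ranked lists are reproducible across platforms.
    """
    ordered = _ordered_by_stat(sig)
    return RankedList(ordered.index.to_numpy(), ordered["stat"].to_numpy())
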