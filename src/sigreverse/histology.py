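"""NAFLD activity score (NAS) arithmetic and cohort summaries.

NAS is the NASH-CRN composite: steatosis (0–3) + hepatocyte ballooning
(0–2) + lobular inflammation (0–3), range 0–8. Fibrosis stage (0–4) and
portal inflammation (0–3) are scored alongside but are never part of the
sum. Per-animal scores are integers; group-mean mode accepts fractional
components (published tables report fractional group means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

_RANGES = {
    "steatosis": (0.0, 3.0),
    "ballooning": (0.0, 2.0),
    "lobular_inflammation": (0.0, 3.0),
    "fibrosis_stage": (0.0, 4.0),
    "portal_inflammation": (0.0, 3.0),
}

NAS_COMPONENTS = ("steatosis", "ballooning", "lobular_inflammation")


@dataclass(frozen=True)
class HistologyScores:
    """Component scores for one animal (integer) or one group mean (real)."""

    steatosis: float
    ballooning: float
    lobular_inflammation: float
    fibrosis_stage: float | None = None
    portal_inflammation: float | None = None

    def validate(self, *, per_animal: bool = False) -> None:
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if not (lo <= value <= hi):
                raise ConfigurationError(
                    f"{name} = {value} outside its range [{lo:g}, {hi:g}]"
                )
            if per_animal and float(value) != int(value):
                raise ConfigurationError(f"{name} = {value} must be an integer per animal")


def nafld_activity_score(scores: HistologyScores, *, per_animal: bool = False) -> float:
    """NAS = steatosis + ballooning + lobular inflammation, in [0, 8]."""
    scores.validate(per_animal=per_animal)
    return float(scores.steatosis + scores.ballooning + scores.lobular_inflammation)


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float | None  # None when n < 2
    n: int


def group_summary(values) -> GroupSummary:
    """Mean, SEM (sample SD over √n), and n of per-animal values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InputError("no values to summarize")
    mean = float(arr.mean())
    if arr.size < 2:
        return GroupSummary(mean, None, int(arr.size))
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return GroupSummary(mean, sem, int(arr.size))


def score_table(
    animals: pd.DataFrame, *, by: str | None = None, per_animal: bool = True
) -> pd.DataFrame:
    """Per-animal NAS, optionally summarised per group.

    ``animals`` columns: steatosis, ballooning, lobular_inflammation and
    optionally fibrosis_stage / portal_inflammation, plus a grouping column
    when ``by`` is given. Returns per-animal NAS, or per-group mean/SEM/n of
    NAS and each component when grouped.
    """
    required = set(NAS_COMPONENTS)
    missing = required - set(animals.columns)
    if missing:
        raise InputError(f"missing columns: {sorted(missing)}")
    nas = []
    for row in animals.itertuples():
        scores = HistologyScores(
            steatosis=row.steatosis,
            ballooning=row.ballooning,
            lobular_inflammation=row.lobular_inflammation,
            fibrosis_stage=getattr(row, "fibrosis_stage", None),
            portal_inflammation=getattr(row, "portal_inflammation", None),
        )
        nas.append(nafld_activity_score(scores, per_animal=per_animal))
    out = animals.copy()
    out["nas"] = nas
    if by is None:
        return out
    if by not in out.columns:
        raise InputError(f"grouping column {by!r} not present")
    rows = []
    value_cols = [c for c in out.columns if c != by and pd.api.types.is_numeric_dtype(out[c])]
    for group, sub in out.groupby(by, sort=True):
        rec: dict = {by: group}
        for col in value_cols:
            summary = group_summary(sub[col].dropna())
            rec[f"{col}_mean"] = summary.mean
            rec[f"{col}_sem"] = summary.sem
            rec["n"] = summary.n
        rows.append(rec)
    return pd.DataFrame(rows)
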