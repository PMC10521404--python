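"""Scoring of the Mental Health Continuum - Short Form (MHC-SF).

The 14-item MHC-SF measures three well-being components: emotional
(hedonic; 3 items), social (5 items) and psychological (6 items, together
with social forming eudaimonic well-being). Each item asks how often a
symptom of well-being was experienced in the past month on a 6-point
frequency scale. Scoring here uses 0-5 numeric coding by default (never = 0
... every day = 5), which yields the conventional subscale maxima
15 / 25 / 30 and total 70; instruments coded 1-6 can be rescored via
``item_offset``.

The item-to-subscale map is configurable; the default follows the standard
MHC-SF ordering (items 1-3 emotional, 4-8 social, 9-14 psychological).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_SUBSCALE_MAP",
    "ITEM_COLUMNS",
    "WellbeingScores",
    "score_mhcsf",
    "score_table",
    "cronbach_alpha",
    "describe_cohort",
]

#: item numbers (1-based) per subscale, standard MHC-SF ordering
DEFAULT_SUBSCALE_MAP: dict[str, tuple[int, ...]] = {
    "emotional": (1, 2, 3),
    "social": (4, 5, 6, 7, 8),
    "psychological": (9, 10, 11, 12, 13, 14),
}

ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, 15)]

DIMENSIONS = ("emotional", "psychological", "social", "total")


@dataclass(frozen=True)
class WellbeingScores:
    subject_id: str
    emotional: int
    psychological: int
    social: int

    @property
    def total(self) -> int:
        return self.emotional + self.psychological + self.social


def _check_map(subscale_map: dict) -> dict[str, tuple[int, ...]]:
    sizes = {"emotional": 3, "social": 5, "psychological": 6}
    if set(subscale_map) != set(sizes):
        raise ValueError(f"subscale map must define exactly {sorted(sizes)}")
    items = [i for v in subscale_map.values() for i in v]
    if sorted(items) != list(range(1, 15)):
        raise ValueError("subscale map must partition items 1..14")
    for key, size in sizes.items():
        if len(subscale_map[key]) != size:
            raise ValueError(f"{key} subscale must have {size} items")
    return {k: tuple(v) for k, v in subscale_map.items()}


def score_mhcsf(
    items,
    subject_id: str = "",
    subscale_map: dict | None = None,
    item_range: tuple[int, int] = (0, 5),
    item_offset: int = 0,
) -> WellbeingScores:
    """Sum item responses into the three subscales and the total.

    ``items`` is the 14 responses in questionnaire order. ``item_offset`` is
    subtracted from every response before range-checking against
    ``item_range`` (use ``item_offset=1`` for raw 1-6 coding).
    """
    smap = _check_map(subscale_map or DEFAULT_SUBSCALE_MAP)
    arr = np.asarray(items, dtype=float)
    if arr.shape != (14,):
        raise ValueError(f"expected 14 item responses, got shape {arr.shape}")
    arr = arr - item_offset
    lo, hi = item_range
    for i, v in enumerate(arr, start=1):
        if not np.isfinite(v):
            raise ValueError(f"item {i} is missing or non-finite")
        if v != int(v) or not (lo <= v <= hi):
            raise ValueError(f"item {i} response {v} outside range [{lo}, {hi}]")
    arr = arr.astype(int)
    sums = {k: int(sum(arr[i - 1] for i in idx)) for k, idx in smap.items()}
    return WellbeingScores(
        subject_id=subject_id,
        emotional=sums["emotional"],
        psychological=sums["psychological"],
        social=sums["social"],
    )


def score_table(
    behavior: pd.DataFrame,
    subscale_map: dict | None = None,
    item_range: tuple[int, int] = (0, 5),
    item_offset: int = 0,
) -> pd.DataFrame:
    """Score a behavior table (``subject_id`` + ``item_01..item_14``)."""
    missing = [c for c in ITEM_COLUMNS if c not in behavior.columns]
    if missing:
        raise ValueError(f"behavior table missing item columns: {missing}")
    rows = []
    for _, rec in behavior.iterrows():
        s = score_mhcsf(
            rec[ITEM_COLUMNS].to_numpy(),
            subject_id=str(rec.get("subject_id", "")),
            subscale_map=subscale_map,
            item_range=item_range,
            item_offset=item_offset,
        )
        rows.append(
            {
                "subject_id": s.subject_id,
                "emotional": s.emotional,
                "psychological": s.psychological,
                "social": s.social,
                "total": s.total,
            }
        )
    return pd.DataFrame(rows)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, sample (n-1) variance convention.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    for an n_subjects x k item matrix.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def describe_cohort(
    scores: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptives and pairwise correlations for the cohort.

    Returns ``(descriptives, correlations)``: per-variable mean / sd /
    min-max, and the lower-triangular Pearson correlation table with
    two-sided p-value star flags (* p<0.05, ** p<0.01), mirroring the usual
    participant-information table layout.
    """
    df = scores.copy()
    if covariates is not None:
        cov = covariates.drop(columns=["sex"], errors="ignore")
        df = cov.merge(df, on="subject_id") if "subject_id" in df.columns else pd.concat(
            [cov.reset_index(drop=True), df.reset_index(drop=True)], axis=1
        )
    num = df.select_dtypes(include=[np.number])
    desc = pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
        }
    )
    cols = num.columns
    corr = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    n = len(num)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j > i:
                continue
            if a == b:
                corr.loc[a, b] = "1"
                continue
            if n < 3:
                corr.loc[a, b] = "n/a"
                continue
            x, y = num[a].to_numpy(), num[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                corr.loc[a, b] = "undefined"
                continue
            r, p = stats.pearsonr(x, y)
            corr.loc[a, b] = f"{r:.3f}{_stars(p)}"
    return desc, corr
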