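"""Monthly trend counting and normalization.

Category mention counts are aggregated per UTC calendar month and
normalized against the total monthly volume of the e-cigarette corpus,
so that category trends are read as shares of the overall discussion
rather than raw volume (which itself trends strongly over time).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import Post

__all__ = [
    "monthly_counts",
    "monthly_totals",
    "normalize_series",
    "category_share",
]


def _month_index(
    window: tuple[str, str] | None, observed: Sequence[pd.Period]
) -> pd.PeriodIndex:
    if window is not None:
        return pd.period_range(window[0], window[1], freq="M")
    if not len(observed):
        return pd.PeriodIndex([], freq="M")
    return pd.period_range(min(observed), max(observed), freq="M")


def _post_month(post: Post) -> pd.Period:
    # created_utc is UTC epoch seconds; tz-naive conversion is UTC wall time
    return pd.Timestamp(post.created_utc, unit="s").to_period("M")


def monthly_counts(
    posts: Iterable[Post],
    category_assignment: Mapping[str, Iterable[str]],
    window: tuple[str, str] | None = None,
    counting_mode: str = "posts",
    keyword_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-category monthly mention counts.

    ``category_assignment`` maps post_id -> categories mentioned. In the
    default ``posts`` counting mode a post increments each of its
    categories once regardless of keyword multiplicity; in ``mentions``
    mode it contributes its keyword occurrence total per category (which
    requires ``keyword_counts``: post_id -> {category: n}). Months inside
    the window with no posts appear with count 0; posts outside an
    explicit window are excluded with a warning.
    """
    if counting_mode not in ("posts", "mentions"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")
    if counting_mode == "mentions" and keyword_counts is None:
        raise ValueError("mentions mode requires keyword_counts")
    rows: list[tuple[pd.Period, str, int]] = []
    months_seen: list[pd.Period] = []
    n_excluded = 0
    window_idx = pd.period_range(window[0], window[1], freq="M") if window else None
    for post in posts:
        month = _post_month(post)
        if window_idx is not None and month not in window_idx:
            n_excluded += 1
            continue
        months_seen.append(month)
        for cat in category_assignment.get(post.post_id, ()):
            if counting_mode == "posts":
                rows.append((month, cat, 1))
            else:
                rows.append((month, cat, keyword_counts[post.post_id].get(cat, 0)))
    if n_excluded:
        warnings.warn(f"{n_excluded} posts outside the configured window excluded")
    idx = window_idx if window_idx is not None else _month_index(None, months_seen)
    if not rows:
        return pd.DataFrame(index=idx)
    df = pd.DataFrame(rows, columns=["month", "category", "n"])
    table = (
        df.pivot_table(index="month", columns="category", values="n", aggfunc="sum")
        .reindex(idx)
        .fillna(0)
        .astype(int)
    )
    table.index.name = "month"
    table.columns.name = None
    return table


def monthly_totals(
    posts: Iterable[Post], window: tuple[str, str] | None = None
) -> pd.Series:
    """Total post count per month over the window (0 for empty months)."""
    months = [_post_month(p) for p in posts]
    idx = _month_index(window, months)
    if months:
        s = pd.PeriodIndex(months, freq="M").value_counts()
    else:
        s = pd.Series(0, index=idx)
    out = s.reindex(idx).fillna(0).astype(int)
    out.index.name = "month"
    return out


def normalize_series(
    category_counts: pd.DataFrame, totals: pd.Series
) -> pd.DataFrame:
    """Proportion of total monthly volume per category.

    Month axes must coincide. Months with total 0 yield missing values,
    not zeros.
    """
    if not category_counts.index.equals(totals.index):
        raise ValueError("month axes of counts and totals are not aligned")
    denom = totals.astype(float).replace(0, np.nan)
    return category_counts.div(denom, axis=0)


def category_share(
    counts: Mapping[str, int],
    denominator: int | None = None,
    ndigits: int = 2,
    mode: str = "round",
) -> dict[str, float]:
    """Percentage share per category, ordered descending.

    ``denominator`` defaults to the sum of counts; pass the corpus size
    when categories are not mutually exclusive at post level. ``mode``
    controls display quantization: ``round`` (banker's rounding, the
    default) or ``truncate`` (toward zero).
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    denom = denominator if denominator is not None else sum(counts.values())
    if denom is None or denom <= 0:
        raise ValueError("denominator must be positive")
    if mode not in ("round", "truncate"):
        raise ValueError(f"unknown mode {mode!r}")
    scale = 10 ** ndigits

    def quantize(x: float) -> float:
        if mode == "round":
            return round(x, ndigits)
        return math.floor(x * scale) / scale

    shares = {cat: quantize(100.0 * c / denom) for cat, c in counts.items()}
    return dict(sorted(shares.items(), key=lambda kv: (-kv[1], kv[0])))
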