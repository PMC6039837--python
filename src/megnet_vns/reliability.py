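"""Test–retest reliability via the two-way-ANOVA intraclass correlation.

For a complete subjects x sessions table, a two-way ANOVA with subject and
session main effects gives

    ICC = (MS_b - MS_E) / (MS_b + (k - 1) * MS_E),

where ``MS_b`` is the between-subject mean square, ``MS_E`` the residual
mean square after removing both main effects, and ``k`` the session count.
This is the consistency form (ICC(3,1)): session-level offsets do not count
against reliability.  Ratings: poor (< 0.2), fair [0.2, 0.4), moderate
[0.4, 0.6), good [0.6, 0.8), excellent (>= 0.8).  Negative estimates are
reported as computed and rated poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ICCResult", "icc_two_way", "icc_rating"]

RATING_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (np.inf, "excellent"),
)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_between: float
    ms_error: float
    k: int
    rating: str


def icc_rating(icc: float) -> str:
    """Rating band of an ICC value (half-open intervals, lower edge inclusive)."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    for upper, name in RATING_BANDS:
        if icc < upper:
            return name
    raise AssertionError("unreachable")


def icc_two_way(values: np.ndarray) -> ICCResult:
    """Two-way-ANOVA consistency ICC of a complete subjects x sessions table."""
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2-D subjects x sessions table")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.isfinite(y).all():
        raise ValueError("table has missing or non-finite cells")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_sess = float(n * ((sess_means - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_sess

    ms_b = ss_subj / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_b + (k - 1) * ms_e
    if denom == 0:
        raise ValueError("degenerate table: no variance at all")
    icc = (ms_b - ms_e) / denom
    return ICCResult(icc=float(icc), ms_between=ms_b, ms_error=ms_e, k=k,
                     rating=icc_rating(float(icc)))
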