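"""Group-difference statistics.

Responder vs non-responder comparisons use a non-parametric two-way ANOVA
(factors: VNS response and sedation status) whose null distribution is built
by bootstrap resampling with replacement (default n = 10,000) of the
reduced-model residuals — chosen because equal-variance assumptions fail for
some graph measures.  The design is unbalanced and fit as a main-effects
model (Type II sums of squares); the interaction is omitted.

P-values over the nine features (three measures x three bands) are corrected
with the Benjamini–Hochberg false discovery rate at the 0.05 level.
Control-vs-patient-group comparisons use a two-sided rank-based location
test; see :func:`controls_vs_group_test` for the paired/unpaired distinction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bootstrap_two_way_anova",
    "fdr_adjust",
    "controls_vs_group_test",
]


def _rss(y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual sum of squares of columns of y against an orthonormal basis q."""
    fitted = q @ (q.T @ y)
    r = y - fitted
    return np.einsum("ij,ij->j", r, r)


def _orth(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q


def bootstrap_two_way_anova(
    y: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
    null: str = "residual",
) -> dict[str, float]:
    """Bootstrap p-values for the two main effects of an unbalanced two-way design.

    The observed F statistic of each factor comes from Type II sums of
    squares in the main-effects model ``y ~ A + B``.  Its null distribution
    is built by resampling with replacement under ``null``:

    * ``"residual"`` (default): resample the residuals of the reduced model
      that omits the factor of interest and add them back to the reduced fit;
    * ``"case"``: resample whole observations of the reduced-model null
      (reduced fit plus its own residual, rows drawn with replacement).

    ``p = (1 + #{F* >= F}) / (n_boot + 1)``.
    Returns ``{"p_a", "p_b", "F_a", "F_b"}``.
    """
    if null not in ("residual", "case"):
        raise ValueError("null must be 'residual' or 'case'")
    y = np.asarray(y, dtype=float).ravel()
    a = np.asarray(factor_a).ravel()
    b = np.asarray(factor_b).ravel()
    if not (y.size == a.size == b.size):
        raise ValueError("y and factors must have equal length")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; F statistic undefined")
    for f, name in ((a, "A"), (b, "B")):
        levels, counts = np.unique(f, return_counts=True)
        if levels.size != 2:
            raise ValueError(f"factor {name} must be binary")
        if counts.min() < 2:
            raise ValueError(f"factor {name} has a level with fewer than 2 observations")

    n = y.size
    da = (a == np.unique(a)[1]).astype(float)
    db = (b == np.unique(b)[1]).astype(float)
    ones = np.ones(n)
    x_full = _orth(np.column_stack([ones, da, db]))
    x_wo_a = _orth(np.column_stack([ones, db]))
    x_wo_b = _orth(np.column_stack([ones, da]))
    df_resid = n - 3

    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for key, x_red in (("a", x_wo_a), ("b", x_wo_b)):
        yc = y[:, None]
        rss_full = _rss(yc, x_full)[0]
        rss_red = _rss(yc, x_red)[0]
        f_obs = (rss_red - rss_full) / (rss_full / df_resid)

        fitted_red = x_red @ (x_red.T @ y)
        resid_red = y - fitted_red
        idx = rng.integers(0, n, size=(n, n_boot))
        if null == "residual":
            y_star = fitted_red[:, None] + resid_red[idx]
        else:  # case resampling within the reduced-model null
            y_star = fitted_red[idx] + resid_red[idx]
        rss_full_s = _rss(y_star, x_full)
        rss_red_s = _rss(y_star, x_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_star = (rss_red_s - rss_full_s) / (rss_full_s / df_resid)
        p = (1.0 + np.sum(f_star >= f_obs)) / (n_boot + 1.0)
        out[f"p_{key}"] = float(p)
        out[f"F_{key}"] = float(f_obs)
    return out


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up adjustment.

    Returns a frame with the raw p, the adjusted p (monotone, capped at 1),
    the BH critical value ``(i/m) * q`` of each ordered p-value, and the
    significance flag at adjusted < q.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    ranks = stats.rankdata(p, method="ordinal")
    crit = ranks / p.size * q
    return pd.DataFrame(
        {"p_raw": p, "p_fdr": p_adj, "bh_critical": crit, "significant": p_adj < q}
    )


def controls_vs_group_test(
    x_controls: np.ndarray,
    y_group: np.ndarray,
    paired: bool = False,
) -> float:
    """Two-sided rank-based test of a location difference between two samples.

    The default is the unpaired Wilcoxon rank-sum (Mann–Whitney) test with an
    exact null for small tie-free samples and the tie-corrected normal
    approximation otherwise.  A paired signed-rank mode exists but requires
    equal sample sizes — controls and patient groups differ in size, so the
    unpaired test is the meaningful comparison for them.
    """
    x = np.asarray(x_controls, dtype=float)
    y = np.asarray(y_group, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("all values tied across both samples; test undefined")
    if paired:
        if x.size != y.size:
            raise ValueError("paired signed-rank test requires equal sample sizes")
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)
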