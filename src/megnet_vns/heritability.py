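"""Twin-based variance-components heritability.

The phenotypic variance of a trait is decomposed as

    sigma_p^2 = sigma_g^2 + sigma_e^2,

additive genetic plus individual-specific environment (the AE model; no
shared-environment component, and environmental effects are taken as
uncorrelated among family members).  For a pedigree the trait covariance is

    Omega = 2*Phi * sigma_g^2 + I * sigma_e^2,

where 2*Phi is the expected-relatedness matrix: 1 for an MZ co-twin pair,
1/2 for DZ co-twins and full siblings, 0 across families, and 1 on the
diagonal.  Narrow-sense heritability is h^2 = sigma_g^2 / sigma_p^2.

Estimation is maximum likelihood with covariates as fixed effects: the
kinship matrix is eigendecomposed once, the likelihood is profiled over the
heritability ratio on [0, 1] (sigma_p^2 and the GLS fixed effects have
closed forms at each ratio), and a 1-D bounded search finds the optimum.
Significance uses a likelihood-ratio test of sigma_g^2 = 0 with the
boundary-corrected null mixture (1/2)*chi2_0 + (1/2)*chi2_1.  Traits are
normalised beforehand with a rank-based inverse-normal transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KinshipMatrix",
    "VarianceComponentsFit",
    "build_kinship",
    "inverse_normal_transform",
    "fit_variance_components",
    "lrt_h2",
    "estimate_h2",
    "covariate_design",
]


@dataclass
class KinshipMatrix:
    """The 2*Phi relatedness matrix for an ordered list of individuals."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("kinship matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("kinship diagonal must be 1 (non-inbred individuals)")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_kinship(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Construct 2*Phi from a FAM-like table.

    Expects columns ``family_id``, ``individual_id``, ``zygosity`` with
    zygosity in {MZ, DZ, NT}.  MZ co-twins get relatedness 1; any other two
    members of the same family (DZ co-twins, siblings) get 1/2; individuals
    from different families get 0.  A family's MZ-labelled members must form
    exactly one pair.
    """
    ids = pedigree["individual_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated individual ids in pedigree")
    n = len(ids)
    fam = pedigree["family_id"].astype(str).to_numpy()
    zyg = pedigree["zygosity"].astype(str).to_numpy()

    for f in np.unique(fam):
        n_mz = int(np.sum((fam == f) & (zyg == "MZ")))
        if n_mz not in (0, 2):
            raise ValueError(f"family {f!r} has {n_mz} MZ members; an MZ pair needs exactly 2")

    k = np.zeros((n, n))
    same_family = fam[:, None] == fam[None, :]
    k[same_family] = 0.5
    both_mz = (zyg[:, None] == "MZ") & (zyg[None, :] == "MZ") & same_family
    k[both_mz] = 1.0
    np.fill_diagonal(k, 1.0)
    return KinshipMatrix(values=k, ids=ids)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Ranks (ties get their mean rank) are mapped through
    ``(r - 3/8) / (n + 1/4)`` and then the standard-normal quantile function.
    Invariant under monotone re-scalings of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to transform")
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")
    if np.ptp(x) == 0:
        raise ValueError("all trait values identical; transform undefined")
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (x.size + 0.25))


@dataclass
class VarianceComponentsFit:
    """Result of one AE maximum-likelihood fit."""

    h2: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    loglik_null: float
    p_value: float
    beta: np.ndarray
    beta_p: np.ndarray
    covariate_variance_explained: float
    covariate_names: list[str]

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2


def _profile_loglik(h2: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Profiled ML log-likelihood at a fixed heritability ratio.

    Works in the kinship eigenbasis where the covariance is diagonal:
    ``d_i = h2 * lam_i + (1 - h2)`` up to the profiled scale sigma_p^2.
    Returns (loglik, beta, sigma_p2, XtDX_inv).
    """
    n = yt.size
    d = h2 * lam + (1.0 - h2)
    d = np.clip(d, 1e-12, None)
    xw = xt / d[:, None]
    xtdx = xt.T @ xw
    xtdy = xw.T @ yt
    beta = np.linalg.solve(xtdx, xtdy)
    resid = yt - xt @ beta
    rss_w = float(np.sum(resid**2 / d))
    sigma_p2 = max(rss_w / n, 1e-300)
    ll = -0.5 * (
        n * np.log(2.0 * np.pi * sigma_p2) + np.sum(np.log(d)) + n
    )
    return ll, beta, sigma_p2, np.linalg.inv(xtdx)


def fit_variance_components(
    trait: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    covariate_names: list[str] | None = None,
    tol: float = 1e-6,
) -> VarianceComponentsFit:
    """ML fit of ``y ~ N(X beta, 2*Phi*sigma_g^2 + I*sigma_e^2)``.

    ``covariates`` is the design without intercept (an intercept is added).
    Profile likelihood over h2 in [0, 1]; Wald p-values for the fixed
    effects; covariate variance explained is the covariates-only R^2.
    """
    y = np.asarray(trait, dtype=float).ravel()
    n = y.size
    if n != kinship.n:
        raise ValueError("trait length does not match kinship size")
    if covariates is None or np.size(covariates) == 0:
        x = np.ones((n, 1))
        names = ["intercept"]
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        x = np.column_stack([np.ones(n), c])
        names = ["intercept"] + (
            covariate_names
            if covariate_names is not None
            else [f"x{i}" for i in range(c.shape[1])]
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")

    lam, vec = np.linalg.eigh(kinship.values)
    if lam.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    yt = vec.T @ y
    xt = vec.T @ x

    neg = lambda h2: -_profile_loglik(h2, lam, yt, xt)[0]
    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": tol})
    h2_hat = float(res.x)
    # the bounded optimiser never evaluates the exact endpoints; snap if better
    for edge in (0.0, 1.0 - 1e-9):
        if neg(edge) < res.fun:
            h2_hat = edge if edge == 0.0 else 1.0
    h2_eval = min(h2_hat, 1.0 - 1e-9)
    ll, beta, sigma_p2, cov_unscaled = _profile_loglik(h2_eval, lam, yt, xt)
    ll0, *_ = _profile_loglik(0.0, lam, yt, xt)

    se = np.sqrt(np.clip(np.diag(cov_unscaled) * sigma_p2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    beta_p = 2.0 * stats.norm.sf(np.abs(z))

    # covariates-only R^2 (OLS of the trait on the fixed effects, no intercept term counted)
    if x.shape[1] > 1:
        bhat, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ bhat
        r2 = 1.0 - resid.var() / y.var()
    else:
        r2 = 0.0

    p = lrt_h2(ll, ll0)
    return VarianceComponentsFit(
        h2=h2_hat,
        sigma_g2=h2_hat * sigma_p2,
        sigma_e2=(1.0 - h2_hat) * sigma_p2,
        loglik=ll,
        loglik_null=ll0,
        p_value=p,
        beta=beta,
        beta_p=beta_p,
        covariate_variance_explained=float(max(r2, 0.0)),
        covariate_names=names,
    )


def lrt_h2(loglik_full: float, loglik_null: float, tol: float = 1e-6) -> float:
    """Boundary-corrected LRT p-value for sigma_g^2 = 0.

    ``Lambda = 2 * (ll_full - ll_null)``, clipped at zero;
    ``p = 0.5 * P(chi2_1 >= Lambda)`` (the null is the mixture
    (1/2)*chi2_0 + (1/2)*chi2_1 because h2 sits on the boundary).
    Lambda = 0 gives p = 0.5.
    """
    lam = 2.0 * (loglik_full - loglik_null)
    if lam < -tol * max(1.0, abs(loglik_null)):
        raise RuntimeError(
            f"full-model likelihood below null ({lam:.3g}); optimizer failure"
        )
    lam = max(lam, 0.0)
    return float(0.5 * stats.chi2.sf(lam, df=1))


def covariate_design(age: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Standard covariate block: sex, age, age^2, age*sex, age^2*sex.

    Age is centred (and age^2 computed from centred age) for conditioning;
    sex is a 0/1 indicator.
    """
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    ac = a - a.mean()
    x = np.column_stack([s, ac, ac**2, ac * s, ac**2 * s])
    return x, ["sex", "age", "age2", "age_sex", "age2_sex"]


def estimate_h2(
    trait: np.ndarray,
    age: np.ndarray | None,
    sex: np.ndarray | None,
    kinship: KinshipMatrix,
    transform: bool = True,
    residualize_first: bool = False,
) -> VarianceComponentsFit:
    """Convenience wrapper: inverse-normal transform, covariate block, ML fit.

    Default order is transform-then-fit with covariates as fixed effects
    inside the ML model; ``residualize_first=True`` instead regresses the
    covariates out by OLS before the (transformed) variance-components fit.
    """
    y = inverse_normal_transform(trait) if transform else np.asarray(trait, float)
    if age is None or sex is None:
        return fit_variance_components(y, None, kinship)
    x, names = covariate_design(age, sex)
    if residualize_first:
        design = np.column_stack([np.ones(y.size), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return fit_variance_components(y - design @ beta, None, kinship)
    return fit_variance_components(y, x, kinship, covariate_names=names)
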