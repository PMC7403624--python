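"""Broad- and narrow-sense heritability with jackknife standard errors.

Broad-sense H2 comes from a one-way random-effects model on replicate
measurements (segregant as the random group effect), fit by REML through a
closed-form per-group profile likelihood.  Narrow-sense h2 comes from a
single-variance-component mixed model y = mu + u + e with u ~ (0, K sigmaA2)
on a marker-derived additive relationship matrix K, fit by REML via one
eigendecomposition of K and a one-dimensional optimisation over the variance
ratio (the EMMA-style profile).  Variance components are clamped at zero, so
both heritabilities live in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .simulate import GenotypeMatrix

__all__ = [
    "H2Estimate",
    "H2Result",
    "estimate_H2",
    "compute_kinship",
    "estimate_h2",
    "jackknife_se",
]


@dataclass
class H2Estimate:
    H2: float
    sigma_G2: float
    sigma_E2: float
    n_segregants_used: int


@dataclass
class H2Result:
    """Narrow-sense estimate (named for symmetry with :class:`H2Estimate`)."""
    h2: float
    sigma_A2: float
    sigma_EV2: float
    n_segregants_used: int


# ---------------------------------------------------------------------------
# broad-sense H2: one-way random-effects REML
# ---------------------------------------------------------------------------

def _oneway_reml_criterion(gamma: float, n_i: np.ndarray, s_i: np.ndarray,
                           ss: float, N: int) -> tuple[float, float]:
    """-2 REML log-likelihood (profiled over sigmaE2) for variance ratio gamma.

    gamma = sigmaG2/sigmaE2.  Uses per-group sizes n_i, sums s_i and the total
    sum of squares ss = sum(y^2).  Returns (criterion, sigmaE2_hat).
    """
    denom = 1.0 + n_i * gamma
    C = np.sum(n_i / denom)
    lin = np.sum(s_i / denom)
    quad = ss - gamma * np.sum(s_i ** 2 / denom)
    mu = lin / C
    Q = quad - mu ** 2 * C
    Q = max(Q, 1e-300)
    sigmaE2 = Q / (N - 1)
    crit = (N - 1) * np.log(sigmaE2) + np.sum(np.log(denom)) + np.log(C)
    return crit, sigmaE2


def estimate_H2(replicate_values: np.ndarray, min_groups: int = 10) -> H2Estimate:
    """Broad-sense heritability from replicate measurements.

    ``replicate_values`` is (n_segregants, n_replicates) with NaN for missing;
    only segregants with >=2 non-missing replicates enter the model
    y_ij = mu + g_i + e_ij (REML).  H2 = sigmaG2/(sigmaG2+sigmaE2), with the
    ratio clamped at zero.
    """
    Y = np.atleast_2d(np.asarray(replicate_values, dtype=float))
    ok = np.isfinite(Y)
    use = ok.sum(axis=1) >= 2
    if not use.any():
        raise ValueError("no segregant has >=2 replicates; H2 undefined")
    if use.sum() < min_groups:
        raise ValueError(f"need >={min_groups} segregants with >=2 replicates, "
                         f"got {int(use.sum())}")
    Y, ok = Y[use], ok[use]
    n_i = ok.sum(axis=1).astype(float)
    s_i = np.where(ok, Y, 0.0).sum(axis=1)
    ss = float(np.nansum(Y ** 2))
    N = int(n_i.sum())

    def crit(log_gamma: float) -> float:
        return _oneway_reml_criterion(np.exp(log_gamma), n_i, s_i, ss, N)[0]

    res = minimize_scalar(crit, bounds=(-18.0, 18.0), method="bounded",
                          options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))
    c0, _ = _oneway_reml_criterion(0.0, n_i, s_i, ss, N)
    if c0 <= res.fun:  # boundary solution: no between-segregant variance
        gamma = 0.0
    _, sigmaE2 = _oneway_reml_criterion(gamma, n_i, s_i, ss, N)
    sigmaG2 = gamma * sigmaE2
    H2 = sigmaG2 / (sigmaG2 + sigmaE2) if (sigmaG2 + sigmaE2) > 0 else 0.0
    return H2Estimate(float(H2), float(sigmaG2), float(sigmaE2), int(use.sum()))


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def compute_kinship(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Additive relationship matrix from haploid {0,1} marker codes.

    Missing genotypes are mean-imputed per marker; monomorphic markers are
    dropped.  K = Z Z' / sum_j p_j (1-p_j) with Z the column-centred codes,
    the haploid analogue of the VanRaden normalisation, so the mean diagonal
    is ~1 and sigmaA2 in the mixed model is on the phenotypic-variance scale.
    """
    X = genotypes.imputed() if isinstance(genotypes, GenotypeMatrix) \
        else np.asarray(genotypes, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two markers")
    p = X.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    Xp = X[:, poly]
    pq = (Xp.var(axis=0)).sum()  # = sum p(1-p) for {0,1} codes
    Z = Xp - Xp.mean(axis=0)
    return (Z @ Z.T) / pq


# ---------------------------------------------------------------------------
# narrow-sense h2: kinship mixed model REML
# ---------------------------------------------------------------------------

def _h2_reml_criterion(delta: float, d: np.ndarray, yt: np.ndarray,
                       xt: np.ndarray) -> tuple[float, float]:
    """-2 REML log-likelihood (profiled over sigmaA2) at ratio delta = sEV2/sA2.

    Works in the eigenbasis of K: d eigenvalues, yt = U'y, xt = U'1.
    Returns (criterion, sigmaA2_hat).
    """
    v = d + delta
    C = np.sum(xt ** 2 / v)
    lin = np.sum(xt * yt / v)
    Q = np.sum(yt ** 2 / v) - lin ** 2 / C
    Q = max(Q, 1e-300)
    n = d.size
    sigmaA2 = Q / (n - 1)
    crit = (n - 1) * np.log(sigmaA2) + np.sum(np.log(v)) + np.log(C)
    return crit, sigmaA2


def estimate_h2(y: np.ndarray, kinship: np.ndarray,
                eig: tuple[np.ndarray, np.ndarray] | None = None,
                psd_tol: float = 1e-8) -> H2Result:
    """Narrow-sense heritability from segregant trait means and kinship.

    Fits y = mu + u + e with u ~ (0, K sigmaA2), e ~ (0, I sigmaEV2) by REML,
    optimising the ratio delta = sigmaEV2/sigmaA2 on the eigenbasis of K.
    h2 = sigmaA2/(sigmaA2+sigmaEV2) = 1/(1+delta).  Pass ``eig`` (values,
    vectors) to reuse one eigendecomposition across traits.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite (drop missing upstream)")
    n = y.size
    if kinship.shape != (n, n):
        raise ValueError("kinship must be square and aligned with y")
    if eig is None:
        d, U = np.linalg.eigh(kinship)
        if d.min() < -psd_tol * max(d.max(), 1.0):
            raise ValueError("kinship is not positive semidefinite within tolerance")
        eig = (np.clip(d, 0.0, None), U)
    d, U = eig
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def crit(log_delta: float) -> float:
        return _h2_reml_criterion(np.exp(log_delta), d, yt, xt)[0]

    res = minimize_scalar(crit, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-10})
    delta = float(np.exp(res.x))
    # boundary checks: all-genetic (delta -> 0) / all-noise (delta -> inf)
    for b, dl in ((crit(-14.0), np.exp(-14.0)), (crit(14.0), np.exp(14.0))):
        if b < res.fun:
            delta = dl
    _, sigmaA2 = _h2_reml_criterion(delta, d, yt, xt)
    sigmaEV2 = delta * sigmaA2
    h2 = 1.0 / (1.0 + delta)
    if np.exp(-13.5) > delta:
        h2 = 1.0
    elif delta > np.exp(13.5):
        h2 = 0.0
    return H2Result(float(h2), float(sigmaA2), float(sigmaEV2), n)


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife_se(estimator, n: int) -> tuple[float, np.ndarray]:
    """Delete-one jackknife standard error over segregants.

    ``estimator(keep_idx)`` must return the statistic computed on the
    segregant subset ``keep_idx``.  SE = sqrt((n-1)/n * sum_i (theta_-i -
    mean)^2).  Leave-one-out failures are skipped with a warning and the SE is
    computed over the successes.
    """
    if n < 3:
        raise ValueError("jackknife needs n >= 3")
    thetas, failures = [], []
    idx = np.arange(n)
    for i in range(n):
        try:
            thetas.append(float(estimator(idx[idx != i])))
        except Exception as exc:  # noqa: BLE001 - estimator may fail per subset
            failures.append((i, repr(exc)))
    if failures:
        warnings.warn(f"jackknife estimator failed on {len(failures)} subsets; "
                      f"SE computed on {len(thetas)} successes")
    thetas = np.asarray(thetas)
    k = thetas.size
    if k < 2:
        raise ValueError("too few successful leave-one-out estimates")
    se = np.sqrt((k - 1) / k * np.sum((thetas - thetas.mean()) ** 2))
    return float(se), thetas
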