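"""Genome scans and stepwise forward QTL search.

The scan statistic is LOD = -n ln(1 - r^2) / (2 ln 10) with r the Pearson
correlation between marker allele code and trait value.  Forward search runs
in escalating-threshold rounds (defaults 2.68 / 2.92 / 3.72 / 4.9, the 5%-FDR
thresholds of the BY x RM panel): within a round, the single best marker is
added to the joint linear model and the residuals rescanned until no marker
clears the round's threshold.  After all rounds the joint model of the
selected markers is refit for per-QTL effects, signs and the joint variance
explained (squared multiple correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "DEFAULT_LOD_THRESHOLDS",
    "lod_from_r",
    "lod_scan",
    "forward_search",
    "calibrate_fdr_thresholds",
    "effect_sign_summary",
    "QTLResult",
]

DEFAULT_LOD_THRESHOLDS: tuple[float, ...] = (2.68, 2.92, 3.72, 4.9)


def lod_from_r(r: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """LOD score from a marker-trait Pearson correlation at sample size n."""
    r2 = np.clip(np.asarray(r, dtype=float) ** 2, 0.0, 1.0 - 1e-15)
    return -np.asarray(n, dtype=float) * np.log1p(-r2) / (2.0 * np.log(10.0))


@dataclass
class QTLResult:
    """Ordered detected QTLs for one trait plus the joint-model summary."""

    trait: str
    qtls: pd.DataFrame  # marker, marker_index, chromosome, position_cM, round,
    #                     lod_at_selection, effect, sign
    joint_R2: float
    n_used: int

    @property
    def n_qtl(self) -> int:
        return len(self.qtls)


def _pairwise_complete_r(y: np.ndarray, X: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of X with y on pairwise-complete rows."""
    M = np.isfinite(X) & np.isfinite(y)[:, None]
    Xz = np.where(M, X, 0.0)
    Yz = np.where(M, y[:, None], 0.0)
    n = M.sum(axis=0).astype(float)
    sx, sy = Xz.sum(axis=0), Yz.sum(axis=0)
    sxx, syy = (Xz ** 2).sum(axis=0), (Yz ** 2).sum(axis=0)
    sxy = (Xz * Yz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx ** 2
        vary = n * syy - sy ** 2
        r = cov / np.sqrt(varx * vary)
    r = np.where((varx > 1e-12) & (vary > 1e-12), r, 0.0)
    return r, n


def lod_scan(y: np.ndarray, genotypes: GenotypeMatrix | np.ndarray,
             marker_names=None) -> pd.DataFrame:
    """Per-marker correlation and LOD score for one trait.

    Correlations use pairwise-complete observations; monomorphic markers get
    r = 0, LOD = 0 and a flag.  A zero-variance trait yields an all-zero scan
    with a warning.
    """
    if isinstance(genotypes, GenotypeMatrix):
        X = genotypes.codes
        marker_names = genotypes.marker_map.marker
    else:
        X = np.asarray(genotypes, dtype=float)
        if marker_names is None:
            marker_names = [f"m{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >=3 segregants with non-missing trait values")
    if np.nanvar(y) < 1e-15:
        warnings.warn("zero-variance trait: all LOD scores are 0")

    r, n = _pairwise_complete_r(y, X)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(X, axis=0)
    mono = (freq <= 0.0) | (freq >= 1.0) | (np.nanvar(X, axis=0) < 1e-12)
    r = np.where(mono, 0.0, r)
    return pd.DataFrame({
        "marker": marker_names, "r": r, "LOD": lod_from_r(r, n),
        "n": n.astype(int), "monomorphic": mono,
    })


def _joint_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS of y on [1, X]; returns (coefs for X, residuals, R^2)."""
    D = np.column_stack([np.ones(y.size), X]) if X.size else np.ones((y.size, 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    fit = D @ beta
    resid = y - fit
    tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / tot if tot > 0 else 0.0
    return beta[1:], resid, float(r2)


def forward_search(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    thresholds=DEFAULT_LOD_THRESHOLDS,
    redundancy_window_cM: float = 10.0,
    trait: str = "trait",
) -> QTLResult:
    """Four-round (by default) stepwise forward QTL search.

    Round k rescans the residuals of the joint model of all selected markers
    and keeps adding the single highest-LOD marker while it clears
    ``thresholds[k]``; markers within ``redundancy_window_cM`` of a marker
    added in the same round are not candidates again that round.  Missing
    genotypes are mean-imputed for model fitting; segregants with missing
    trait values are excluded throughout.
    """
    thresholds = list(thresholds)
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("need at least one positive LOD threshold")
    mm = genotypes.marker_map
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    yv = y[ok]
    X = genotypes.imputed()[ok]
    n = yv.size
    if n < 3:
        raise ValueError("need >=3 segregants with non-missing trait values")

    # X is imputed and yv complete, so the scan is one GEMM on standardised codes
    Xc = X - X.mean(axis=0)
    xsd = Xc.std(axis=0)
    zero_var = xsd < 1e-12
    xsd[zero_var] = 1.0
    Xs = Xc / xsd

    selected: list[int] = []
    records: list[dict] = []
    for rnd, thr in enumerate(thresholds, start=1):
        round_block = np.zeros(mm.n_markers, dtype=bool)
        while True:
            _, resid, _ = _joint_fit(yv, X[:, selected])
            rc = resid - resid.mean()
            rsd = rc.std()
            r = (Xs.T @ rc) / (n * rsd) if rsd > 1e-12 else np.zeros(mm.n_markers)
            r[zero_var] = 0.0
            lod = np.asarray(lod_from_r(r, n))
            lod[selected] = -np.inf
            lod[round_block] = -np.inf
            best = int(np.argmax(lod))
            if lod[best] < thr:
                break
            cand = X[:, selected + [best]]
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), cand])) \
                    < len(selected) + 2:
                warnings.warn(f"marker {mm.marker[best]} collinear with selected "
                              "markers; skipped")
                round_block[best] = True
                continue
            selected.append(best)
            near = (mm.chromosome == mm.chromosome[best]) & \
                (np.abs(mm.position_cM - mm.position_cM[best])
                 <= redundancy_window_cM)
            round_block |= near
            records.append({"marker": mm.marker[best], "marker_index": best,
                            "chromosome": int(mm.chromosome[best]),
                            "position_cM": float(mm.position_cM[best]),
                            "round": rnd, "lod_at_selection": float(lod[best])})

    effects, _, joint_r2 = _joint_fit(yv, X[:, selected])
    qtls = pd.DataFrame(records, columns=["marker", "marker_index", "chromosome",
                                          "position_cM", "round",
                                          "lod_at_selection"])
    qtls["effect"] = effects if len(records) else np.empty(0)
    qtls["sign"] = np.where(qtls["effect"] >= 0, "+", "-") if len(records) else \
        np.empty(0, dtype=object)
    return QTLResult(trait=trait, qtls=qtls,
                     joint_R2=joint_r2 if selected else 0.0, n_used=n)


def calibrate_fdr_thresholds(
    traits: np.ndarray,
    genotypes: GenotypeMatrix,
    n_perm: int = 100,
    target_fdr: float = 0.05,
    n_rounds: int = 4,
    seed: int | np.random.Generator = 0,
) -> list[float]:
    """Permutation-FDR LOD thresholds, one per forward-search round.

    For each round, phenotype residuals (on the markers selected in earlier
    rounds) are scanned against all markers, and segregant labels of the
    residuals are permuted ``n_perm`` times to build the null.  The round's
    threshold is the smallest LOD t at which

        mean permuted count of (trait, marker) scans >= t
        ------------------------------------------------  <= target_fdr.
        observed count of (trait, marker) scans >= t

    If no t achieves this the round's threshold is +inf (no detections).
    """
    rng = np.random.default_rng(seed)
    Y = np.atleast_2d(np.asarray(traits, dtype=float))
    if Y.ndim != 2:
        raise ValueError("traits must be (n_segregants, n_traits)")
    n, T = Y.shape
    if T < 5:
        raise ValueError("need >=5 traits to calibrate")
    if n_perm < 10:
        raise ValueError("need n_perm >= 10")
    X = genotypes.imputed()
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xs / sd

    def scan_all(R: np.ndarray) -> np.ndarray:
        # columns of R standardized -> correlation matrix via one GEMM
        Rc = R - R.mean(axis=0)
        rs = Rc.std(axis=0)
        rs[rs == 0] = 1.0
        corr = (Xs.T @ (Rc / rs)) / n  # (m, T)
        return np.asarray(lod_from_r(corr, n))

    selected: list[list[int]] = [[] for _ in range(T)]
    thresholds: list[float] = []
    for rnd in range(n_rounds):
        resid = np.empty_like(Y)
        for t in range(T):
            _, resid[:, t], _ = _joint_fit(Y[:, t], X[:, selected[t]])
        obs = scan_all(resid)
        perm_counts = []
        for _ in range(n_perm):
            perm = rng.permutation(n)
            perm_counts.append(scan_all(resid[perm]))
        cand = np.unique(obs[obs > 0])[::-1]
        thr = np.inf
        perm_all = np.concatenate([p.ravel() for p in perm_counts])
        obs_all = np.sort(obs.ravel())
        perm_sorted = np.sort(perm_all)
        for t_cand in cand:
            n_obs = obs_all.size - np.searchsorted(obs_all, t_cand, side="left")
            n_perm_mean = (perm_sorted.size
                           - np.searchsorted(perm_sorted, t_cand, side="left")) \
                / n_perm
            if n_obs > 0 and n_perm_mean / n_obs <= target_fdr:
                thr = float(t_cand)
            else:
                break
        thresholds.append(thr)
        if np.isinf(thr):
            continue
        # apply this round's threshold: forward additions per trait
        for t in range(T):
            while True:
                _, res_t, _ = _joint_fit(Y[:, t], X[:, selected[t]])
                r, nn = _pairwise_complete_r(res_t, X)
                lod = np.asarray(lod_from_r(r, n))
                lod[selected[t]] = -np.inf
                best = int(np.argmax(lod))
                if lod[best] < thr:
                    break
                selected[t].append(best)
    return thresholds


def effect_sign_summary(results: list[QTLResult]) -> tuple[pd.DataFrame, dict]:
    """Per-trait counts of +/- QTL effects and the mixed-sign fraction.

    The sign is that of the fitted joint-model coefficient of the parent-B
    allele code.  A trait is "mixed" when both signs occur among its QTLs.
    The summary reports the mixed fraction among traits with >=1 QTL and among
    multi-QTL (>=2) traits.
    """
    with_qtl = [r for r in results if r.n_qtl >= 1]
    if not with_qtl:
        raise ValueError("no result has any QTLs")
    rows = []
    for r in with_qtl:
        pos = int((r.qtls["sign"] == "+").sum())
        neg = int((r.qtls["sign"] == "-").sum())
        rows.append({"trait": r.trait, "n_qtl": r.n_qtl, "n_positive": pos,
                     "n_negative": neg, "mixed": pos > 0 and neg > 0})
    tab = pd.DataFrame(rows)
    multi = tab[tab["n_qtl"] >= 2]
    summary = {
        "mixed_fraction": float(tab["mixed"].mean()),
        "mixed_fraction_multi_qtl": float(multi["mixed"].mean()) if len(multi)
        else float("nan"),
        "n_traits_with_qtl": len(tab),
    }
    return tab, summary
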