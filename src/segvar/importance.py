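"""Trait evolutionary-importance indices and exemplar-trait clustering.

RTGR (relatedness to growth rate) is the absolute Pearson correlation between
a trait's segregant means and the segregants' growth rates; 1-CV of the
technical-control replicates is the complementary importance proxy.  Traits
are categorised by the CalMorph naming convention (channel by initial letter,
cell-cycle stage by the suffix after the connector) and reduced to exemplar
traits by affinity propagation on negative squared Euclidean distances
between trait profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "compute_rtgr",
    "ExemplarClustering",
    "cluster_exemplars",
    "categorize_trait",
    "correlate_h2_importance",
]

STAGE_TOKENS = ("A", "A1B", "B", "C")


def compute_rtgr(trait_means: pd.DataFrame | np.ndarray,
                 growth: np.ndarray | pd.Series) -> pd.DataFrame:
    """|Pearson r| between each trait's segregant means and growth rate.

    Pairwise-complete observations; traits with <3 complete pairs or zero
    variance are flagged with RTGR = NaN.
    """
    X = np.asarray(trait_means, dtype=float)
    names = (trait_means.columns if isinstance(trait_means, pd.DataFrame)
             else [f"trait{j}" for j in range(X.shape[1])])
    g = np.asarray(growth, dtype=float)
    if g.size != X.shape[0]:
        raise ValueError("growth vector must align with trait-mean rows")
    out = np.full(X.shape[1], np.nan)
    flagged = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        ok = np.isfinite(X[:, j]) & np.isfinite(g)
        if ok.sum() < 3 or np.var(X[ok, j]) < 1e-15 or np.var(g[ok]) < 1e-15:
            flagged[j] = True
            continue
        out[j] = abs(stats.pearsonr(X[ok, j], g[ok])[0])
    if flagged.any():
        warnings.warn(f"RTGR undefined for {int(flagged.sum())} traits")
    return pd.DataFrame({"trait": names, "RTGR": out, "undefined": flagged})


@dataclass
class ExemplarClustering:
    exemplar_indices: np.ndarray   # indices into the trait axis
    labels: np.ndarray             # cluster id per trait
    exemplar_of: np.ndarray        # trait index of each trait's exemplar
    converged: bool
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return self.exemplar_indices.size

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def cluster_exemplars(
    trait_means: pd.DataFrame | np.ndarray,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 100,
    random_state: int = 0,
) -> ExemplarClustering:
    """Affinity-propagation exemplars over trait profiles.

    Traits are the clustered items; the profile of a trait is its vector of
    segregant means.  Similarity s(i,k) = -||x_i - x_k||^2 (negative squared
    Euclidean distance); the self-preference defaults to the median similarity.
    Non-convergence returns the best-effort single-cluster assignment with a
    flag rather than raising.
    """
    X = np.asarray(trait_means, dtype=float).T  # traits x segregants
    if X.shape[0] < 1:
        raise ValueError("need at least one trait")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    if X.shape[0] == 1:
        return ExemplarClustering(np.array([0]), np.array([0]), np.array([0]),
                                  True, 0)
    pref = None if preference == "median" else float(preference)
    ap = AffinityPropagation(damping=damping, max_iter=max_iter,
                             convergence_iter=convergence_iter,
                             preference=pref, affinity="euclidean",
                             random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        ap.fit(X)
    centers = np.asarray(ap.cluster_centers_indices_)
    converged = centers.size > 0 and ap.n_iter_ < max_iter
    if centers.size == 0:  # did not converge to any exemplar set
        medoid = int(np.argmin(((X[:, None, :] - X[None, :, :]) ** 2)
                               .sum(-1).sum(1)))
        return ExemplarClustering(np.array([medoid]),
                                  np.zeros(X.shape[0], dtype=int),
                                  np.full(X.shape[0], medoid), False,
                                  int(ap.n_iter_))
    labels = np.asarray(ap.labels_)
    return ExemplarClustering(centers, labels, centers[labels], converged,
                              int(ap.n_iter_))


def categorize_trait(name: str) -> tuple[str, str]:
    """(channel, stage) from a CalMorph-style trait name.

    Channel: initial letter "C" -> cell_wall, "D" -> nucleus.  Stage: the
    token after the final "_" when it is one of A (unbudded, one nucleus),
    A1B (budded, one nucleus in the mother or dividing at the neck), B
    (budded, one nucleus at/through the neck) or C (one nucleus each in
    mother and bud); anything else -> "unassigned".
    """
    if not name:
        raise ValueError("trait name must be non-empty")
    first = name[0].upper()
    if first == "C":
        channel = "cell_wall"
    elif first == "D":
        channel = "nucleus"
    else:
        channel = "unassigned"
        warnings.warn(f"unknown channel letter in trait name {name!r}")
    stage = name.rsplit("_", 1)[1] if "_" in name else ""
    if stage not in STAGE_TOKENS:
        stage = "unassigned"
    return channel, stage


def correlate_h2_importance(
    h2: np.ndarray | pd.Series,
    importance: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlation between heritability and an importance index.

    Returns one row per group (plus an "all" row when groups are given) with
    (group, n, pearson_r, p_value).  Non-finite pairs are dropped; groups with
    a constant vector or fewer than ``min_n`` pairs get NaN and are reported.
    """
    h2 = np.asarray(h2, dtype=float)
    imp = np.asarray(importance, dtype=float)
    if h2.size != imp.size:
        raise ValueError("h2 and importance must align")

    def one(mask: np.ndarray) -> tuple[int, float, float]:
        ok = mask & np.isfinite(h2) & np.isfinite(imp)
        n = int(ok.sum())
        if n < min_n or np.var(h2[ok]) < 1e-15 or np.var(imp[ok]) < 1e-15:
            return n, np.nan, np.nan
        r, p = stats.pearsonr(h2[ok], imp[ok])
        return n, float(r), float(p)

    rows = []
    n, r, p = one(np.ones(h2.size, dtype=bool))
    rows.append({"group": "all", "n": n, "pearson_r": r, "p_value": p})
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            n, r, p = one(groups == g)
            rows.append({"group": str(g), "n": n, "pearson_r": r, "p_value": p})
    out = pd.DataFrame(rows)
    if out["pearson_r"].isna().any():
        warnings.warn("correlation undefined for some groups (constant or small)")
    return out
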