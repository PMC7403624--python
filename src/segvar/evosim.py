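"""Population-genetic simulators for the birth-death cycle of additive variance.

Three scenarios:

* ``wf_trajectory`` / ``wf_fixation_probability`` - classical Wright-Fisher
  binomial resampling with deterministic selection each generation (haploid or
  diploid), with Kimura diffusion formulas as analytic companions.
* ``simulate_depletion`` - the death process: a segregant-like haploid panel
  with an additive trait under truncation (or fitness-proportional) selection,
  random mating with recombination, tracking V_A, V_NonA and h2 per generation.
* ``simulate_birth_cycle`` - the birth process: two demes seeded with disjoint
  rare beneficial variants of matched magnitude, additive versus pairwise-
  epistatic, evolve under directional selection; admixing the demes and
  crossing for one generation shows where hybrid additive variance comes from.

The variance decomposition used throughout regresses phenotype (or the
noiseless genetic values) on allele dosages: V_A is the variance of the best
additive fit, V_NonA the remaining genetic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WFTrajectory",
    "wf_trajectory",
    "wf_fixation_probability",
    "diffusion_fixation_probability",
    "diffusion_conditional_fixation_time",
    "VarianceDecomposition",
    "decompose_variance",
    "EvoSimResult",
    "simulate_depletion",
    "simulate_birth_cycle",
    "BirthCycleResult",
]


# ---------------------------------------------------------------------------
# Wright-Fisher single locus
# ---------------------------------------------------------------------------

def _selection_update(p: np.ndarray, s: float, dominance: float,
                      ploidy: str) -> np.ndarray:
    """Deterministic change in allele frequency due to selection."""
    if s == 0.0:
        return p
    if ploidy == "haploid":
        return p * (1.0 + s) / (1.0 + s * p)
    q = 1.0 - p
    wbar = p ** 2 * (1 + s) + 2 * p * q * (1 + dominance * s) + q ** 2
    return (p ** 2 * (1 + s) + p * q * (1 + dominance * s)) / wbar


@dataclass
class WFTrajectory:
    fixed: bool | None          # True fixed, False lost, None unabsorbed at cap
    generations_to_absorption: int
    trajectory: np.ndarray


def wf_trajectory(N: int, s: float, p0: float, dominance: float = 0.5,
                  ploidy: str = "haploid", max_generations: int | None = None,
                  seed: int | np.random.Generator = 0) -> WFTrajectory:
    """One Wright-Fisher trajectory run to absorption (or a generation cap)."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    n_gam = N if ploidy == "haploid" else 2 * N
    cap = max_generations if max_generations is not None else 100 * N
    p = p0
    traj = [p]
    for g in range(1, cap + 1):
        p = rng.binomial(n_gam, _selection_update(np.asarray(p), s, dominance,
                                                  ploidy)) / n_gam
        traj.append(float(p))
        if p in (0.0, 1.0):
            return WFTrajectory(p == 1.0, g, np.asarray(traj))
    warnings.warn("generation cap reached before absorption")
    return WFTrajectory(None, cap, np.asarray(traj))


def wf_fixation_probability(N: int, s: float, p0: float, n_runs: int,
                            dominance: float = 0.5, ploidy: str = "haploid",
                            max_generations: int | None = None,
                            seed: int | np.random.Generator = 0
                            ) -> tuple[float, float]:
    """Monte-Carlo fixation probability over ``n_runs`` replicate populations.

    Vectorised across runs.  Returns (probability, Monte-Carlo SE); runs still
    segregating at the cap (rare) count as not fixed, with a warning.
    """
    rng = np.random.default_rng(seed)
    n_gam = N if ploidy == "haploid" else 2 * N
    cap = max_generations if max_generations is not None else 100 * N
    p = np.full(n_runs, p0)
    active = np.ones(n_runs, dtype=bool)
    for _ in range(cap):
        if not active.any():
            break
        pa = _selection_update(p[active], s, dominance, ploidy)
        p[active] = rng.binomial(n_gam, pa) / n_gam
        active &= (p > 0.0) & (p < 1.0)
    if active.any():
        warnings.warn(f"{int(active.sum())} runs unabsorbed at the cap")
    prob = float((p == 1.0).mean())
    se = float(np.sqrt(max(prob * (1 - prob), 1e-12) / n_runs))
    return prob, se


def diffusion_fixation_probability(N: int, s: float, p0: float,
                                   ploidy: str = "haploid") -> float:
    """Kimura diffusion fixation probability for genic selection.

    (1 - exp(-2 N_e s p0)) / (1 - exp(-2 N_e s)) with N_e = N gametes for
    haploids and 2N for diploids with additive fitness (h = 1/2).
    """
    ne = N if ploidy == "haploid" else 2 * N
    a = 2.0 * ne * s
    if abs(a) < 1e-12:
        return p0
    with np.errstate(over="ignore"):
        return float(np.expm1(-a * p0) / np.expm1(-a))


def diffusion_conditional_fixation_time(N: int, s: float, p0: float,
                                        ploidy: str = "haploid",
                                        grid: int = 4000) -> float:
    """Expected generations to fixation given fixation, by diffusion theory.

    Solves the boundary-value problem for w(x) = u(x) T*(x),
    a(x) w' + b(x)/2 w'' = -u(x) with w(0) = w(1) = 0, where a = s x(1-x),
    b = x(1-x)/N_e and u is the fixation probability, by finite differences.
    """
    ne = N if ploidy == "haploid" else 2 * N
    x = np.linspace(0.0, 1.0, grid + 1)[1:-1]
    h = 1.0 / grid
    a = s * x * (1 - x)
    b = x * (1 - x) / ne
    alpha = 2.0 * ne * s
    if abs(alpha) < 1e-12:
        u = x.copy()
    else:
        u = np.expm1(-alpha * x) / np.expm1(-alpha)
    # tridiagonal system for a w' + b/2 w'' = -u (central differences)
    lower = b / 2 / h ** 2 - a / (2 * h)
    diag = -b / h ** 2
    upper = b / 2 / h ** 2 + a / (2 * h)
    rhs = -u
    n = x.size
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1] = diag
    ab[2, :-1] = lower[1:]
    from scipy.linalg import solve_banded
    w = solve_banded((1, 1), ab, rhs)
    u_p = np.interp(p0, x, u)
    w_p = np.interp(p0, x, w)
    return float(w_p / u_p)


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    V_A: float
    V_NonA: float
    V_G: float
    V_P: float
    h2: float
    H2: float
    ridge_used: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("V_A", "V_NonA", "V_G", "V_P", "h2", "H2")}


def decompose_variance(genotypes: np.ndarray, phenotypes: np.ndarray,
                       genetic_values: np.ndarray | None = None,
                       ridge: float = 1e-6) -> VarianceDecomposition:
    """Split phenotypic variance into additive / nonadditive / environmental.

    V_A is the variance of the least-squares additive fit of the genetic
    values (or, if unavailable, the phenotypes) on all allele dosages; the
    total genetic variance is the variance of the noiseless genetic values
    when given, else of genotype-class means; V_NonA = V_G - V_A clamped at 0.
    With more loci than individuals a ridge-penalised fit is used and flagged.
    All variances use ddof=0 so noiseless conservation V_P = V_A + V_NonA
    holds exactly.
    """
    X = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    n, L = X.shape
    if len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least two distinct genotypes")
    target = genetic_values if genetic_values is not None else y
    target = np.asarray(target, dtype=float)

    Xc = X - X.mean(axis=0)
    tc = target - target.mean()
    ridge_used = L >= n
    if ridge_used:
        beta = np.linalg.solve(Xc.T @ Xc + ridge * np.eye(L), Xc.T @ tc)
    else:
        beta, *_ = np.linalg.lstsq(Xc, tc, rcond=None)
    V_A = float(np.var(Xc @ beta, ddof=0))

    if genetic_values is not None:
        V_G = float(np.var(genetic_values, ddof=0))
    else:
        # genotype-class means over identical rows
        _, inv = np.unique(X, axis=0, return_inverse=True)
        class_mean = np.bincount(inv, weights=y) / np.bincount(inv)
        V_G = float(np.var(class_mean[inv], ddof=0))
    V_P = float(np.var(y, ddof=0))
    V_NonA = max(V_G - V_A, 0.0)
    h2 = V_A / V_P if V_P > 0 else 0.0
    H2 = (V_A + V_NonA) / V_P if V_P > 0 else 0.0
    return VarianceDecomposition(V_A, V_NonA, V_G, V_P, h2, H2, ridge_used)


# ---------------------------------------------------------------------------
# recombination machinery (haploid random mating)
# ---------------------------------------------------------------------------

def _recombine(mothers: np.ndarray, fathers: np.ndarray, r: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Haploid meiotic gametes from paired parental genomes.

    Parental origin along the loci is a Markov chain: random starting parent,
    switch probability r_j between adjacent loci (0.5 across chromosomes).
    """
    n, L = mothers.shape
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        switches = rng.random((n, L - 1)) < r
        origin = (start + np.concatenate(
            [np.zeros((n, 1), dtype=int), np.cumsum(switches, axis=1)],
            axis=1)) % 2
    else:
        origin = start
    return np.where(origin == 0, mothers, fathers)


def _free_recombination_r(L: int) -> np.ndarray:
    return np.full(max(L - 1, 0), 0.5)


# ---------------------------------------------------------------------------
# depletion of additive variance under selection
# ---------------------------------------------------------------------------

@dataclass
class EvoSimResult:
    trajectory: pd.DataFrame          # generation, V_A, V_NonA, V_G, V_P, h2, H2,
    #                                   mean_trait
    allele_freqs: np.ndarray          # (generations+1, n_loci)
    fixation_events: pd.DataFrame     # locus, generation, allele_class

    def h2_trajectory(self) -> np.ndarray:
        return self.trajectory["h2"].to_numpy()


def _genetic_values(G: np.ndarray, effects: np.ndarray,
                    epi_pairs: np.ndarray, epi_effects: np.ndarray
                    ) -> np.ndarray:
    v = G @ effects
    if len(epi_pairs):
        v = v + (G[:, epi_pairs[:, 0]] * G[:, epi_pairs[:, 1]]) @ epi_effects
    return v


def simulate_depletion(
    genotypes0: np.ndarray,
    effects: np.ndarray,
    recomb_r: np.ndarray | None = None,
    epi_pairs: np.ndarray | None = None,
    epi_effects: np.ndarray | None = None,
    noise_sd: float = 1.0,
    n_generations: int = 25,
    selection: str = "truncation",
    truncation_fraction: float = 0.2,
    fitness_s: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> EvoSimResult:
    """Track the decay of h2 in a haploid population under directional selection.

    Each generation: phenotype = genetic value + noise; parents are the top
    ``truncation_fraction`` by phenotype (``selection='truncation'``) or are
    sampled with probability proportional to exp(fitness_s * standardised
    phenotype) (``'fitness_proportional'``); offspring are meiotic products of
    random parent pairs with recombination fractions ``recomb_r`` between
    adjacent loci (free recombination by default); population size is constant.
    ``selection='none'`` gives the neutral (drift-only) control.
    """
    rng = np.random.default_rng(seed)
    G = np.asarray(genotypes0, dtype=float).copy()
    N, L = G.shape
    effects = np.asarray(effects, dtype=float)
    epi_pairs = np.asarray(epi_pairs if epi_pairs is not None else
                           np.empty((0, 2)), dtype=int)
    epi_effects = np.asarray(epi_effects if epi_effects is not None else
                             np.empty(0), dtype=float)
    r = _free_recombination_r(L) if recomb_r is None else np.asarray(recomb_r)
    if not 0.0 < truncation_fraction < 1.0:
        raise ValueError("truncation fraction must be in (0, 1)")
    if np.all(G == G[0]):
        warnings.warn("monomorphic starting population: trajectory will be flat")

    freqs = np.empty((n_generations + 1, L))
    rows = []
    fixed_at = {}

    def record(gen: int, G: np.ndarray) -> None:
        gv = _genetic_values(G, effects, epi_pairs, epi_effects)
        if len(np.unique(G, axis=0)) < 2:
            V_A = V_NonA = V_G = 0.0
        else:
            dec = decompose_variance(G, gv, genetic_values=gv)
            V_A, V_NonA, V_G = dec.V_A, dec.V_NonA, dec.V_G
        V_P = V_G + noise_sd ** 2
        rows.append({
            "generation": gen, "V_A": V_A, "V_NonA": V_NonA,
            "V_G": V_G, "V_P": V_P,
            "h2": V_A / V_P if V_P > 0 else 0.0,
            "H2": V_G / V_P if V_P > 0 else 0.0,
            "mean_trait": float(gv.mean()),
        })
        freqs[gen] = G.mean(axis=0)
        epi_loci = set(epi_pairs.ravel().tolist())
        for loc in np.where(freqs[gen] == 1.0)[0]:
            fixed_at.setdefault(int(loc), (gen, "epistatic" if int(loc)
                                           in epi_loci else "additive"))

    record(0, G)
    for gen in range(1, n_generations + 1):
        gv = _genetic_values(G, effects, epi_pairs, epi_effects)
        pheno = gv + rng.normal(scale=noise_sd, size=N)
        if selection == "truncation":
            k = max(int(np.ceil(truncation_fraction * N)), 2)
            parents = np.argpartition(-pheno, k - 1)[:k]
        elif selection == "fitness_proportional":
            z = (pheno - pheno.mean()) / max(pheno.std(), 1e-12)
            w = np.exp(fitness_s * z)
            parents = rng.choice(N, size=N, p=w / w.sum())
        elif selection == "none":
            parents = np.arange(N)
        else:
            raise ValueError(f"unknown selection mode {selection!r}")
        mothers = G[rng.choice(parents, size=N)]
        fathers = G[rng.choice(parents, size=N)]
        G = _recombine(mothers, fathers, r, rng)
        record(gen, G)

    events = pd.DataFrame(
        [{"locus": loc, "generation": g, "allele_class": cls}
         for loc, (g, cls) in sorted(fixed_at.items())],
        columns=["locus", "generation", "allele_class"])
    return EvoSimResult(pd.DataFrame(rows), freqs, events)


# ---------------------------------------------------------------------------
# birth of additive variance: adaptive divergence then admixture
# ---------------------------------------------------------------------------

@dataclass
class BirthCycleResult:
    fixation_fraction_additive: float       # across demes
    fixation_fraction_epistatic: float
    per_deme_fixed: pd.DataFrame            # deme, allele_class, n_fixed, n_seeded
    decomposition_founder: VarianceDecomposition
    decomposition_demes: list[VarianceDecomposition]
    decomposition_hybrid: VarianceDecomposition
    h2_founder: float
    h2_demes: list[float]
    h2_hybrid: float


def _evolve_deme(G: np.ndarray, effects: np.ndarray, epi_pairs: np.ndarray,
                 epi_effects: np.ndarray, s: float, generations: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Directional (fitness-proportional) selection with free recombination."""
    N, L = G.shape
    r = _free_recombination_r(L)
    for _ in range(generations):
        gv = _genetic_values(G, effects, epi_pairs, epi_effects)
        w = np.exp(s * gv)
        w = w / w.sum()
        mothers = G[rng.choice(N, size=N, p=w)]
        fathers = G[rng.choice(N, size=N, p=w)]
        G = _recombine(mothers, fathers, r, rng)
        p = G.mean(axis=0)
        if np.all((p == 0.0) | (p == 1.0)):
            break
    return G


def simulate_birth_cycle(
    N: int = 1000,
    n_additive: int = 10,
    n_epistatic_pairs: int = 10,
    effect: float = 0.5,
    s: float = 1.0,
    p0: float = 0.01,
    generations: int = 150,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> BirthCycleResult:
    """Adaptive divergence of two demes, then admixture and one cross.

    Each deme is seeded with its own disjoint set of initially rare beneficial
    variants: ``n_additive`` loci with additive effect ``effect`` and
    ``n_epistatic_pairs`` locus pairs whose {0,1}-coded product carries the
    same effect magnitude (so an epistatic allele has no marginal benefit
    while its partner is rare).  Both demes evolve under fitness-proportional
    directional selection (fitness = exp(s * genetic value)) for up to
    ``generations`` generations; a 50/50 admixed pool is then crossed for one
    generation of free recombination.  Reports per-class fixation fractions
    and the variance decomposition (with environmental noise ``noise_sd``)
    before divergence, per fixed deme and after admixture.
    """
    rng = np.random.default_rng(seed)
    L_per = n_additive + 2 * n_epistatic_pairs
    L = 2 * L_per
    add_eff = np.zeros(L)
    epi_pairs, epi_eff = [], []
    classes = np.empty(L, dtype=object)
    for deme in range(2):
        off = deme * L_per
        add_idx = np.arange(off, off + n_additive)
        add_eff[add_idx] = effect
        classes[add_idx] = "additive"
        for k in range(n_epistatic_pairs):
            i = off + n_additive + 2 * k
            epi_pairs.append((i, i + 1))
            epi_eff.append(effect)
            classes[i] = classes[i + 1] = "epistatic"
    epi_pairs = np.asarray(epi_pairs, dtype=int)
    epi_eff = np.asarray(epi_eff, dtype=float)

    def seed_deme(deme: int) -> np.ndarray:
        G = np.zeros((N, L))
        off = deme * L_per
        n_copies = max(int(round(p0 * N)), 1)
        for loc in range(off, off + L_per):
            carriers = rng.choice(N, size=n_copies, replace=False)
            G[carriers, loc] = 1.0
        return G

    def decomp(G: np.ndarray) -> VarianceDecomposition:
        gv = _genetic_values(G, add_eff, epi_pairs, epi_eff)
        if len(np.unique(G, axis=0)) < 2:
            zero = VarianceDecomposition(0.0, 0.0, 0.0, noise_sd ** 2, 0.0, 0.0)
            return zero
        return decompose_variance(G, gv, genetic_values=gv)

    def h2_of(dec: VarianceDecomposition) -> float:
        vp = dec.V_G + noise_sd ** 2
        return dec.V_A / vp if vp > 0 else 0.0

    founders = [seed_deme(0), seed_deme(1)]
    dec_founder = decomp(founders[0])

    finals, per_deme_rows = [], []
    for deme in range(2):
        Gf = _evolve_deme(founders[deme], add_eff, epi_pairs, epi_eff, s,
                          generations, rng)
        finals.append(Gf)
        p = Gf.mean(axis=0)
        off = deme * L_per
        own = slice(off, off + L_per)
        for cls in ("additive", "epistatic"):
            mask = (classes[own] == cls)
            fixed = int(np.sum(p[own][mask] == 1.0))
            per_deme_rows.append({"deme": deme + 1, "allele_class": cls,
                                  "n_fixed": fixed,
                                  "n_seeded": int(mask.sum())})

    per_deme = pd.DataFrame(per_deme_rows)
    if per_deme["n_fixed"].sum() == 0:
        warnings.warn("no variant fixed in either deme; admixture still run "
                      "on standing variation")

    half = N // 2
    pool = np.vstack([finals[0][rng.choice(N, size=half, replace=False)],
                      finals[1][rng.choice(N, size=N - half, replace=False)]])
    mothers = pool[rng.choice(N, size=N)]
    fathers = pool[rng.choice(N, size=N)]
    hybrid = _recombine(mothers, fathers, _free_recombination_r(L), rng)

    dec_demes = [decomp(finals[0]), decomp(finals[1])]
    dec_hybrid = decomp(hybrid)

    def frac(cls: str) -> float:
        sub = per_deme[per_deme["allele_class"] == cls]
        return float(sub["n_fixed"].sum() / sub["n_seeded"].sum())

    return BirthCycleResult(
        fixation_fraction_additive=frac("additive"),
        fixation_fraction_epistatic=frac("epistatic"),
        per_deme_fixed=per_deme,
        decomposition_founder=dec_founder,
        decomposition_demes=dec_demes,
        decomposition_hybrid=dec_hybrid,
        h2_founder=h2_of(dec_founder),
        h2_demes=[h2_of(d) for d in dec_demes],
        h2_hybrid=h2_of(dec_hybrid),
    )
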