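"""Synthetic segregant panels, trait architectures, phenotypes and growth curves.

Emulates a haploid two-parent yeast cross (BY x RM style): ~hundreds to a
thousand recombinant segregants genotyped at biallelic markers on a genetic
map, measured for many correlated morphological traits with technical
replicates, plus a microplate growth-rate assay.  Every generated panel
records its true variance components so estimator-recovery tests have an
exact ground truth.

Meiosis model: no crossover interference.  Crossovers per chromosome are
Poisson(length_cM/100) with uniform positions, which makes the parental
origin along ordered markers a two-state Markov chain whose switch
probability between adjacent markers is the Haldane map function
r = (1 - exp(-2d/100)) / 2.  The Markov form is what is sampled (it is
distribution-identical at the markers and vectorises).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "TraitArchitecture",
    "TraitPanel",
    "GrowthCurveSet",
    "PanelConfig",
    "ArchitectureConfig",
    "GrowthBiasConfig",
    "haldane_r",
    "simulate_segregant_panel",
    "simulate_traits",
    "simulate_growth_curves",
]


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Genetic map: marker ids, chromosome index and cM position per marker."""

    marker: np.ndarray          # str array, unique ids
    chromosome: np.ndarray      # int array
    position_cM: np.ndarray     # float array, non-decreasing within chromosome

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=int)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        if len(set(self.marker)) != self.marker.size:
            raise ValueError("marker ids must be unique")
        if np.any(self.position_cM < 0):
            raise ValueError("map positions must be nonnegative")
        for c in np.unique(self.chromosome):
            pos = self.position_cM[self.chromosome == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions must be non-decreasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return self.marker.size

    def interval_recomb_fractions(self) -> np.ndarray:
        """Recombination fraction for each of the n-1 adjacent-marker intervals.

        Intervals spanning a chromosome boundary get r = 0.5 (free recombination).
        """
        d = np.diff(self.position_cM)
        r = haldane_r(np.maximum(d, 0.0))
        same_chrom = np.diff(self.chromosome) == 0
        return np.where(same_chrom, r, 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker, "chromosome": self.chromosome,
             "position_cM": self.position_cM}
        )


@dataclass
class GenotypeMatrix:
    """Haploid segregant x marker parental-origin codes.

    Codes: 0.0 = parent-A (BY) allele, 1.0 = parent-B (RM) allele, NaN = missing.
    """

    segregant_ids: np.ndarray
    marker_map: MarkerMap
    codes: np.ndarray  # float (n_segregants, n_markers); values in {0, 1, NaN}

    def __post_init__(self) -> None:
        self.segregant_ids = np.asarray(self.segregant_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (self.segregant_ids.size, self.marker_map.n_markers):
            raise ValueError("codes shape does not match ids and map")
        vals = self.codes[np.isfinite(self.codes)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("allele codes must be 0, 1 or NaN")

    @property
    def n_segregants(self) -> int:
        return self.segregant_ids.size

    @property
    def n_markers(self) -> int:
        return self.marker_map.n_markers

    def allele_freq(self) -> np.ndarray:
        """Frequency of the parent-B (code 1) allele per marker, ignoring missing."""
        return np.nanmean(self.codes, axis=0)

    def imputed(self) -> np.ndarray:
        """Codes with per-marker mean imputation of missing values."""
        X = self.codes.copy()
        if np.isnan(X).any():
            mu = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = mu[idx[1]]
        return X

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.segregant_ids,
                            columns=self.marker_map.marker)

    def write_tsv(self, genotype_path, map_path) -> None:
        df = self.to_frame()
        df.index.name = "segregant"
        df.to_csv(genotype_path, sep="\t")
        self.marker_map.to_frame().to_csv(map_path, sep="\t", index=False)


@dataclass
class TraitArchitecture:
    """True generating model of one trait, with recorded variance components.

    Variance components refer to the realized panel: ``V_A`` is the variance of
    the best additive fit of the genetic values on the causal allele dosages,
    ``V_G`` the variance of the genetic values, ``V_NonA = V_G - V_A`` and
    ``V_E`` the single-measurement noise variance, so V_P = V_A + V_NonA + V_E
    holds exactly.  ``h2_rep_mean`` / ``H2_rep_mean`` are the heritabilities of
    an ``n_replicates``-replicate segregant mean (error variance divided by the
    replicate count), which is the scale on which the panel is analysed.
    """

    name: str
    additive_loci: np.ndarray
    additive_effects: np.ndarray
    epistatic_pairs: np.ndarray       # (k, 2) marker indices
    epistatic_effects: np.ndarray
    noise_sd: float
    importance_w: float
    coupling: float                    # weight on the shared growth genetic signal
    V_A: float = 0.0
    V_NonA: float = 0.0
    V_G: float = 0.0
    V_E: float = 0.0
    h2_single: float = 0.0
    H2_single: float = 0.0
    h2_rep_mean: float = 0.0
    H2_rep_mean: float = 0.0

    @property
    def V_P(self) -> float:
        return self.V_G + self.V_E


@dataclass
class TraitPanel:
    """Replicate-level trait measurements with per-measurement cell counts."""

    segregant_ids: np.ndarray
    trait_names: np.ndarray
    values: np.ndarray        # (n_segregants, n_traits, n_replicates), NaN = missing
    cell_counts: np.ndarray   # (n_segregants, n_replicates)

    def __post_init__(self) -> None:
        n, t, r = self.values.shape
        if self.cell_counts.shape != (n, r):
            raise ValueError("cell_counts shape must be (n_segregants, n_replicates)")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate_matrix(self, rep: int) -> np.ndarray:
        """Segregant x trait matrix for one replicate batch."""
        return self.values[:, :, rep]

    def copy(self) -> "TraitPanel":
        return TraitPanel(self.segregant_ids.copy(), self.trait_names.copy(),
                          self.values.copy(), self.cell_counts.copy())

    def to_long_frame(self) -> pd.DataFrame:
        n, t, r = self.values.shape
        seg = np.repeat(self.segregant_ids, t * r)
        trait = np.tile(np.repeat(self.trait_names, r), n)
        rep = np.tile(np.arange(1, r + 1), n * t)
        counts = np.tile(self.cell_counts[:, None, :], (1, t, 1)).ravel()
        return pd.DataFrame({
            "segregant": seg, "trait": trait, "replicate": rep,
            "value": self.values.ravel(), "cell_count": counts.astype(int),
        })

    def write_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GrowthCurveSet:
    """Hourly OD600 trajectories, one well per segregant replicate."""

    wells: pd.DataFrame       # plate, row, column, segregant, replicate
    times: np.ndarray         # hours, equally spaced
    od: np.ndarray            # (n_wells, n_times)

    def __post_init__(self) -> None:
        if self.od.shape != (len(self.wells), self.times.size):
            raise ValueError("od shape must be (n_wells, n_times)")
        if self.times.size < 2:
            raise ValueError("need at least two readings per well")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0]):
            raise ValueError("time points must be equally spaced")

    def write_tsv(self, path) -> None:
        df = self.wells.copy()
        for j, t in enumerate(self.times):
            df[f"t{t:g}"] = self.od[:, j]
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Genetic-map and cross dimensions (desk-scale defaults)."""

    n_chromosomes: int = 16
    n_markers: int = 1000
    chromosome_length_cM: float | Sequence[float] = 100.0
    missing_rate: float = 0.0

    def lengths(self) -> np.ndarray:
        L = np.broadcast_to(np.asarray(self.chromosome_length_cM, dtype=float),
                            (self.n_chromosomes,)).copy()
        if np.any(L < 0):
            raise ValueError("chromosome lengths must be >= 0 cM")
        return L


@dataclass
class ArchitectureConfig:
    """Trait-architecture generator settings.

    ``mode='adaptive_divergence'`` makes the number of additive loci, the
    additive variance and the growth coupling all increase with the trait's
    importance weight w (the generating assumption that alleles with additive
    effects on fitness-coupled traits were preferentially fixed between the
    parents).  ``mode='decoupled'`` removes the growth coupling so importance
    carries no information about architecture (negative control).

    Variance targets are on the quantile-normalised scale where every trait
    has single-measurement phenotypic variance near 1: additive variance runs
    from ``additive_var_base`` (w=0) to ``additive_var_base+additive_var_span``
    (w=1) before coupling, epistatic traits get ``epistatic_var`` of pairwise-
    product variance, and the residual is environmental noise (floored).
    """

    n_traits: int = 60
    mode: str = "adaptive_divergence"   # or "decoupled"
    additive_loci_min: int = 1
    additive_loci_max: int = 10
    additive_var_base: float = 0.05
    additive_var_span: float = 0.35
    epistasis_fraction: float = 0.3
    n_epistatic_pairs: int = 2
    epistatic_var: float = 0.15
    coupling_strength: float = 0.5
    growth_n_loci: int = 15
    growth_h2: float = 0.7
    genetic_var_cap: float = 0.7
    noise_var_floor: float = 0.3
    cell_count_log_mean: float = float(np.log(250.0))
    cell_count_log_sd: float = 0.35
    channel_cell_wall_fraction: float = 0.33

    def __post_init__(self) -> None:
        if not 0.0 <= self.epistasis_fraction <= 1.0:
            raise ValueError("epistasis fraction must be in [0, 1]")


@dataclass
class GrowthBiasConfig:
    """Smooth multiplicative positional bias over a microplate, plus OD noise."""

    amplitude: float = 0.15    # peak-to-centre relative bias
    noise_sd: float = 0.0      # additive OD observation noise
    n_rows: int = 8
    n_cols: int = 12
    carrying_capacity: float = 1.5
    baseline_od: float = 0.05
    t_mid: float = 10.5        # hours; inflection of the logistic (mid-interval
    #                            of the hourly grid, so the max hourly
    #                            difference straddles it symmetrically)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_segregant_panel(
    map_config: PanelConfig,
    n_segregants: int,
    seed: int | np.random.Generator,
) -> tuple[MarkerMap, GenotypeMatrix]:
    """Simulate independent haploid meiotic products of a two-parent cross.

    Markers are evenly spaced along each chromosome.  Each segregant picks its
    starting parent with probability 1/2 per chromosome and switches parental
    origin between adjacent markers with the Haldane probability for the
    marker spacing (equivalent to Poisson crossovers with uniform positions).
    """
    rng = np.random.default_rng(seed)
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    if map_config.n_markers < 1 or map_config.n_chromosomes < 1:
        raise ValueError("marker and chromosome counts must be positive")

    lengths = map_config.lengths()
    # allocate markers as evenly as possible across chromosomes
    base, extra = divmod(map_config.n_markers, map_config.n_chromosomes)
    per_chrom = np.full(map_config.n_chromosomes, base, dtype=int)
    per_chrom[:extra] += 1
    if np.any(per_chrom == 0):
        raise ValueError("fewer markers than chromosomes")

    chroms, positions, names = [], [], []
    for c in range(map_config.n_chromosomes):
        k = per_chrom[c]
        pos = np.linspace(0.0, lengths[c], k) if k > 1 else np.array([lengths[c] / 2.0])
        chroms.append(np.full(k, c + 1))
        positions.append(pos)
        names.extend(f"chr{c + 1:02d}_m{j + 1:04d}" for j in range(k))
    marker_map = MarkerMap(np.array(names, dtype=object),
                           np.concatenate(chroms), np.concatenate(positions))

    r = marker_map.interval_recomb_fractions()  # chromosome boundaries -> 0.5
    start = rng.integers(0, 2, size=(n_segregants, 1))
    switches = rng.random((n_segregants, marker_map.n_markers - 1)) < r
    origin = (start + np.concatenate(
        [np.zeros((n_segregants, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
    )) % 2
    codes = origin.astype(float)

    if map_config.missing_rate > 0:
        miss = rng.random(codes.shape) < map_config.missing_rate
        codes[miss] = np.nan

    ids = np.array([f"seg{i + 1:04d}" for i in range(n_segregants)], dtype=object)
    return marker_map, GenotypeMatrix(ids, marker_map, codes)


def _trait_name(i: int, cfg: ArchitectureConfig) -> str:
    # deterministic CalMorph-style name: channel letter + number + stage suffix;
    # every third trait is cell-wall ("C"), the rest nucleus ("D"), roughly the
    # 133:272 split of the real trait set
    channel = "C" if (i % 3 == 0) else "D"
    stage = ("A", "A1B", "B", "C")[i % 4]
    return f"{channel}{100 + i}_{stage}"


def _additive_fit_variance(genetic: np.ndarray, dosages: np.ndarray) -> float:
    """Variance (ddof=1) of the least-squares additive fit of genetic values."""
    if dosages.size == 0:
        return 0.0
    X = dosages - dosages.mean(axis=0)
    y = genetic - genetic.mean()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = X @ beta
    return float(np.var(fit, ddof=1))


def simulate_traits(
    genotypes: GenotypeMatrix,
    arch_config: ArchitectureConfig,
    n_replicates: int,
    seed: int | np.random.Generator,
    n_control_replicates: tuple[int, int] = (26, 28),
) -> tuple[list[TraitArchitecture], TraitPanel, np.ndarray, dict]:
    """Generate trait architectures, replicate phenotypes and growth rates.

    Returns ``(architectures, panel, growth_rates, extras)`` where
    ``growth_rates`` is (n_segregants, n_replicates) and ``extras`` holds the
    growth architecture and two control-segregant replicate blocks
    (``control_values[k]``: (n_control_reps_k, n_traits) raw measurements of
    segregants 0 and 1) emulating the per-experiment technical controls.
    """
    rng = np.random.default_rng(seed)
    if n_replicates < 1:
        raise ValueError("replicate count must be >= 1")
    if genotypes.n_segregants == 0:
        raise ValueError("empty genotype panel")
    cfg = arch_config
    X = genotypes.imputed()
    n, m = X.shape
    Xc = X - X.mean(axis=0)

    # shared growth/fitness trait
    g_loci = rng.choice(m, size=min(cfg.growth_n_loci, m), replace=False)
    g_eff = rng.normal(size=g_loci.size)
    g_raw = Xc[:, g_loci] @ g_eff
    sd = g_raw.std(ddof=1)
    g_genetic = g_raw / sd * np.sqrt(cfg.growth_h2) if sd > 0 else g_raw
    g_noise_sd = np.sqrt(max(1.0 - cfg.growth_h2, 1e-12))
    growth_rates = g_genetic[:, None] + rng.normal(
        scale=g_noise_sd, size=(n, n_replicates))
    # growth rates on a positive OD/h scale (affine; correlations unaffected)
    growth_rates = 0.35 + 0.06 * growth_rates
    g_std = g_genetic / g_genetic.std(ddof=1) if g_genetic.std(ddof=1) > 0 else g_genetic

    w = np.linspace(0.0, 1.0, cfg.n_traits) if cfg.n_traits > 1 else np.array([0.5])
    rng.shuffle(w)  # importance not confounded with trait index/name
    epi_traits = rng.random(cfg.n_traits) < cfg.epistasis_fraction

    archs: list[TraitArchitecture] = []
    genetic_values = np.empty((n, cfg.n_traits))
    noise_sds = np.empty(cfg.n_traits)
    for t in range(cfg.n_traits):
        wt = float(w[t])
        k = int(round(cfg.additive_loci_min
                      + (cfg.additive_loci_max - cfg.additive_loci_min) * wt))
        k = max(k, 0)
        loci = rng.choice(m, size=k, replace=False) if k else np.empty(0, dtype=int)
        eff = rng.normal(size=k)
        own = Xc[:, loci] @ eff if k else np.zeros(n)
        target_va = cfg.additive_var_base + cfg.additive_var_span * wt
        s = own.std(ddof=1)
        if s > 0:
            scale = np.sqrt(target_va) / s
            own *= scale
            eff = eff * scale
        coup = cfg.coupling_strength * wt if cfg.mode == "adaptive_divergence" else 0.0
        value = own + coup * g_std

        pairs = np.empty((0, 2), dtype=int)
        p_eff = np.empty(0)
        if epi_traits[t] and cfg.n_epistatic_pairs > 0:
            pairs = rng.choice(m, size=(cfg.n_epistatic_pairs, 2), replace=False)
            raw = (Xc[:, pairs[:, 0]] * Xc[:, pairs[:, 1]])
            p_eff = rng.normal(size=cfg.n_epistatic_pairs)
            epi = raw @ p_eff
            es = epi.std(ddof=1)
            if es > 0:
                escale = np.sqrt(cfg.epistatic_var) / es
                epi *= escale
                p_eff = p_eff * escale
            value = value + epi

        vg = float(np.var(value, ddof=1))
        ve = max(1.0 - min(vg, cfg.genetic_var_cap), cfg.noise_var_floor)
        noise_sd = float(np.sqrt(ve))
        causal = np.unique(np.concatenate(
            [loci, pairs.ravel(), g_loci if coup != 0 else np.empty(0, dtype=int)]
        ).astype(int))
        va = _additive_fit_variance(value, Xc[:, causal]) if causal.size else 0.0
        arch = TraitArchitecture(
            name=_trait_name(t, cfg),
            additive_loci=loci, additive_effects=eff,
            epistatic_pairs=pairs, epistatic_effects=p_eff,
            noise_sd=noise_sd, importance_w=wt, coupling=coup,
            V_A=va, V_NonA=max(vg - va, 0.0), V_G=vg, V_E=ve,
            h2_single=va / (vg + ve),
            H2_single=vg / (vg + ve),
            h2_rep_mean=va / (vg + ve / n_replicates),
            H2_rep_mean=vg / (vg + ve / n_replicates),
        )
        archs.append(arch)
        genetic_values[:, t] = value
        noise_sds[t] = noise_sd

    values = genetic_values[:, :, None] + rng.normal(
        size=(n, cfg.n_traits, n_replicates)) * noise_sds[None, :, None]
    # measurement cell counts (lognormal around ~250 cells, matching a panel
    # where ~99.5% of measurements use >100 cells)
    counts = np.round(np.exp(rng.normal(cfg.cell_count_log_mean,
                                        cfg.cell_count_log_sd,
                                        size=(n, n_replicates)))).astype(int)
    panel = TraitPanel(genotypes.segregant_ids.copy(),
                       np.array([a.name for a in archs], dtype=object),
                       values, counts)

    control_values = []
    for ci, n_reps in enumerate(n_control_replicates[:2]):
        base = genetic_values[ci % n]
        cv = base[None, :] + rng.normal(size=(n_reps, cfg.n_traits)) * noise_sds[None, :]
        # raw-scale positive measurements: controls are used for CV = SD/mean
        control_values.append(5.0 + cv)
    extras = {
        "growth_loci": g_loci, "growth_effects": g_eff,
        "growth_genetic": g_genetic, "growth_h2": cfg.growth_h2,
        "control_values": control_values,
        "importance_w": w,
    }
    return archs, panel, growth_rates, extras


def default_bias_surface(row: np.ndarray, col: np.ndarray,
                         cfg: GrowthBiasConfig) -> np.ndarray:
    """Smooth multiplicative bias: cosine bowl centred mid-plate, mean ~1."""
    r = (row - (cfg.n_rows - 1) / 2.0) / max(cfg.n_rows - 1, 1)
    c = (col - (cfg.n_cols - 1) / 2.0) / max(cfg.n_cols - 1, 1)
    return 1.0 + cfg.amplitude * (np.cos(np.pi * r) * np.cos(np.pi * c) - 0.5)


def simulate_growth_curves(
    growth_rates: np.ndarray,
    bias_config: GrowthBiasConfig | None = None,
    seed: int | np.random.Generator = 0,
    segregant_ids: np.ndarray | None = None,
    bias_surface=None,
) -> GrowthCurveSet:
    """Logistic OD600 trajectories whose max hourly slope encodes growth rate.

    ``growth_rates`` is (n_segregants, n_replicates); each replicate gets one
    well, filled plate by plate in row-major order.  The well's true maximum
    slope is rate x positional bias; hourly sampling and observation noise are
    then applied.
    """
    cfg = bias_config or GrowthBiasConfig()
    rng = np.random.default_rng(seed)
    rates = np.atleast_2d(np.asarray(growth_rates, dtype=float))
    n, n_rep = rates.shape
    if segregant_ids is None:
        segregant_ids = np.array([f"seg{i + 1:04d}" for i in range(n)], dtype=object)
    if bias_surface is None:
        bias_surface = default_bias_surface

    wells_per_plate = cfg.n_rows * cfg.n_cols
    n_wells = n * n_rep
    idx = np.arange(n_wells)
    plate = idx // wells_per_plate + 1
    row = (idx % wells_per_plate) // cfg.n_cols
    col = (idx % wells_per_plate) % cfg.n_cols
    seg_idx = idx // n_rep
    rep = idx % n_rep + 1

    bias = np.asarray(bias_surface(row, col, cfg), dtype=float)
    vmax_true = rates[seg_idx, rep - 1] * bias

    times = np.arange(0.0, 25.0)
    K = cfg.carrying_capacity
    m = 4.0 * vmax_true / K  # logistic max slope = m*K/4
    od = cfg.baseline_od + K / (1.0 + np.exp(-m[:, None] * (times[None, :] - cfg.t_mid)))
    if cfg.noise_sd > 0:
        od = od + rng.normal(scale=cfg.noise_sd, size=od.shape)

    wells = pd.DataFrame({
        "plate": plate, "row": row, "column": col,
        "segregant": segregant_ids[seg_idx], "replicate": rep,
    })
    return GrowthCurveSet(wells, times, od)
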