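"""End-to-end orchestration: simulate/ingest -> QC -> heritability -> QTL ->
importance -> correlations, plus the evolutionary scenarios.

Every stage is a pure function of (inputs, config, seed); stage seeds are
spawned deterministically from the global seed, so reruns with the same config
are byte-identical.  ``run_synthetic_analysis`` is the in-memory workhorse
(returns the per-trait results table); ``run_pipeline`` wraps it with TSV
outputs and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evosim, heritability, importance, preprocess, qtl
from .simulate import (ArchitectureConfig, GrowthBiasConfig, PanelConfig,
                       simulate_growth_curves, simulate_segregant_panel,
                       simulate_traits)

__all__ = ["PipelineConfig", "run_synthetic_analysis", "run_pipeline",
           "run_evolution"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the analysis' standard thresholds
    (min_cells=80, cv_max=0.4, dist_max=0.2, LOD 2.68/2.92/3.72/4.9)."""

    seed: int = 0
    n_segregants: int = 500
    n_replicates: int = 2
    panel: PanelConfig = field(default_factory=PanelConfig)
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    growth_bias: GrowthBiasConfig = field(default_factory=GrowthBiasConfig)
    min_cells: int = 80
    cv_max: float = 0.4
    dist_max: float = 0.2
    lod_thresholds: tuple = qtl.DEFAULT_LOD_THRESHOLDS
    redundancy_window_cM: float = 10.0
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    jackknife: str = "none"       # "none" | "H2" | "both"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lod_thresholds"] = list(self.lod_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("panel", PanelConfig),
                         ("architecture", ArchitectureConfig),
                         ("growth_bias", GrowthBiasConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "lod_thresholds" in d:
            d["lod_thresholds"] = tuple(d["lod_thresholds"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_seeds(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def run_synthetic_analysis(config: PipelineConfig) -> dict:
    """Simulate a panel and run the full trait analysis in memory.

    Returns a dict with the per-trait results table (``traits``: true and
    estimated heritabilities, RTGR, QTL count, joint R2, categories, exemplar
    membership), the QTL results, correlation summaries, QC tables and the raw
    stage objects.
    """
    rngs = _stage_seeds(config.seed)
    cfg = config

    marker_map, genotypes = simulate_segregant_panel(
        cfg.panel, cfg.n_segregants, rngs[0])
    archs, panel, growth_rates, extras = simulate_traits(
        genotypes, cfg.architecture, cfg.n_replicates, rngs[1])
    curves = simulate_growth_curves(growth_rates, cfg.growth_bias, rngs[2],
                                    segregant_ids=panel.segregant_ids)

    # --- preprocessing -----------------------------------------------------
    well_table = preprocess.extract_growth_rate(curves)
    growth = preprocess.growth_rate_per_segregant(well_table)
    panel_f, retention = preprocess.filter_low_cell_count(panel, cfg.min_cells)
    panel_n = preprocess.normalize_panel(panel_f)
    means = preprocess.aggregate_replicates(panel_n)
    consistency = preprocess.assess_trait_consistency(
        extras["control_values"][0], extras["control_values"][1],
        trait_names=panel.trait_names, cv_max=cfg.cv_max, dist_max=cfg.dist_max)

    keep = np.isin(genotypes.segregant_ids, panel_f.segregant_ids)
    from .simulate import GenotypeMatrix
    geno_f = GenotypeMatrix(genotypes.segregant_ids[keep], marker_map,
                            genotypes.codes[keep])
    growth = growth.reindex(panel_f.segregant_ids).to_numpy()

    # --- heritability ------------------------------------------------------
    K = heritability.compute_kinship(geno_f)
    d, U = np.linalg.eigh(K)
    eig = (np.clip(d, 0.0, None), U)
    rows = []
    qtl_results = []
    for t, arch in enumerate(archs):
        reps = panel_n.values[:, t, :]
        try:
            h2b = heritability.estimate_H2(reps)
            H2, sG, sE, n2 = h2b.H2, h2b.sigma_G2, h2b.sigma_E2, \
                h2b.n_segregants_used
        except ValueError:
            H2, sG, sE, n2 = np.nan, np.nan, np.nan, 0
        y = means.iloc[:, t].to_numpy()
        ok = np.isfinite(y)
        if ok.all():
            h2n = heritability.estimate_h2(y, K, eig=eig)
        else:
            Ks = K[np.ix_(ok, ok)]
            h2n = heritability.estimate_h2(y[ok], Ks)
        res = qtl.forward_search(y, geno_f, cfg.lod_thresholds,
                                 cfg.redundancy_window_cM, trait=arch.name)
        qtl_results.append(res)
        channel, stage = importance.categorize_trait(arch.name)
        rows.append({
            "trait": arch.name, "importance_w": arch.importance_w,
            "true_h2": arch.h2_rep_mean, "true_H2": arch.H2_single,
            "true_V_A": arch.V_A, "true_V_NonA": arch.V_NonA,
            "H2": H2, "sigma_G2": sG, "sigma_E2": sE, "n_H2": n2,
            "h2": h2n.h2, "sigma_A2": h2n.sigma_A2, "sigma_EV2": h2n.sigma_EV2,
            "n_h2": h2n.n_segregants_used,
            "n_qtl": res.n_qtl, "joint_R2": res.joint_R2,
            "channel": channel, "stage": stage,
        })
    traits = pd.DataFrame(rows)

    if cfg.jackknife in ("H2", "both"):
        ses = []
        for t in range(len(archs)):
            reps = panel_n.values[:, t, :]
            se, _ = heritability.jackknife_se(
                lambda idx, reps=reps: heritability.estimate_H2(reps[idx]).H2,
                reps.shape[0])
            ses.append(se)
        traits["H2_se"] = ses
    if cfg.jackknife == "both":
        ses = []
        for t in range(len(archs)):
            y = means.iloc[:, t].to_numpy()
            se, _ = heritability.jackknife_se(
                lambda idx, y=y: heritability.estimate_h2(
                    y[idx], K[np.ix_(idx, idx)]).h2, y.size)
            ses.append(se)
        traits["h2_se"] = ses

    # --- importance --------------------------------------------------------
    rtgr = importance.compute_rtgr(means, growth)
    traits["RTGR"] = rtgr["RTGR"].to_numpy()
    cons_idx = consistency.set_index("trait").reindex(traits["trait"])
    traits["one_minus_cv"] = cons_idx["one_minus_cv"].to_numpy()
    traits["cv_included"] = cons_idx["included"].to_numpy()

    clustering = importance.cluster_exemplars(means, damping=cfg.ap_damping,
                                              max_iter=cfg.ap_max_iter)
    traits["exemplar"] = panel.trait_names[clustering.exemplar_of]
    traits["is_exemplar"] = np.isin(np.arange(len(archs)),
                                    clustering.exemplar_indices)

    # --- correlations ------------------------------------------------------
    correlations = {}
    correlations["h2_vs_RTGR"] = importance.correlate_h2_importance(
        traits["h2"], traits["RTGR"])
    correlations["h2_vs_RTGR_exemplars"] = importance.correlate_h2_importance(
        traits.loc[traits["is_exemplar"], "h2"],
        traits.loc[traits["is_exemplar"], "RTGR"])
    correlations["h2_vs_RTGR_by_stage"] = importance.correlate_h2_importance(
        traits["h2"], traits["RTGR"], groups=traits["stage"])
    correlations["h2_vs_RTGR_by_channel"] = importance.correlate_h2_importance(
        traits["h2"], traits["RTGR"], groups=traits["channel"])
    cons_ok = traits["cv_included"].fillna(False).astype(bool)
    if cons_ok.sum() >= 3:
        correlations["h2_vs_one_minus_cv"] = importance.correlate_h2_importance(
            traits.loc[cons_ok, "h2"], traits.loc[cons_ok, "one_minus_cv"])
    correlations["qtl_count_vs_h2"] = importance.correlate_h2_importance(
        traits["h2"], traits["n_qtl"].astype(float))
    correlations["qtl_R2_vs_h2"] = importance.correlate_h2_importance(
        traits["h2"], traits["joint_R2"])

    sign_table, sign_summary = (None, None)
    if any(r.n_qtl for r in qtl_results):
        sign_table, sign_summary = qtl.effect_sign_summary(qtl_results)

    return {
        "traits": traits, "qtl_results": qtl_results,
        "correlations": correlations, "consistency": consistency,
        "retention": retention, "well_table": well_table,
        "clustering": clustering, "architectures": archs,
        "genotypes": geno_f, "marker_map": marker_map, "means": means,
        "growth": growth, "sign_table": sign_table,
        "sign_summary": sign_summary, "panel_raw": panel,
    }


PROVENANCE = "# produced by segvar run_pipeline; deterministic given config+seed"


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    with open(path, "w") as fh:
        fh.write(PROVENANCE + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic analysis and write result tables + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": [], "outputs": {}}
    try:
        res = run_synthetic_analysis(config)
        manifest["stages"].append("simulate+preprocess+herit+qtl+importance")
    except Exception as exc:
        manifest["error"] = {"stage": "analysis", "message": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    qtl_rows = []
    for r in res["qtl_results"]:
        for _, row in r.qtls.iterrows():
            qtl_rows.append({"trait": r.trait, **row.to_dict()})
    qtl_table = pd.DataFrame(qtl_rows, columns=[
        "trait", "marker", "marker_index", "chromosome", "position_cM",
        "round", "lod_at_selection", "effect", "sign"])
    corr_rows = []
    for name, tab in res["correlations"].items():
        for _, row in tab.iterrows():
            corr_rows.append({"analysis": name, **row.to_dict()})

    outputs = {
        "traits.tsv": res["traits"],
        "qtls.tsv": qtl_table,
        "correlations.tsv": pd.DataFrame(corr_rows),
        "consistency.tsv": res["consistency"],
        "retention.tsv": res["retention"],
        "growth_wells.tsv": res["well_table"],
    }
    if res["sign_table"] is not None:
        outputs["qtl_signs.tsv"] = res["sign_table"]
    for name, df in outputs.items():
        manifest["outputs"][name] = _write_tsv(df, out / name)
    if res["sign_summary"]:
        manifest["sign_summary"] = res["sign_summary"]
    manifest["n_traits"] = len(res["traits"])
    manifest["n_segregants_retained"] = int(res["retention"]["retained"].sum())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def run_evolution(seed: int = 0, outdir=None,
                  n_generations: int = 25, N: int = 1000,
                  truncation_fraction: float = 0.2,
                  target_h2: float = 0.6, n_loci: int = 20) -> dict:
    """Run the depletion and birth-cycle scenarios once and summarise them."""
    rngs = _stage_seeds(seed, 4)
    panel_cfg = PanelConfig(n_chromosomes=16, n_markers=n_loci)
    _, geno = simulate_segregant_panel(panel_cfg, N, rngs[0])
    r = geno.marker_map.interval_recomb_fractions()
    effects = rngs[1].normal(size=n_loci)
    gv = (geno.codes - geno.codes.mean(axis=0)) @ effects
    dec = evosim.decompose_variance(geno.codes, gv, genetic_values=gv)
    noise_sd = float(np.sqrt(dec.V_A * (1 - target_h2) / target_h2))

    depl = evosim.simulate_depletion(
        geno.codes, effects, recomb_r=r, noise_sd=noise_sd,
        n_generations=n_generations,
        truncation_fraction=truncation_fraction, seed=rngs[2])
    cycle = evosim.simulate_birth_cycle(N=N, seed=rngs[3])

    summary = {
        "depletion_h2_start": float(depl.trajectory["h2"].iloc[0]),
        "depletion_h2_end": float(depl.trajectory["h2"].iloc[-1]),
        "depletion_generations": n_generations,
        "birth_fixation_fraction_additive": cycle.fixation_fraction_additive,
        "birth_fixation_fraction_epistatic": cycle.fixation_fraction_epistatic,
        "birth_h2_demes": cycle.h2_demes,
        "birth_h2_hybrid": cycle.h2_hybrid,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(depl.trajectory, out / "depletion_trajectory.tsv")
        _write_tsv(cycle.per_deme_fixed, out / "birth_cycle_fixations.tsv")
        (out / "evolution_summary.json").write_text(
            json.dumps(summary, indent=2))
    return {"summary": summary, "depletion": depl, "birth_cycle": cycle}
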