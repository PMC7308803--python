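"""End-to-end pipeline: simulate -> qc -> prune -> score -> associate -> report.

Every stage writes its outputs under the run directory and the run log
records every threshold actually applied plus package versions and the
seed, so a result is reproducible from the log alone.  The pipeline is a
deterministic function of its configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from agestrat_prs import io as aio
from agestrat_prs.assoc import (
    ModelSpec,
    StratumSpec,
    apoe_survival_tables,
    build_analysis_frame,
    parental_models,
    stratified_table,
)
from agestrat_prs.prune import PruneConfig, prune
from agestrat_prs.qc import QCConfig, apply_filters, compute_metrics
from agestrat_prs.score import (
    ScoreConfig,
    adjust_and_standardize,
    call_apoe_panel,
    compute_prs,
)
from agestrat_prs.simulate import (
    SimulationConfig,
    attach_apoe,
    simulate_discovery_sumstats,
    simulate_genotypes,
    simulate_parents,
    simulate_phenotype,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full synthetic-cohort analysis run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc_profile: str = "array"  # or "imputed"
    prune: PruneConfig = field(default_factory=PruneConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    stratum: StratumSpec = field(default_factory=StratumSpec)
    outcome: str = "status"  # or "parental" (requires sim.proxy)
    log_level: str = "INFO"

    _SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "PipelineConfig":
        """Build from a flat key=value mapping (see io.read_flat_config).

        Simulation keys use their field names (seed, n_variants, ...);
        pairs like maf_range are comma-separated.  Pipeline keys:
        qc_profile, r2_max, window_bp, ref_n, p_threshold, missing_policy,
        outcome, age_cutoff.
        """
        sim_kwargs: dict = {}
        for key in cls._SIM_FIELDS & flat.keys():
            raw = flat[key]
            default = getattr(SimulationConfig, key, None)
            if isinstance(default, tuple):
                parts = [float(x) for x in raw.split(",")]
                sim_kwargs[key] = tuple(int(p) if p.is_integer() and all(
                    isinstance(d, int) for d in default) else p for p in parts)
            elif isinstance(default, bool):
                sim_kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                sim_kwargs[key] = int(raw)
            elif isinstance(default, float):
                sim_kwargs[key] = float(raw)
            else:
                sim_kwargs[key] = raw
        outcome = flat.get("outcome", "status")
        if outcome == "parental":
            sim_kwargs["proxy"] = True
        sim = SimulationConfig(**sim_kwargs)
        prune_cfg = PruneConfig(
            r2_max=float(flat.get("r2_max", 0.1)),
            window_bp=int(flat.get("window_bp", 1_000_000)),
            ref_n=int(flat["ref_n"]) if "ref_n" in flat else None,
            seed=sim.seed,
        )
        score_cfg = ScoreConfig(
            p_threshold=float(flat.get("p_threshold", 0.5)),
            missing_policy=flat.get("missing_policy", "mean"),
        )
        stratum = StratumSpec(
            age_variable="parental_age" if outcome == "parental" else "participant_age",
            cutoff_years=float(flat.get("age_cutoff", sim.age_cutoff)),
        )
        return cls(sim=sim, qc_profile=flat.get("qc_profile", "array"),
                   prune=prune_cfg, score=score_cfg, stratum=stratum, outcome=outcome,
                   log_level=flat.get("log_level", "INFO"))


def _qc_config(profile: str) -> QCConfig:
    if profile == "array":
        return QCConfig.array()
    if profile == "imputed":
        return QCConfig.imputed()
    raise ValueError(f"unknown QC profile {profile!r}")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages, writing per-stage outputs and a run log.

    Returns a dict with the in-memory results (panel, sumstats, scores,
    association tables).  Any stage error aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.sim.seed, "stages": {}}
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    # -- simulate ---------------------------------------------------------
    def _simulate():
        panel = attach_apoe(simulate_genotypes(config.sim), config.sim)
        samples = simulate_phenotype(panel, config.sim)
        father = mother = None
        if config.sim.proxy:
            father, mother, samples = simulate_parents(panel, config.sim)
        sumstats = simulate_discovery_sumstats(config.sim)
        aio.write_panel_vcf(panel, out / "panel.vcf")
        aio.write_sumstats(sumstats, out / "sumstats.tsv")
        aio.write_sample_table(samples, out / "samples.tsv")
        log["stages"]["simulate"] = {
            "n_target": config.sim.n_target,
            "n_discovery": config.sim.n_discovery,
            "n_variants": panel.n_variants,
            "prevalence": config.sim.prevalence,
            "proxy": config.sim.proxy,
        }
        return panel, samples, sumstats, father, mother

    panel, samples, sumstats, father, mother = stage("simulate")(_simulate)
    results.update(panel=panel, samples=samples, sumstats=sumstats)

    # -- qc ---------------------------------------------------------------
    def _qc():
        qc_cfg = _qc_config(config.qc_profile)
        metrics = compute_metrics(panel, qc_cfg, status=samples.get("status"))
        filtered, report = apply_filters(panel, metrics, qc_cfg)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        log["stages"]["qc"] = {
            "profile": config.qc_profile,
            "maf_min": qc_cfg.maf_min,
            "missing_max": qc_cfg.missing_max,
            "hwe_p_min": qc_cfg.hwe_p_min,
            "info_min": qc_cfg.info_min,
            "n_before": panel.n_variants,
            "n_after": filtered.n_variants,
        }
        return filtered

    filtered = stage("qc")(_qc)
    results["panel_qc"] = filtered

    # -- prune ------------------------------------------------------------
    def _prune():
        kept = prune(filtered, sumstats, config.prune)
        (out / "pruned_variants.txt").write_text("\n".join(kept) + "\n")
        log["stages"]["prune"] = {
            "r2_max": config.prune.r2_max,
            "window_bp": config.prune.window_bp,
            "n_retained": len(kept),
        }
        return kept

    kept = stage("prune")(_prune)
    results["retained"] = kept

    # -- score ------------------------------------------------------------
    def _score():
        raw = compute_prs(filtered, sumstats, kept, config.score)
        if int(raw["n_variants_used"].iloc[0]) == 0:
            warnings.warn("polygenic score uses zero variants", stacklevel=2)
        pcs = [c for c in samples.columns if c.startswith("pc")]
        age_col = "parental_age" if config.outcome == "parental" else "age"
        covars = build_analysis_frame(samples)
        cov_cols = pcs + ["sex"] + ([age_col] if age_col in covars.columns else [])
        scores = adjust_and_standardize(raw, covars, cov_cols)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        log["stages"]["score"] = {
            "p_threshold": config.score.p_threshold,
            "exclude_regions": raw.attrs["exclude_regions"],
            "n_variants_used": int(raw["n_variants_used"].iloc[0]),
            "adjust_covariates": cov_cols,
        }
        return scores

    scores = stage("score")(_score)
    results["scores"] = scores

    # -- associate --------------------------------------------------------
    def _associate():
        apoe = call_apoe_panel(panel)
        frame = build_analysis_frame(samples, scores, apoe)
        if int(scores["n_variants_used"].iloc[0]) == 0:
            raise ValueError("cannot associate: polygenic score uses zero variants")
        out_tables: dict = {"apoe_calls": apoe, "frame": frame}
        if config.outcome == "parental":
            spec = ModelSpec(outcome="parental_count",
                             predictors=("e4_dose", "e2_dose", "prs"), family="poisson")
            table, fits = stratified_table(frame, spec, config.stratum)
            table.to_csv(out / "association_stratified.tsv", sep="\t", index=False)
            pm = parental_models(frame)
            parental_rows = []
            for name, fit in pm.items():
                for _, row in fit.coefficients.iterrows():
                    parental_rows.append({"model": name, **row.to_dict(), "auc": fit.auc})
            pd.DataFrame(parental_rows).to_csv(out / "association_parental.tsv",
                                               sep="\t", index=False)
            surv = apoe_survival_tables(frame, apoe, config.stratum.cutoff_years)
            surv["ages"].to_csv(out / "survival_ages.tsv", sep="\t", index=False)
            surv["proportions"].to_csv(out / "survival_proportions.tsv",
                                       sep="\t", index=False)
            out_tables.update(stratified=table, fits=fits, parental=pm, survival=surv)
        else:
            spec = ModelSpec(outcome="status",
                             predictors=("e4_dose", "e2_dose", "prs"), family="binomial")
            table, fits = stratified_table(frame, spec, config.stratum)
            table.to_csv(out / "association_stratified.tsv", sep="\t", index=False)
            out_tables.update(stratified=table, fits=fits)
        log["stages"]["associate"] = {
            "outcome": config.outcome,
            "age_cutoff": config.stratum.cutoff_years,
            "age_variable": config.stratum.age_variable,
        }
        return out_tables

    results.update(stage("associate")(_associate))

    # -- report -----------------------------------------------------------
    versions = {}
    for mod in ("numpy", "scipy", "pandas", "statsmodels"):
        versions[mod] = __import__(mod).__version__
    import agestrat_prs

    log["versions"] = {**versions, "agestrat_prs": agestrat_prs.__version__}
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    results["log"] = log
    return results
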