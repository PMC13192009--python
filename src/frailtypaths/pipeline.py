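"""End-to-end orchestration: cohort -> harmonisation -> survival ->
network learning -> path models -> four-way decomposition.

Each stage writes plain-text artifacts (CSV/JSON/DOT) into the output
directory and a manifest records the seed, a hash of the configuration
and of every file written, plus per-stage record counts, so a run is
fully auditable and byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abn as abn_mod
from . import __version__
from .decompose import DecompositionSpec, bootstrap_decomposition
from .harmonize import score_frailty_table
from .paths import fit_path_models, path_table
from .simulate import (CLOCKS, FRAILTY_COMPONENTS, GeneratorConfig,
                       covariate_matrix, generate_cohort,
                       apply_sampling_design)
from .survival import fit_cox, km_weighted, test_proportional_hazards

log = logging.getLogger("frailtypaths")

STAGES = ("harmonize", "survival", "abn", "paths", "decompose")

__all__ = ["PipelineConfig", "run_pipeline", "correlation_matrix", "STAGES"]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run; YAML-serialisable."""

    input_mode: str = "synthetic"            # synthetic | csv
    input_csv: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sampling_design: dict | None = field(default_factory=lambda: {
        "n_strata": 2, "psus_per_stratum": 3,
        "weight_model": {"age_per_decade": 0.3, "ses": 0.2},
    })                                       # kwargs of apply_sampling_design
    instrument: str = "fried_nhanes"
    clocks: list = field(default_factory=lambda: list(CLOCKS))
    mediators: list = field(default_factory=lambda: ["grimage_eaa"])
    direction: str = "forward"               # forward | reverse | both
    age_squared: bool = False
    leukocyte_covariates: bool = False
    interval_width: float = 2.0
    n_bins: int = 5
    parent_limits: tuple = (1, 2, 3)
    include_period_node: bool = False
    n_boot: int = 200
    seed: int = 0
    stages: tuple = STAGES
    output_dir: str = "frailtypaths_output"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "generator" in d and isinstance(d["generator"], dict):
            g = d["generator"]
            if "eaa_cov" in g:
                g["eaa_cov"] = np.asarray(g["eaa_cov"], dtype=float)
            d["generator"] = GeneratorConfig(**g)
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("output_dir")  # identifies the analysis, not its destination
        d["generator"]["eaa_cov"] = np.asarray(
            d["generator"]["eaa_cov"]).tolist()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def correlation_matrix(data: pd.DataFrame, variables, method="pearson"
                       ) -> pd.DataFrame:
    """Pairwise-complete correlation matrix over ``variables``.

    Constant variables yield missing rows/columns; the diagonal is 1 for
    every non-degenerate variable.  Descriptive (unweighted) by design.
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    sub = data[variables].astype(float)
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete rows")
    corr = sub.corr(method=method)
    for v in variables:
        if sub[v].nunique(dropna=True) > 1:
            corr.loc[v, v] = 1.0
    return corr


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _decomp_covariates(cfg: PipelineConfig, df: pd.DataFrame):
    cov = covariate_matrix(df)
    if cfg.age_squared:
        cov["age_c_sq"] = cov["age_c"] ** 2
    if cfg.leukocyte_covariates:
        for c in ("wbc_neut", "wbc_lymph", "wbc_mono"):
            if c in df.columns:
                cov[c] = df[c]
    return cov


def _load_data(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.input_mode == "synthetic":
        df = generate_cohort(cfg.generator)
        if cfg.sampling_design:
            df = apply_sampling_design(df, seed=cfg.generator.seed + 1,
                                       **cfg.sampling_design)
        return df
    if cfg.input_csv is None:
        raise ValueError("input_mode 'csv' requires input_csv")
    df = pd.read_csv(cfg.input_csv)
    required = (["age", "sex", "race", "ses_z", "followup_time", "event",
                 "weight", "psu", "stratum"] + list(cfg.clocks)
                + FRAILTY_COMPONENTS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV is missing required columns: {missing}")
    return df


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order, writing artifacts and a
    manifest; returns {stage: in-memory results}.

    Stages are isolated: disabling one never changes another's numbers
    (the decomposition always reads the cohort table, not the network).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    stage_log: dict[str, dict] = {}
    results: dict = {}

    def write_text(name, text):
        p = out / name
        p.write_text(text)
        written[name] = _sha256(p)

    def write_csv(name, frame, **kw):
        p = out / name
        frame.to_csv(p, float_format="%.10g", **kw)
        written[name] = _sha256(p)

    df = _load_data(cfg)
    for col in cfg.mediators:
        if col not in df.columns:
            raise ValueError(f"configured mediator column {col!r} absent "
                             "from the input data")
    log.info("loaded cohort: n=%d events=%d", len(df), int(df["event"].sum()))
    write_csv("cohort.csv", df, index=False)
    results["data"] = df
    stage_log["data"] = {"n": len(df), "events": int(df["event"].sum())}

    if "harmonize" in cfg.stages:
        scored = score_frailty_table(df, cfg.instrument)
        df = df.assign(frailty_score=scored["frailty_score"],
                       frail=scored["frail"])
        n_missing = int(scored["frailty_score"].isna().sum())
        corr = correlation_matrix(df, list(cfg.clocks) + ["frailty_score"])
        write_csv("frailty_scores.csv", scored, index=False)
        write_csv("correlations.csv", corr)
        results["harmonize"] = {"scores": scored, "correlations": corr}
        stage_log["harmonize"] = {"n": len(df), "missing_scores": n_missing}
        log.info("harmonize: %d subjects, %d unscoreable", len(df), n_missing)
        df = df.dropna(subset=["frail"]).copy()

    cov = _decomp_covariates(cfg, df)
    adj = list(cov.columns.drop("ses_z"))
    psu_col = "psu" if df["psu"].nunique() > 1 else None
    work = pd.concat([df.reset_index(drop=True),
                      cov.reset_index(drop=True)], axis=1)
    work = work.loc[:, ~work.columns.duplicated()]

    if "survival" in cfg.stages:
        curves = km_weighted(work, "frail", weight_col="weight")
        km = pd.concat([c.as_frame() for c in curves])
        write_csv("km_curves.csv", km, index=False)
        fits = {}
        for predictor in ["frail"] + list(cfg.clocks) + ["ses_z"]:
            f = fit_cox(work, [predictor] + adj, weight_col="weight",
                        cluster_col=psu_col, time_scale="attained_age")
            ph = test_proportional_hazards(f)
            fits[predictor] = {
                "summary": f.summary().to_dict(orient="index"),
                "n": f.n, "n_events": f.n_events,
                "ph_test": ph.to_dict(orient="index"),
            }
        write_text("cox_fits.json", json.dumps(fits, indent=2, sort_keys=True,
                                               default=float))
        results["survival"] = {"km": curves, "cox": fits}
        stage_log["survival"] = {"n": len(work),
                                 "events": int(work["event"].sum())}
        log.info("survival: fitted %d weighted Cox models", len(fits))

    dag = None
    if "abn" in cfg.stages:
        node_cols = (["age", "sex", "ses_z", "frail"] + list(cfg.clocks)
                     + ["period_event"])
        pp = abn_mod.to_person_period(
            work, cfg.interval_width,
            baseline_cols=["subject_id", "age", "sex", "ses_z", "frail"]
            + list(cfg.clocks))
        for c in ["age", "ses_z"] + list(cfg.clocks):
            pp[c], _, _ = abn_mod.discretize_percentile(pp[c], cfg.n_bins)
        specs = ([abn_mod.NodeSpec("age", "gaussian", "exogenous"),
                  abn_mod.NodeSpec("sex", "binomial", "exogenous"),
                  abn_mod.NodeSpec("ses_z", "gaussian", "endogenous"),
                  abn_mod.NodeSpec("frail", "binomial", "endogenous")]
                 + [abn_mod.NodeSpec(c, "gaussian", "endogenous")
                    for c in cfg.clocks]
                 + [abn_mod.NodeSpec("period_event", "binomial", "sink")])
        if cfg.include_period_node:
            specs.append(abn_mod.NodeSpec("period_index", "gaussian",
                                          "exogenous"))
        pp_model = pp[[s.name for s in specs]].astype(float)
        table, selected, all_results = abn_mod.compare_parent_limits(
            pp_model, specs, cfg.parent_limits)
        dag = all_results[selected]
        write_csv("abn_scores.csv", table, index=False)
        write_text("abn_dag.dot", dag.to_dot())
        write_text("abn_dag.json", dag.to_json())
        results["abn"] = {"person_period": pp, "table": table,
                          "selected_limit": selected, "dag": dag,
                          "all": all_results, "node_specs": specs}
        stage_log["abn"] = {"person_periods": len(pp),
                            "selected_parent_limit": int(selected),
                            "n_arcs": len(dag.arcs)}
        log.info("abn: %d person-periods, parent limit %d, %d arcs",
                 len(pp), selected, len(dag.arcs))

    if "paths" in cfg.stages and dag is not None:
        renamed = {ch if ch != "period_event" else "event": tuple(ps)
                   for ch, ps in dag.parents.items()}
        cdag = abn_mod.DagResult(parents=renamed, node_scores={},
                                 total_score=dag.total_score,
                                 parent_limit=dag.parent_limit)
        cspecs = [abn_mod.NodeSpec("event" if s.name == "period_event"
                                   else s.name, s.family, s.role)
                  for s in results["abn"]["node_specs"]]
        m1 = path_table(fit_path_models(cdag, work, cspecs,
                                        survival_node="event"))
        m2 = path_table(fit_path_models(cdag, work, cspecs,
                                        weight_col="weight", psu_col=psu_col,
                                        survival_node="event"))
        write_csv("paths_model1.csv", m1, index=False)
        write_csv("paths_model2.csv", m2, index=False)
        results["paths"] = {"model1": m1, "model2": m2}
        stage_log["paths"] = {"n_paths": len(m1)}
        log.info("paths: %d arcs fitted under both designs", len(m1))

    if "decompose" in cfg.stages:
        rows, decs = [], {}
        directions = {"forward": ["forward"], "reverse": ["reverse"],
                      "both": ["forward", "reverse"]}[cfg.direction]
        for mediator in cfg.mediators:
            for direction in directions:
                if direction == "forward":
                    spec = DecompositionSpec(
                        exposure="frail", mediator=mediator,
                        covariates=list(cov.columns),
                        weight_col="weight", psu_col=psu_col)
                else:
                    spec = DecompositionSpec(
                        exposure=mediator, mediator="frail",
                        mediator_family="bernoulli",
                        covariates=list(cov.columns),
                        weight_col="weight", psu_col=psu_col)
                res = bootstrap_decomposition(
                    work, spec, n_boot=cfg.n_boot, seed=cfg.seed)
                decs[(mediator, direction)] = res
                frame = res.as_frame()
                frame.insert(0, "direction", direction)
                frame.insert(0, "mediator", mediator)
                rows.append(frame.reset_index(names="quantity"))
        tab = pd.concat(rows, ignore_index=True)
        write_csv("decomposition.csv", tab, index=False)
        results["decompose"] = decs
        stage_log["decompose"] = {"n_models": len(decs),
                                  "n_boot": cfg.n_boot}
        log.info("decompose: %d mediator models, %d bootstrap draws each",
                 len(decs), cfg.n_boot)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg.config_hash(),
        "stages": stage_log,
        "files": dict(sorted(written.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    results["manifest"] = manifest
    return results
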