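"""End-to-end orchestration: simulate/load -> QC -> covariates -> traits ->
residual models -> repeatability -> correlations -> ranking.

Each stage writes its CSV outputs into the artifact directory and appends to
the structured log; removals accumulate into one ``exclusions.csv``.  A stage
that cannot run on the provided data because a required table is absent
(e.g. ranking without intake records) is logged and skipped; genuine errors
abort with the stage name attached.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import metrics, qc, ranking, residual
from .covariates import compute_covariates
from .io import RunLog, write_bundle, write_table, read_bundle
from .lmm import estimate_repeatability
from .simulate import SimulationConfig, config_to_dict, simulate_flocks


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full run needs; thresholds default to the standard edits."""

    cohort: str = "growing"
    input_dir: str | None = None            # read an existing CSV bundle ...
    simulation: SimulationConfig | None = None  # ... or generate one
    output_dir: str = "artifacts"
    ch4_min: float = qc.CH4_MIN_G_D
    co2_max: float = qc.CO2_MAX_G_D
    sd_multiple: float = qc.SD_MULTIPLE
    min_group_size: int = qc.MIN_GROUP_SIZE
    rmt_mode: str = "conditional"           # or "keep_animal"
    repeatability_include_cg: bool = True
    bootstrap_replicates: int = 200
    seed: int = 0
    ranking_metrics: tuple = ranking.DEFAULT_RANKING_METRICS

    def validate(self) -> None:
        if self.input_dir is None and self.simulation is None:
            raise PipelineError("config", "neither input_dir nor a simulation block given")
        if self.cohort not in ("growing", "ewe"):
            raise PipelineError("config", f"unknown cohort {self.cohort!r}")
        for name in ("ch4_min", "co2_max", "sd_multiple"):
            if getattr(self, name) <= 0:
                raise PipelineError("config", f"threshold {name} must be positive")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(outdir)
    exclusions = []

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as err:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(name, str(err)) from err

    def _simulate():
        if config.simulation is not None:
            sim = config.simulation
            sim.cohort = config.cohort
            bundle = simulate_flocks(sim)
            write_bundle(bundle, outdir / "input", config_to_dict(sim))
            log.event("simulate", "generated dataset bundle",
                      n_records=len(bundle["emissions"]), seed=sim.seed)
            return bundle
        bundle = read_bundle(config.input_dir)
        if "emissions" not in bundle or "animals" not in bundle:
            raise PipelineError("load", f"missing emissions/animals in {config.input_dir}")
        log.event("load", "read dataset bundle", path=str(config.input_dir))
        return bundle

    bundle = _stage("simulate", _simulate)

    def _qc():
        rec = bundle["emissions"]
        n0 = len(rec)
        rec, e = qc.filter_cohort_eligibility(rec); exclusions.append(e)
        rec, e = qc.assign_contemporary_groups(rec); exclusions.append(e)
        rec, e = qc.apply_emission_filters(
            rec, cohort=config.cohort, ch4_min=config.ch4_min,
            co2_max=config.co2_max, sd_multiple=config.sd_multiple)
        exclusions.append(e)
        rec, e = qc.filter_small_groups(rec, config.min_group_size); exclusions.append(e)
        rec, e = qc.apply_weight_and_window_filters(
            rec, dmi=bundle.get("dmi"), carcass=bundle.get("carcass"),
            ct=bundle.get("ct"))
        exclusions.append(e)
        log.event("qc", "editing complete", n_in=n0, n_out=len(rec))
        return rec

    records = _stage("qc", _qc)

    def _covariates():
        cov = compute_covariates(bundle["animals"], records, bundle.get("weights"))
        cov, e = qc.apply_adg_filter(cov)
        exclusions.append(e)
        write_table(cov, outdir / "covariates.csv")
        log.event("covariates", "derived", n=len(cov))
        return cov

    covariates = _stage("covariates", _covariates)
    write_table(records, outdir / "records_qc.csv")

    def _traits():
        traits = metrics.compute_ratio_traits(records, covariates)
        summary = metrics.trait_summary(traits)
        write_table(traits, outdir / "traits.csv")
        write_table(summary, outdir / "trait_summary.csv")
        log.event("traits", "ratio traits computed", n=len(traits))
        return traits

    traits = _stage("traits", _traits)

    def _residual():
        frame = residual.prepare_model_frame(records, covariates,
                                             bundle["animals"], config.cohort)
        rmt, fits = residual.derive_all_residual_traits(frame, config.cohort,
                                                        mode=config.rmt_mode)
        write_table(rmt, outdir / "residual_traits.csv")
        fitdir = outdir / "fits"
        fitdir.mkdir(exist_ok=True)
        for name, fit in fits.items():
            safe = name.replace("+", "_")
            pd.DataFrame({"estimate": fit.beta, "se": fit.beta_se}).to_csv(
                fitdir / f"{safe}_fixed_effects.csv")
            pd.Series(fit.varcomps).to_csv(fitdir / f"{safe}_varcomps.csv",
                                           header=["estimate"])
            log.event("residual", f"fitted {name}", n=fit.n,
                      iterations=fit.n_iterations, converged=fit.converged)
        return frame, rmt, fits

    frame, rmt, fits = _stage("residual", _residual)

    def _repeatability():
        cg = "cg_key" if config.repeatability_include_cg else None
        res = estimate_repeatability(
            records, "ch4_g_d", contemporary_group=cg,
            n_bootstrap=config.bootstrap_replicates, seed=config.seed)
        df = pd.DataFrame([{"trait": "ch4_g_d", "R": res["R"], "SE": res["SE"]}])
        write_table(df, outdir / "repeatability.csv")
        log.event("repeatability", "estimated", R=res["R"], SE=res["SE"])
        return res

    _stage("repeatability", _repeatability)

    merged = traits.merge(rmt, on="record_id", how="left")

    def _correlations():
        ratio_cols = (metrics.GROWING_RATIOS if config.cohort == "growing"
                      else metrics.EWE_RATIOS)
        cols = ["ch4_g_d", *ratio_cols, *[c for c in rmt.columns if c != "record_id"]]
        cols = [c for c in cols if c in merged.columns and merged[c].notna().sum() >= 3]
        table = ranking.correlation_table(merged, cols)
        write_table(table, outdir / "correlations.csv")
        log.event("correlations", "computed", n_pairs=len(table))
        return table

    _stage("correlations", _correlations)

    def _ranking():
        data = merged.merge(
            records[["record_id", "body_weight_kg", "dmi_kg_d"]]
            if "dmi_kg_d" in records.columns
            else records[["record_id", "body_weight_kg"]],
            on="record_id", how="left")
        group_traits = ["dmi_kg_d", "ch4_g_d", "body_weight_kg"]
        if config.cohort == "growing":
            ww = bundle["animals"][["animal_id", "weaning_weight_kg"]] \
                if "weaning_weight_kg" in bundle["animals"].columns else None
            if ww is not None:
                data = data.merge(ww, on="animal_id", how="left")
                group_traits.append("weaning_weight_kg")
        elif "maternal" in bundle and len(bundle["maternal"]):
            data = data.merge(
                bundle["maternal"][["animal_id", "n_lambs_born", "n_lambs_reared"]],
                on="animal_id", how="left")
            group_traits += ["n_lambs_born", "n_lambs_reared"]
        want = [m for m in config.ranking_metrics if m in data.columns]
        if len(want) < len(config.ranking_metrics):
            log.event("ranking", "skipped: metrics unavailable",
                      missing=[m for m in config.ranking_metrics if m not in data.columns])
            return None
        try:
            report = ranking.rank_top_quartile(data, metrics=want,
                                               group_traits=tuple(group_traits))
        except ValueError as err:
            log.event("ranking", f"skipped: {err}")
            return None
        write_table(report, outdir / "ranking_report.csv")
        letters = report.attrs.get("letters", {})
        if letters:
            rows = [{"trait": t, "metric": m, "letters": l}
                    for t, d in letters.items() for m, l in d.items()]
            write_table(pd.DataFrame(rows), outdir / "ranking_significance.csv")
        log.event("ranking", "top-quartile comparison done", n_metrics=len(want))
        return report

    _stage("ranking", _ranking)

    non_empty = [e for e in exclusions if len(e)]
    if non_empty:
        allx = pd.concat(non_empty, ignore_index=True)
    else:
        allx = pd.DataFrame(columns=["record_id", "table", "rule", "value"])
    write_table(allx, outdir / "exclusions.csv")
    log.event("done", "pipeline complete", n_exclusions=len(allx))
    return outdir


def config_from_yaml(d: dict) -> PipelineConfig:
    d = dict(d)
    sim = d.pop("simulation", None)
    cfg = PipelineConfig(**{k: v for k, v in d.items()
                            if k in {f.name for f in dataclasses.fields(PipelineConfig)}})
    if sim is not None:
        sim = dict(sim)
        if "body_weight" in sim and "window" in sim["body_weight"]:
            sim["body_weight"]["window"] = tuple(sim["body_weight"]["window"])
        if "records_per_animal" in sim:
            sim["records_per_animal"] = {int(k): v
                                         for k, v in sim["records_per_animal"].items()}
        for lit in ("birth_litter_effects", "rearing_litter_effects"):
            fe = sim.get("fixed_effects", {})
            if lit in fe:
                fe[lit] = {int(k): v for k, v in fe[lit].items()}
        cfg.simulation = SimulationConfig(**sim)
    return cfg
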