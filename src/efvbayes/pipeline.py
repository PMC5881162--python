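"""End-to-end driver: calibrate → simulate → train → ROC → verify.

Stages, mirroring the published workflow:

1. Calibrate per-phenotype population specs to the PK summary targets.
2. Simulate verification cohorts (default 10×30 per phenotype) on a dense
   0–72 h grid and summarize AUC/Cmax/CL with predicted:observed ratios.
3. Simulate training cohorts (default 10×500 per phenotype) at the candidate
   sampling times and fit the binned conditional table at every time.
4. Compute per-time ROC points (in-sample, development style) and select the
   optimal sampling time for the target phenotype by Youden's J.
5. Simulate a blinded mixed cohort (default 100 subjects at the normalized
   published phenotype frequencies), classify it at the optimal time without
   the labels, then join the held-out truths and score.

All randomness descends from the single master seed; every output file is a
deterministic function of (resolved config, seed).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, evaluation, plots, popsim
from .config import RunConfig
from .dataset import CohortDataset, write_cohort_csv
from .phenotype import PHENOTYPES, Phenotype

log = logging.getLogger("efvbayes")

_TRAIN_STREAM, _VERIFY_STREAM, _BLIND_STREAM = 0, 10, 20


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _fmt(df: pd.DataFrame, path: Path, prob_cols=(), conc_cols=()) -> None:
    out = df.copy()
    for c in prob_cols:
        if c in out:
            out[c] = out[c].map(lambda x: f"{x:.4f}" if pd.notna(x) else "")
    for c in conc_cols:
        if c in out:
            out[c] = out[c].map(lambda x: f"{x:.1f}" if pd.notna(x) else "")
    out.to_csv(path, index=False)


def _targets_dict(cfg: RunConfig, field: str):
    src = getattr(cfg, field)
    if src is None:
        return None
    return {Phenotype(ph): t.model_dump() for ph, t in src.items()}


def run_pipeline(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    results: dict = {}
    stage = "calibrate"
    try:
        specs = popsim.calibrate_population(
            _targets_dict(config, "calibration_targets"),
            dose=config.dose_mg,
            cv_v=config.cv_v,
            cv_ka=config.cv_ka,
            mean_ka=config.mean_ka,
        )
        results["specs"] = specs
        spec_payload = {
            ph.value: {
                k: getattr(specs[ph], k)
                for k in ("mean_cl", "cv_cl", "mean_v", "cv_v", "mean_ka", "cv_ka")
            }
            for ph in specs
        }
        (outdir / "population_specs.json").write_text(
            json.dumps(spec_payload, indent=2), encoding="utf-8"
        )
        log.info("calibrate: %d phenotype specs", len(specs))

        stage = "verify_pk"
        dense = config.dense_times()
        verify = {}
        for ph in PHENOTYPES:
            ds = popsim.simulate_cohort(
                specs[ph],
                dose=config.dose_mg,
                times=dense,
                n_trials=config.verify_design.n_trials,
                n_per_trial=config.verify_design.n_per_trial,
                seed=config.seed,
                id_prefix=ph.value,
                stream_offset=_VERIFY_STREAM,
            )
            verify[ph.value] = ds
            log.info("verify_pk: %s cohort %d records", ph.value, len(ds.df))
        summaries = {}
        for ph in PHENOTYPES:
            summaries.update(
                popsim.summarize_pk(
                    verify[ph.value], observed=_targets_dict(config, "observed_reference")
                )
            )
        results["pk_summaries"] = summaries
        _fmt(
            popsim.summary_table(summaries),
            outdir / "pk_summary.csv",
            prob_cols=("ratio_pred_obs",),
            conc_cols=("predicted_mean", "ci_low", "ci_high"),
        )
        plots.plot_concentration_bands(verify, outdir / "concentration_time.png")

        stage = "simulate_training"
        frames = []
        for ph in PHENOTYPES:
            ds = popsim.simulate_cohort(
                specs[ph],
                dose=config.dose_mg,
                times=config.sampling_times_h,
                n_trials=config.train_design.n_trials,
                n_per_trial=config.train_design.n_per_trial,
                seed=config.seed,
                id_prefix=ph.value,
                stream_offset=_TRAIN_STREAM,
            )
            frames.append(ds.df)
        training = CohortDataset(
            df=pd.concat(frames, ignore_index=True),
            dose=config.dose_mg,
            design=(config.train_design.n_trials, 3 * config.train_design.n_per_trial),
            seed=config.seed,
        )
        results["training"] = training
        write_cohort_csv(training, outdir / "training_cohort.csv")
        log.info("simulate_training: %d records, %d subjects", len(training.df), training.n_subjects)

        stage = "roc"
        priors = (
            {Phenotype(k): v for k, v in config.priors.items()} if config.priors else None
        )
        clf_kwargs = dict(
            bin_width=config.bin_width,
            smoothing=config.smoothing,
            guard_bins=config.guard_bins,
            priors=priors,
        )
        roc = evaluation.roc_over_times(
            training, training, config.sampling_times_h, **clf_kwargs
        )
        results["roc"] = roc
        _fmt(
            evaluation.roc_frame(roc),
            outdir / "roc.csv",
            prob_cols=("tpr", "fpr", "youden_j"),
        )
        target = Phenotype(config.target_phenotype)
        optimal_time = evaluation.select_optimal_time(roc, target)
        results["optimal_time"] = optimal_time
        log.info("roc: optimal sampling time for %s = %g h", target.value, optimal_time)

        stage = "train_model"
        table = bayes.fit_conditional_table(training, optimal_time, **clf_kwargs)
        results["model"] = table
        table.to_json(outdir / "model.json")
        curve = bayes.posterior_curve(table)
        results["posterior_curve"] = curve
        curve_df = pd.DataFrame(
            {
                "bin_center": curve.bin_centers,
                **{f"p_{ph.value.lower()}": curve.posteriors[ph] for ph in PHENOTYPES},
                "populated": curve.populated,
            }
        )
        _fmt(
            curve_df,
            outdir / "posterior_curve.csv",
            prob_cols=[f"p_{ph.value.lower()}" for ph in PHENOTYPES],
            conc_cols=("bin_center",),
        )
        plots.plot_posterior_curve(curve, outdir / "posterior_curve.png")
        ranges = bayes.phenotype_concentration_ranges(curve)
        results["ranges"] = ranges
        (outdir / "phenotype_ranges.json").write_text(
            json.dumps({ph.value: ranges[ph] for ph in PHENOTYPES}, indent=2),
            encoding="utf-8",
        )

        stage = "simulate_blinded"
        blinded_full = popsim.simulate_cohort(
            specs,
            dose=config.dose_mg,
            times=config.sampling_times_h,
            n_trials=1,
            n_per_trial=config.blinded_n,
            phenotype_mix=config.normalized_frequencies(),
            seed=config.seed,
            id_prefix="blind",
            stream_offset=_BLIND_STREAM,
        )
        truths = blinded_full.subject_phenotypes()
        blinded = blinded_full.blinded()
        write_cohort_csv(blinded, outdir / "blinded_cohort.csv")
        truths.rename("phenotype").to_csv(outdir / "blinded_truth.csv")
        log.info("simulate_blinded: %d subjects", blinded.n_subjects)

        stage = "evaluate"
        calls, matrix, perf = evaluation.evaluate_cohort(table, blinded, truths)
        results["calls"], results["confusion"], results["performance"] = calls, matrix, perf
        _fmt(
            evaluation.calls_frame(calls),
            outdir / "calls.csv",
            prob_cols=[f"p_{ph.value.lower()}" for ph in PHENOTYPES],
        )
        matrix.frame().to_csv(outdir / "confusion.csv")
        matrix.normalized().round(4).to_csv(outdir / "confusion_normalized.csv")
        _fmt(
            perf.frame(),
            outdir / "performance.csv",
            prob_cols=("true_positive_prob", "true_negative_prob", "false_positive_prob"),
        )
        undefined = [ph.value for ph in matrix.undefined_rows()]
        if undefined:
            log.warning("evaluate: undefined confusion rows (no subjects): %s", undefined)

        target_perf = perf.per_phenotype[target]
        summary = {
            "optimal_time_h": optimal_time,
            "target_phenotype": target.value,
            "youden_j_by_time": {
                f"{p.sampling_time:g}": round(p.youden_j, 4)
                for p in roc
                if p.phenotype is target
            },
            "in_sample_tpr_at_optimal": round(
                next(
                    p.tpr for p in roc if p.phenotype is target and p.sampling_time == optimal_time
                ),
                4,
            ),
            "blinded_tpr": None
            if target_perf.true_positive_prob is None
            else round(target_perf.true_positive_prob, 4),
            "blinded_tnr": None
            if target_perf.true_negative_prob is None
            else round(target_perf.true_negative_prob, 4),
            "undefined_confusion_rows": undefined,
        }
        (outdir / "run_summary.json").write_text(
            json.dumps(summary, indent=2), encoding="utf-8"
        )
        results["summary"] = summary
        log.info("evaluate: blinded %s tpr=%s tnr=%s", target.value, summary["blinded_tpr"], summary["blinded_tnr"])
        return results
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %r failed with config %s", stage, config.model_dump(mode="json"))
        raise PipelineError(stage, exc) from exc
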