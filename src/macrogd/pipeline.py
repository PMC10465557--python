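"""End-to-end orchestration: filter -> grid -> diversity -> statistics ->
spatial model -> prediction -> extrapolation mask.

Every stage writes its table under the configured output directory and a
run manifest records the configuration, seeds, stage log and package
versions.  A stage failure raises :class:`PipelineError` naming the
stage; tables already written are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bold_io, diversity, env_model, gridding, mess, spatial_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (one structured file)."""

    records_tsv: str
    env_csv: str
    output_dir: str
    invasive_csv: str | None = None
    resolution: float = 193_000.0
    min_otus: int = 10
    min_copies: int = 3
    seed: int = 0
    literal_evenness: bool = False
    logit_gde: bool = False
    response: str = "gdm"  # or "gde"
    run_model: bool = True
    predictors: list[str] | None = None
    collinearity_threshold: float = 0.75
    train_fraction: float = 0.75
    n_knots: int = 25
    mcmc_steps: int = 1600
    mcmc_burn: int = 700
    mcmc_walkers: int = 20
    n_draws: int = 800
    moran_permutations: int = 1000
    stat_min_cells: int = 10

    def __post_init__(self) -> None:
        if self.min_otus not in diversity.OTU_THRESHOLDS:
            raise ValueError(f"min_otus must be one of {diversity.OTU_THRESHOLDS}")
        if float(self.resolution) not in gridding.RESOLUTIONS:
            raise ValueError(f"resolution must be one of {gridding.RESOLUTIONS}")
        if self.response not in ("gdm", "gde"):
            raise ValueError("response must be 'gdm' or 'gde'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.12g", **kw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": {"macrogd": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": [],
    }

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    stage = "filter"
    try:
        records, n_malformed = bold_io.read_records(config.records_tsv)
        invasive = (
            bold_io.read_invasive_list(config.invasive_csv) if config.invasive_csv else set()
        )
        filtered, report = bold_io.apply_filters(records, invasive)
        report.n_malformed = n_malformed
        with open(out / "filter_report.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=1, sort_keys=True)
        done(stage, n_input=report.n_input, retained=report.retained)

        stage = "grid"
        grid = gridding.GridSpec(cell_size=float(config.resolution))
        assigned = gridding.assign_cells(filtered, grid)
        cell_tab = gridding.cell_table(assigned, grid).set_index("cell")
        _csv(cell_tab, out / "cells.csv")
        done(stage, n_cells_touched=len(cell_tab))

        stage = "diversity"
        summaries, otu_div = diversity.summarize_cells(
            assigned,
            min_otus=config.min_otus,
            min_copies=config.min_copies,
            literal_evenness=config.literal_evenness,
        )
        _csv(summaries.set_index("cell"), out / "cell_summaries.csv")
        _csv(otu_div, out / "otu_diversity.csv", index=False)
        per_otu, occ_hist = diversity.occupancy_table(assigned)
        _csv(occ_hist.rename_axis("n_cells_occupied").to_frame(), out / "occupancy.csv")
        done(stage, n_cells=len(summaries), n_otus=int(otu_div["otu_id"].nunique()) if len(otu_div) else 0)
        if len(summaries) == 0:
            done("stopped", after="diversity", reason="no cells pass the OTU threshold")
            return out

        stage = "stats"
        summaries = summaries.merge(
            cell_tab[["centroid_lat", "centroid_lon", "continent"]], on="cell"
        )
        coords = gridding.cell_coords(summaries["cell"].tolist(), grid)
        stats_rows = []
        if len(summaries) >= config.stat_min_cells:
            for metric in ("gdm", "gde"):
                vals = summaries[metric].to_numpy()
                if np.ptp(vals[np.isfinite(vals)]) == 0:
                    continue
                tests = spatial_stats.quadratic_latitude_test(
                    vals, summaries["centroid_lat"].to_numpy(), coords
                )
                for term, res in tests.items():
                    stats_rows.append(
                        {"model": f"{metric} ~ latitude" + ("^2" if term == "quadratic" else ""),
                         "term": term, "r": res.r, "F": res.F, "dof": res.dof, "p": res.p}
                    )
            try:
                res = spatial_stats.modified_ttest(
                    summaries["gdm"].to_numpy(), summaries["gde"].to_numpy(), coords
                )
                stats_rows.append(
                    {"model": "gdm ~ gde", "term": "linear", "r": res.r, "F": res.F,
                     "dof": res.dof, "p": res.p}
                )
            except ValueError as exc:
                logger.warning("gdm~gde test skipped: %s", exc)
        _csv(pd.DataFrame(stats_rows), out / "correlation_tests.csv", index=False)
        _csv(
            spatial_stats.pearson_sampling_checks(summaries, otu_div),
            out / "sampling_checks.csv",
            index=False,
        )
        done(stage, n_tests=len(stats_rows))

        stage = "environment"
        env = pd.read_csv(config.env_csv, index_col="cell")
        missing_cells = [c for c in summaries["cell"] if c not in env.index]
        if missing_cells:
            raise ValueError(f"{len(missing_cells)} cells lack environment rows")
        env_cells = env.loc[summaries["cell"]]
        if "mtcm" in env_cells:
            summaries["freeze"] = env_model.freeze_from_mtcm(env_cells["mtcm"].to_numpy())
            if summaries["freeze"].nunique() == 2 and len(summaries) >= config.stat_min_cells:
                for metric in ("gdm", "gde"):
                    try:
                        res = env_model.freeze_test(
                            summaries[metric].to_numpy(), summaries["freeze"].to_numpy(), coords
                        )
                        stats_rows.append(
                            {"model": f"{metric} ~ freeze", "term": "binary", "r": res.r,
                             "F": res.F, "dof": res.dof, "p": res.p}
                        )
                    except ValueError as exc:
                        logger.warning("freeze test skipped for %s: %s", metric, exc)
                _csv(pd.DataFrame(stats_rows), out / "correlation_tests.csv", index=False)
        done(stage, n_env_cells=len(env))

        if not config.run_model:
            done("stopped", after="environment", reason="model stage disabled")
            return out

        stage = "model"
        predictors = config.predictors or [c for c in env.columns]
        retained, _corr = env_model.prune_collinear(
            env_cells[predictors], threshold=config.collinearity_threshold, priority=predictors
        )
        cells_df = summaries.set_index("cell")
        train_idx, test_idx = env_model.split_train_test(
            cells_df, fraction=config.train_fraction, seed=config.seed
        )
        if len(train_idx) < 10:
            done("stopped", after="model", reason="too few training cells for regression")
            return out
        env_z, scaler = env_model.standardize(env[retained], train_index=train_idx)
        y_all = cells_df[config.response].astype(float)
        if config.response == "gde" and config.logit_gde:
            y_all = np.log(y_all / (1 - y_all.clip(upper=1 - 1e-9)))
        sel, path = env_model.select_variables(
            env_z.loc[train_idx], y_all.loc[train_idx], seed=config.seed
        )
        if not sel:
            sel = retained[:1]
        _csv(path, out / "selection_path.csv", index=False)
        fit = env_model.fit_spatial_glmm(
            y_all.loc[train_idx].to_numpy(),
            env_z.loc[train_idx, sel],
            gridding.cell_coords(list(train_idx), grid),
            mcmc=env_model.MCMCConfig(
                n_walkers=config.mcmc_walkers,
                n_steps=config.mcmc_steps,
                n_burn=config.mcmc_burn,
                n_draws=config.n_draws,
                seed=config.seed,
            ),
            n_knots=config.n_knots,
        )
        r2 = env_model.bayesian_r2(fit)
        overlap = env_model.prior_posterior_overlap(fit) if fit.n_draws >= 400 else {}
        fit_rows = [
            {"parameter": "intercept", "median": float(np.median(fit.intercept)),
             **dict(zip(("hdi_low", "hdi_high"), env_model.hdi(fit.intercept)))},
            {"parameter": "sigma", "median": float(np.median(fit.sigma)),
             **dict(zip(("hdi_low", "hdi_high"), env_model.hdi(fit.sigma)))},
            {"parameter": "field_sd", "median": float(np.median(fit.field_sd)),
             **dict(zip(("hdi_low", "hdi_high"), env_model.hdi(fit.field_sd)))},
        ]
        for j, name in enumerate(fit.predictors):
            fit_rows.append(
                {"parameter": f"beta_{name}", "median": float(np.median(fit.beta[:, j])),
                 **dict(zip(("hdi_low", "hdi_high"), env_model.hdi(fit.beta[:, j])))}
            )
        fit_df = pd.DataFrame(fit_rows)
        fit_df["prior_posterior_overlap_pct"] = [
            overlap.get(r_["parameter"], np.nan) for r_ in fit_rows
        ]
        fit_df["r2_median"] = r2["median"]
        fit_df["converged"] = fit.converged
        _csv(fit_df, out / "fit_summary.csv", index=False)

        # residual autocorrelation on training cells
        resid = y_all.loc[train_idx].to_numpy() - (
            np.median(fit.intercept)
            + np.asarray(env_z.loc[train_idx, sel]) @ np.median(fit.beta, axis=0)
            + np.median(fit.w, axis=0)
        )
        moran = spatial_stats.morans_i(
            resid,
            gridding.cell_coords(list(train_idx), grid),
            k=min(8, len(train_idx) - 1),
            n_perm=config.moran_permutations,
            seed=config.seed,
        )
        done(stage, converged=fit.converged, r2_median=r2["median"],
             moran_i=moran.I, moran_p=moran.p, selected=sel)

        stage = "predict"
        test_metrics = {}
        if len(test_idx) >= 3:
            pred_test = env_model.predict_cells(
                fit,
                env_z.loc[test_idx, sel],
                gridding.cell_coords(list(test_idx), grid),
                n_draws=min(500, fit.n_draws),
                seed=config.seed,
                allow_unconverged=True,
            )
            obs = y_all.loc[test_idx].to_numpy()
            test_metrics = bias_precision(pred_test["median"].to_numpy(), obs)
            with open(out / "test_metrics.json", "w") as fh:
                json.dump(test_metrics, fh, indent=1, sort_keys=True)
        pred_all = env_model.predict_cells(
            fit,
            env_z.loc[:, sel],
            gridding.cell_coords(list(env_z.index), grid),
            n_draws=min(500, fit.n_draws),
            seed=config.seed,
            allow_unconverged=True,
        )
        done(stage, n_prediction_cells=len(pred_all), **test_metrics)

        stage = "mask"
        masked = mess.mask_predictions(
            pred_all, env_z.loc[train_idx, sel], env_z.loc[:, sel]
        )
        _csv(masked.rename_axis("cell"), out / "predictions.csv")
        done(stage, n_masked=int(masked["non_analog"].sum()))
        return out
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError(stage, exc) from exc


def bias_precision(predicted: np.ndarray, observed: np.ndarray) -> dict:
    """Bias/precision of predictions against observations: OLS slope and
    intercept of observed ~ predicted, R^2 and RMSE.  Minimal bias shows as
    slope near 1 with intercept near 0."""
    slope, intercept = np.polyfit(predicted, observed, 1)
    resid = observed - (slope * predicted + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "rmse": float(np.sqrt(np.mean((observed - predicted) ** 2))),
    }


def threshold_sweep(config: PipelineConfig, thresholds=diversity.OTU_THRESHOLDS) -> pd.DataFrame:
    """Re-run diversity + model across minimum-OTU thresholds.

    Writes each run under ``<output_dir>/threshold_<t>`` and returns a
    comparison table of cells retained and prediction bias/precision —
    the basis for picking the threshold with slope near 1, intercept near
    0, high R^2 and low RMSE.
    """
    rows = []
    base = Path(config.output_dir)
    for t in thresholds:
        sub = dataclasses.replace(config, min_otus=int(t), output_dir=str(base / f"threshold_{t}"))
        out = run_pipeline(sub)
        row = {"min_otus": int(t), "n_cells": 0}
        summaries = out / "cell_summaries.csv"
        if summaries.exists():
            row["n_cells"] = len(pd.read_csv(summaries))
        metrics = out / "test_metrics.json"
        if metrics.exists():
            row.update(json.load(open(metrics)))
        rows.append(row)
    df = pd.DataFrame(rows)
    _csv(df, base / "threshold_sweep.csv", index=False)
    return df
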