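"""End-to-end analysis pipeline and report generation.

Stages, in the order they run:

1. load or simulate a trial table;
2. per-cell +/-3 SD outlier pass (accounted, never silent);
3. restriction to the comparison grid (the +/-30 deg azimuth columns are
   dropped so azimuth and elevation cover the same +/-20 deg range);
4. per-subject and pooled per-target bivariate summaries for A, V, VA;
5. the MLE condition: per-target fusion of the two unimodal summaries,
   treated downstream exactly like an observed modality;
6. precision/accuracy measures (VE, CE, ellipse orientation deviation,
   error-vector direction deviation) per subject and target, then averaged
   over subjects;
7. integration metrics (redundancy gain, inverse effectiveness, visual
   weights, hierarchical regressions, observed-vs-predicted comparisons);
8. tables, a condition-by-measure summary, affine maps, distortion grids,
   optional plots, and a run log.

Aggregation conventions (package design choices): subject-level measures
and weights are averaged across subjects, matching a subject-level
analysis; the observed-vs-predicted field comparison uses pooled
per-target summaries, whose fusion is essentially free of the
small-sample Jensen bias that per-subject variance estimates would leak
into the prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy import AffineMap, DistortionGrid, distortion_grid, error_vector_table, fit_affine
from .dataset_io import (ResponseDataset, RemovalReport, filter_outliers,
                         read_responses, select_subset, write_responses)
from .dispersion import axial_deviation, ellipse_table, estimate_distribution_table
from .fusion import predict_bimodal_field
from .integration import (CorrelationResult, FieldComparison, compare_fields,
                          hierarchical_regression, inverse_effectiveness,
                          redundancy_gain)
from .synth import GeneratorConfig, default_config, simulate_dataset

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "IntegrationReport",
    "CONDITIONS",
    "analyze_dataset",
    "run_pipeline",
]

CONDITIONS = ("A", "V", "VA", "MLE")
MEASURES = ("ve", "ce", "orientation_dev", "direction_dev")


@dataclass(frozen=True)
class PipelineConfig:
    """One pipeline run: exactly one of input_path / generator."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    outlier_k: float = 3.0
    coverage: float = 0.95
    exclude_az30: bool = True
    out_dir: str | None = None
    make_plots: bool = False
    seed: int | None = None     # overrides generator seed when simulating

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("specify exactly one of input_path / generator")


@dataclass(frozen=True)
class IntegrationReport:
    """Integration metrics over the comparison grid."""

    rg_per_target: pd.DataFrame          # target_id, rg_observed, rg_predicted
    rg_observed_mean: float
    rg_predicted_mean: float
    ie_observed: CorrelationResult       # RG_obs vs pooled visual 2D variance
    ie_predicted: CorrelationResult
    weights_per_target: pd.DataFrame     # target_id, w_visual_x/_y/_scalar
    wv_azimuth_axis_mean: float          # mean per-axis Eq.-2 weight, x
    wv_elevation_axis_mean: float
    weight_accuracy_correlation: CorrelationResult
    precision_accuracy_correlation: CorrelationResult
    regression_observed: list
    regression_predicted: list
    vif: pd.Series
    precision_comparison: FieldComparison   # observed vs predicted VE, pooled
    accuracy_comparison: FieldComparison    # observed vs predicted CE


@dataclass
class PipelineResult:
    dataset: ResponseDataset
    removal: RemovalReport
    analysis: ResponseDataset               # after outlier pass + grid restriction
    per_subject: dict[str, pd.DataFrame]    # condition -> subject x target summaries
    pooled: dict[str, pd.DataFrame]         # condition -> per-target summary table
    measures: pd.DataFrame                  # per-target subject-mean measures (long)
    condition_table: pd.DataFrame           # measures x conditions, "mean (sd)"
    integration: IntegrationReport
    affine: dict[str, AffineMap]
    distortion: dict[str, DistortionGrid]
    config: PipelineConfig
    out_dir: Path | None = None
    written: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# measure computation


def _with_geometry(summaries: pd.DataFrame, grid, coverage: float) -> pd.DataFrame:
    """Attach ellipse geometry, error vectors and scalar measures."""
    out = ellipse_table(summaries, coverage=coverage)
    out = error_vector_table(out, grid)
    out["ve"] = np.sqrt(out["sigma_xy2"])
    out["ce"] = out["r"]
    central = (out["az_deg"] == 0) & (out["el_deg"] == 0)
    tdir = np.degrees(np.arctan2(out["el_deg"], out["az_deg"])) % 180.0
    dev = axial_deviation(out["theta_deg"].to_numpy(), tdir.to_numpy())
    out["orientation_dev"] = np.where(
        central.to_numpy() | ~out["orientation_defined"].to_numpy(), np.nan, dev
    )
    out["direction_dev"] = out["axial_dev_deg"]
    out["direction_dev_circular"] = out["circular_dev_deg"]
    return out


def _subject_condition_tables(frame: pd.DataFrame, grid,
                              coverage: float) -> dict[str, pd.DataFrame]:
    """Per-subject per-target geometric summaries for A, V, VA and MLE."""
    by = ["subject", "target_id"]
    tables: dict[str, pd.DataFrame] = {}
    for mod in ("A", "V", "VA"):
        sub = frame[frame["modality"] == mod]
        if not len(sub):
            continue
        tables[mod] = estimate_distribution_table(sub, by=by)
    if "A" in tables and "V" in tables:
        tables["MLE"] = predict_bimodal_field(tables["V"], tables["A"], by=by)
    return {
        mod: _with_geometry(tab, grid, coverage) for mod, tab in tables.items()
    }


def _pooled_condition_tables(frame: pd.DataFrame, grid,
                             coverage: float) -> dict[str, pd.DataFrame]:
    by = ["target_id"]
    tables: dict[str, pd.DataFrame] = {}
    for mod in ("A", "V", "VA"):
        sub = frame[frame["modality"] == mod]
        if not len(sub):
            continue
        tables[mod] = estimate_distribution_table(sub, by=by)
    if "A" in tables and "V" in tables:
        tables["MLE"] = predict_bimodal_field(tables["V"], tables["A"], by=by)
    return {
        mod: _with_geometry(tab, grid, coverage) for mod, tab in tables.items()
    }


def _target_measures(per_subject: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Average subject-level measures per target; long format by condition."""
    rows = []
    for cond, tab in per_subject.items():
        cols = ["ve", "ce", "orientation_dev", "direction_dev",
                "direction_dev_circular"]
        extra = [c for c in ("w_visual_x", "w_visual_y", "w_visual")
                 if c in tab.columns]
        agg = tab.groupby("target_id")[cols + extra].mean().reset_index()
        agg.insert(0, "condition", cond)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


def _condition_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Measures x conditions summary with 'mean (sd)' cells over targets."""
    cells = {}
    for cond in CONDITIONS:
        sub = measures[measures["condition"] == cond]
        col = {}
        for m in MEASURES:
            vals = sub[m].dropna()
            col[m] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})" if len(vals) else ""
        cells[cond] = col
    out = pd.DataFrame(cells)
    out.index.name = "measure"
    return out


def _integration_report(per_subject: dict[str, pd.DataFrame],
                        pooled: dict[str, pd.DataFrame],
                        measures: pd.DataFrame) -> IntegrationReport:
    wide = measures.pivot(index="target_id", columns="condition")
    ve = wide["ve"]

    rg_obs = redundancy_gain(ve["V"].to_numpy(), ve["VA"].to_numpy())
    rg_pred = redundancy_gain(ve["V"].to_numpy(), ve["MLE"].to_numpy())
    rg_table = pd.DataFrame(
        {"target_id": ve.index, "rg_observed": rg_obs, "rg_predicted": rg_pred}
    )

    pooled_v = pooled["V"].set_index("target_id").loc[ve.index]
    ie_obs = inverse_effectiveness(rg_obs, pooled_v["ve"].to_numpy(), square=True)
    ie_pred = inverse_effectiveness(rg_pred, pooled_v["ve"].to_numpy(), square=True)

    mle = measures[measures["condition"] == "MLE"].set_index("target_id")
    weights = mle[["w_visual_x", "w_visual_y", "w_visual"]].reset_index()

    ce_va = wide["ce"]["VA"]
    w_scalar = mle["w_visual"].loc[ce_va.index]
    if w_scalar.std() > 0 and ce_va.std() > 0:
        from scipy import stats as _st
        r, p = _st.pearsonr(w_scalar, ce_va)
        w_acc = CorrelationResult(float(r), float(p), len(ce_va))
    else:
        w_acc = CorrelationResult(np.nan, np.nan, len(ce_va), defined=False)

    va_meas = measures[measures["condition"] == "VA"].set_index("target_id")
    if va_meas["ve"].std() > 0 and va_meas["ce"].std() > 0:
        from scipy import stats as _st
        r, p = _st.pearsonr(va_meas["ve"] ** 2, va_meas["ce"])
        prec_acc = CorrelationResult(float(r), float(p), len(va_meas))
    else:
        prec_acc = CorrelationResult(np.nan, np.nan, len(va_meas), defined=False)

    # hierarchical regressions on pooled per-target 2D variances
    idx = ve.index
    pred = pd.DataFrame(
        {
            "sigma_xy2_V": pooled["V"].set_index("target_id")["sigma_xy2"].loc[idx],
            "sigma_xy2_A": pooled["A"].set_index("target_id")["sigma_xy2"].loc[idx],
        }
    )
    reg_obs, vif = hierarchical_regression(
        pooled["VA"].set_index("target_id")["sigma_xy2"].loc[idx], pred
    )
    reg_pred, _ = hierarchical_regression(
        pooled["MLE"].set_index("target_id")["sigma_xy2"].loc[idx], pred
    )

    # observed vs predicted fields on pooled summaries
    prec_cmp = compare_fields(
        pooled["VA"].set_index("target_id")["ve"].loc[idx],
        pooled["MLE"].set_index("target_id")["ve"].loc[idx],
    )
    acc_cmp = compare_fields(
        pooled["VA"].set_index("target_id")["ce"].loc[idx],
        pooled["MLE"].set_index("target_id")["ce"].loc[idx],
    )

    return IntegrationReport(
        rg_per_target=rg_table,
        rg_observed_mean=float(np.mean(rg_obs)),
        rg_predicted_mean=float(np.mean(rg_pred)),
        ie_observed=ie_obs,
        ie_predicted=ie_pred,
        weights_per_target=weights,
        wv_azimuth_axis_mean=float(mle["w_visual_x"].mean()),
        wv_elevation_axis_mean=float(mle["w_visual_y"].mean()),
        weight_accuracy_correlation=w_acc,
        precision_accuracy_correlation=prec_acc,
        regression_observed=reg_obs,
        regression_predicted=reg_pred,
        vif=vif,
        precision_comparison=prec_cmp,
        accuracy_comparison=acc_cmp,
    )


def analyze_dataset(dataset: ResponseDataset,
                    outlier_k: float = 3.0,
                    coverage: float = 0.95,
                    exclude_az30: bool = True):
    """Run stages 2-7 on an in-memory dataset.

    Returns ``(analysis_dataset, removal, per_subject, pooled, measures,
    integration)``; ``run_pipeline`` wraps this with IO and artifacts.
    """
    filtered, removal = filter_outliers(dataset, k=outlier_k)
    analysis = (
        select_subset(filtered, max_abs_azimuth=20.0) if exclude_az30 else filtered
    )
    frame = analysis.frame
    per_subject = _subject_condition_tables(frame, analysis.grid, coverage)
    pooled = _pooled_condition_tables(frame, analysis.grid, coverage)
    measures = _target_measures(per_subject)
    integration = _integration_report(per_subject, pooled, measures)
    return analysis, removal, per_subject, pooled, measures, integration


def _affine_and_distortion(pooled: dict[str, pd.DataFrame], grid):
    affine: dict[str, AffineMap] = {}
    distortion: dict[str, DistortionGrid] = {}
    for cond, tab in pooled.items():
        t = tab.set_index("target_id")
        ids = [tg.id for tg in grid if tg.id in t.index]
        targets = np.array([[grid[i].azimuth, grid[i].elevation] for i in ids])
        centroids = t.loc[ids, ["mu_x", "mu_y"]].to_numpy()
        if len(ids) >= 3:
            try:
                affine[cond] = fit_affine(targets, centroids)
            except np.linalg.LinAlgError:
                pass
        distortion[cond] = distortion_grid(
            {i: c for i, c in zip(ids, centroids)}, grid
        )
    return affine, distortion


# ---------------------------------------------------------------------------
# artifacts


def _format_integration(rep: IntegrationReport) -> str:
    lines = ["Integration report", "=" * 60]
    lines.append(
        f"Redundancy gain: observed mean {rep.rg_observed_mean:.2f}%, "
        f"predicted mean {rep.rg_predicted_mean:.2f}%"
    )
    lines.append(
        f"Inverse effectiveness (RG vs pooled visual 2D variance): "
        f"observed r={rep.ie_observed.r:.2f} (p={rep.ie_observed.p:.3g}), "
        f"predicted r={rep.ie_predicted.r:.2f} (p={rep.ie_predicted.p:.3g})"
    )
    lines.append(
        f"Visual weight: azimuth-axis mean {rep.wv_azimuth_axis_mean:.3f}, "
        f"elevation-axis mean {rep.wv_elevation_axis_mean:.3f}"
    )
    lines.append(
        f"W_V vs bimodal CE: r={rep.weight_accuracy_correlation.r:.2f} "
        f"(p={rep.weight_accuracy_correlation.p:.3g})"
    )
    lines.append(
        f"Bimodal precision vs accuracy: r={rep.precision_accuracy_correlation.r:.2f} "
        f"(p={rep.precision_accuracy_correlation.p:.3g})"
    )
    for label, steps in (("observed", rep.regression_observed),
                         ("predicted", rep.regression_predicted)):
        lines.append(f"Hierarchical regression ({label} bimodal 2D variance):")
        for st in steps:
            lines.append(
                f"  + {st.predictors[-1]}: R2={st.r2:.3f} adjR2={st.adj_r2:.3f} "
                f"dR2={st.r2_change:.3f} F={st.f_change:.2f} p={st.p_change:.3g}"
            )
    lines.append("VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in rep.vif.items()))
    pc = rep.precision_comparison
    lines.append(
        f"Observed vs predicted precision (pooled VE): mean diff "
        f"{pc.mean_difference:+.3f} deg, t={pc.t:.2f}, p={pc.p:.3g}, "
        f"r={pc.correlation.r:.2f}"
    )
    ac = rep.accuracy_comparison
    lines.append(
        f"Observed vs predicted accuracy (CE): mean diff "
        f"{ac.mean_difference:+.3f} deg, t={ac.t:.2f}, p={ac.p:.3g}, "
        f"r={ac.correlation.r:.2f}"
    )
    return "\n".join(lines) + "\n"


def _make_plots(result: "PipelineResult", out_dir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    written = []
    grid = result.analysis.grid
    pos = grid.positions

    fig, axes = plt.subplots(2, 2, figsize=(11, 8), sharex=True, sharey=True)
    for ax, cond in zip(axes.ravel(), CONDITIONS):
        if cond not in result.pooled:
            continue
        tab = result.pooled[cond]
        ax.plot(pos[:, 0], pos[:, 1], "k+", ms=5)
        for row in tab.itertuples():
            ax.add_patch(
                MplEllipse((row.mu_x, row.mu_y), 2 * row.a, 2 * row.b,
                           angle=row.theta_deg, fill=False, color="tab:blue",
                           lw=0.8)
            )
        ax.set_title(f"{cond}: 95% ellipses")
        ax.set_aspect("equal")
    fig.tight_layout()
    p = out_dir / "ellipse_maps.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    fig, axes = plt.subplots(2, 2, figsize=(11, 8), sharex=True, sharey=True)
    for ax, cond in zip(axes.ravel(), CONDITIONS):
        if cond not in result.pooled:
            continue
        tab = result.pooled[cond]
        ax.quiver(tab["az_deg"], tab["el_deg"],
                  tab["mu_x"] - tab["az_deg"], tab["mu_y"] - tab["el_deg"],
                  angles="xy", scale_units="xy", scale=1, color="tab:red",
                  width=0.004)
        ax.plot(pos[:, 0], pos[:, 1], "k+", ms=5)
        ax.set_title(f"{cond}: error vectors")
        ax.set_aspect("equal")
    fig.tight_layout()
    p = out_dir / "error_vectors.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    fig, axes = plt.subplots(2, 2, figsize=(11, 8), sharex=True, sharey=True)
    for ax, cond in zip(axes.ravel(), CONDITIONS):
        if cond not in result.distortion:
            continue
        tab = result.pooled[cond].set_index("target_id")
        for e in result.distortion[cond].edges.itertuples():
            xs = [tab.loc[e.id_a, "mu_x"], tab.loc[e.id_b, "mu_x"]]
            ys = [tab.loc[e.id_a, "mu_y"], tab.loc[e.id_b, "mu_y"]]
            ax.plot(xs, ys, "-", color="tab:green", lw=0.8)
        ax.plot(pos[:, 0], pos[:, 1], "k+", ms=5)
        ax.set_title(f"{cond}: distortion grid")
        ax.set_aspect("equal")
    fig.tight_layout()
    p = out_dir / "distortion_grids.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for j, cond in enumerate(CONDITIONS):
        sub = result.measures[result.measures["condition"] == cond]
        merged = sub.merge(grid.to_frame(), on="target_id")
        for i, metric in enumerate(("ve", "ce")):
            ax = axes[i, j]
            piv = merged.pivot(index="el_deg", columns="az_deg", values=metric)
            im = ax.imshow(piv.to_numpy()[::-1], cmap="coolwarm",
                           extent=[piv.columns.min(), piv.columns.max(),
                                   piv.index.min(), piv.index.max()])
            fig.colorbar(im, ax=ax, shrink=0.8)
            ax.set_title(f"{cond}: {'VE' if metric == 've' else 'CE'} (deg)")
    fig.tight_layout()
    p = out_dir / "field_heatmaps.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))
    return written


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline; write artifacts when an output dir is set."""
    if config.input_path is not None:
        dataset = read_responses(config.input_path)
    else:
        gen = config.generator
        if config.seed is not None:
            from dataclasses import replace
            gen = replace(gen, seed=config.seed)
        dataset = simulate_dataset(gen)

    analysis, removal, per_subject, pooled, measures, integration = analyze_dataset(
        dataset, outlier_k=config.outlier_k, coverage=config.coverage,
        exclude_az30=config.exclude_az30,
    )
    condition_table = _condition_table(measures)
    affine, distortion = _affine_and_distortion(pooled, analysis.grid)

    result = PipelineResult(
        dataset=dataset, removal=removal, analysis=analysis,
        per_subject=per_subject, pooled=pooled, measures=measures,
        condition_table=condition_table, integration=integration,
        affine=affine, distortion=distortion, config=config,
    )

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.out_dir = out_dir
        written = result.written

        for cond, tab in pooled.items():
            p = out_dir / f"summary_{cond}.csv"
            cols = ["target_id", "n", "mu_x", "mu_y", "sigma_x2", "sigma_y2",
                    "rho", "sigma_xy2", "a", "b", "theta_deg", "anisotropy",
                    "ve", "ce", "orientation_dev", "direction_dev"]
            tab[cols].to_csv(p, index=False, float_format="%.6f")
            written.append(str(p))
        p = out_dir / "measures_by_target.csv"
        measures.to_csv(p, index=False, float_format="%.6f")
        written.append(str(p))
        p = out_dir / "condition_table.csv"
        condition_table.to_csv(p)
        written.append(str(p))
        p = out_dir / "redundancy_gain.csv"
        integration.rg_per_target.to_csv(p, index=False, float_format="%.4f")
        written.append(str(p))
        p = out_dir / "visual_weights.csv"
        integration.weights_per_target.to_csv(p, index=False, float_format="%.4f")
        written.append(str(p))
        p = out_dir / "removal_report.csv"
        removal.per_cell.to_csv(p, index=False)
        written.append(str(p))
        p = out_dir / "integration_report.txt"
        p.write_text(_format_integration(integration))
        written.append(str(p))

        affine_rows = []
        for cond, m in affine.items():
            affine_rows.append(
                {
                    "condition": cond,
                    "scale_x": m.scale_x, "scale_y": m.scale_y,
                    "rotation_deg": m.rotation_deg, "shear": m.shear,
                    "translation_x": m.translation[0],
                    "translation_y": m.translation[1],
                    "rms_residual": m.rms_residual,
                }
            )
        p = out_dir / "affine_maps.csv"
        pd.DataFrame(affine_rows).to_csv(p, index=False, float_format="%.5f")
        written.append(str(p))

        gen = config.generator
        log = {
            "seed": config.seed if config.seed is not None
            else (gen.seed if gen else None),
            "n_records": int(len(dataset)),
            "n_removed": removal.n_removed,
            "outlier_k": config.outlier_k,
            "coverage": config.coverage,
            "exclude_az30": config.exclude_az30,
            "conventions": {
                "anisotropy": "b/a ratio (1 = isotropic)",
                "redundancy_gain": "100*(VE_best - VE_VA)/VE_best",
                "outlier_rule": "per-axis |z| > k within subject x modality x target",
                "ellipse_scale": "chi-square(2 df) quantile at coverage",
                "aggregation": "subject-level measures averaged over subjects; "
                               "field comparison on pooled summaries",
            },
            "versions": _versions(),
        }
        p = out_dir / "run_log.json"
        p.write_text(json.dumps(log, indent=2))
        written.append(str(p))

        if config.make_plots:
            written.extend(_make_plots(result, out_dir))
    return result


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels
    from . import __version__
    return {
        "avloc": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
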