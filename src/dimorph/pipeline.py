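"""End-to-end orchestration of the two-dataset (raw + PCP) analysis.

``run_full_analysis`` chains: dataset construction (raw and PCP robust-z
variants) → per-dataset univariate battery and TIV-dependence table →
reference-category selection → penalized logistic models (optionally also
with TIV as predictor) with bootstrap validation and calibration → Pclass
score batteries, pairwise-difference summaries and nomogram tables →
projection analysis with the cross-method comparison → coefficient
structure and significant-predictor intersection reports.  All stage
seeds derive from one master seed, so a rerun with the same input and
configuration reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    PclassModel,
    bootstrap_validate,
    build_nomogram,
    calibration_curve,
    compare_model_structure,
    fit_penalized_lr,
    fit_tiv_augmented,
    pairwise_difference_summary,
    pclass_scores,
    score_battery,
    select_reference_category,
    significant_predictor_intersections,
)
from .effects import BootstrapConfig, derive_rng, DECILES
from .projection import (
    crossmethod_comparison,
    project_onto_center_line,
    projection_ps_inference,
    projection_r2,
    q_statistic,
)
from .tiv import AnalysisDataset, CohortTable, build_datasets
from .univariate import UnivariateTable, run_univariate_battery, tiv_dependence_correlation

__all__ = ["RunConfig", "ReportBundle", "read_cohort_table", "run_full_analysis", "write_report_bundle"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None
    output_dir: str | None = None
    n_boot_deciles: int = 4000
    n_boot_overlap: int = 1000
    n_boot_u3: int = 2000
    n_boot_moments: int = 2000
    n_boot_pairwise: int = 500
    n_boot_correlation: int = 599
    n_validation_reps: int = 200
    alpha: float = 0.05
    penalty_grid: tuple[float, ...] | None = None
    datasets: tuple[str, ...] = ("raw", "pcp")
    with_tiv_models: bool = True
    with_plots: bool = False
    pairwise_cap: int = 4_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_boot_deciles", "n_boot_overlap", "n_boot_u3", "n_boot_moments",
                     "n_boot_pairwise", "n_boot_correlation", "n_validation_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.datasets) - {"raw", "pcp"}
        if bad:
            raise ValueError(f"unknown dataset selection {sorted(bad)}")
        self.datasets = tuple(self.datasets)

    @classmethod
    def reduced(cls, **overrides) -> "RunConfig":
        """Desk-scale preset: bootstrap families 500/250/250/250 and 50
        validation repetitions."""
        defaults = dict(
            n_boot_deciles=500, n_boot_overlap=250, n_boot_u3=250, n_boot_moments=250,
            n_boot_pairwise=200, n_boot_correlation=399, n_validation_reps=50,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "datasets" in raw:
            raw["datasets"] = tuple(raw["datasets"])
        if "penalty_grid" in raw and raw["penalty_grid"] is not None:
            raw["penalty_grid"] = tuple(float(v) for v in raw["penalty_grid"])
        return cls(**raw)

    def bootstrap_config(self, seed: int) -> BootstrapConfig:
        return BootstrapConfig(
            n_boot_deciles=self.n_boot_deciles,
            n_boot_overlap=self.n_boot_overlap,
            n_boot_u3=self.n_boot_u3,
            n_boot_moments=self.n_boot_moments,
            alpha=self.alpha,
            seed=seed,
        )


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus a manifest."""

    adjustment: pd.DataFrame
    univariate: dict[str, UnivariateTable]
    tiv_dependence: dict[str, pd.DataFrame]
    models: dict[str, PclassModel]
    score_batteries: dict[str, dict]
    pairwise: dict[str, object]
    nomograms: dict[str, pd.DataFrame]
    calibration: dict[str, pd.DataFrame]
    projection: dict[str, dict]
    crossmethod: dict[str, dict]
    structure: dict
    intersections: dict | None
    scores: pd.DataFrame
    manifest: dict


def read_cohort_table(path: str | Path, roi_labels: Sequence[str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    The schema is: subject_id, sex (F/M), tiv_ml, then one positive volume
    column per ROI.  If ``roi_labels`` is omitted, every column after the
    three required ones is treated as an ROI.  Validation problems are
    collected and reported together.
    """
    df = pd.read_csv(path)
    problems = []
    for col in ("subject_id", "sex", "tiv_ml"):
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if roi_labels is None:
        roi_labels = [c for c in df.columns if c not in ("subject_id", "sex", "tiv_ml")]
        if not roi_labels:
            problems.append("no ROI volume columns found")
    else:
        missing = [c for c in roi_labels if c not in df.columns]
        if missing:
            problems.append(f"missing ROI column(s): {missing}")
    if problems:
        raise ValueError(f"invalid cohort file {path}: " + "; ".join(problems))

    if df["sex"].isna().any() or (~df["sex"].isin(["F", "M"])).any():
        bad = sorted(set(df["sex"].dropna()) - {"F", "M"})
        problems.append(f"unrecognized sex code(s) {bad}; accepted codes are ['F', 'M']")
    for col in ("tiv_ml", *roi_labels):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            problems.append(f"non-numeric values in column {col!r}")
        elif (vals <= 0).any():
            rows = df.index[vals <= 0].tolist()[:5]
            problems.append(f"non-positive values in column {col!r} (rows {rows})")
    if problems:
        raise ValueError(f"invalid cohort file {path}: " + "; ".join(problems))
    return CohortTable(df, roi_labels=tuple(roi_labels))


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def run_full_analysis(cohort: CohortTable, cfg: RunConfig) -> ReportBundle:
    """Execute the complete raw + PCP analysis on a validated cohort."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        timings[stage] = round(time.perf_counter() - t0, 2)
        logger.info("stage %-22s done at %.1fs", stage, timings[stage])

    raw_ds, pcp_ds = build_datasets(cohort)
    datasets = {k: v for k, v in (("raw", raw_ds), ("pcp", pcp_ds)) if k in cfg.datasets}
    adjustment = pd.DataFrame(
        {
            "b_hat": pcp_ds.b_hat,
            "tiv_r2_raw": raw_ds.tiv_r2,
            "tiv_r2_pcp": pcp_ds.tiv_r2,
        }
    )
    tick("build_datasets")

    univariate: dict[str, UnivariateTable] = {}
    tiv_dep: dict[str, pd.DataFrame] = {}
    for kind, ds in datasets.items():
        bcfg = cfg.bootstrap_config(_stage_seed(cfg.seed, f"univariate-{kind}"))
        univariate[kind] = run_univariate_battery(ds, bcfg)
        tiv_dep[kind] = tiv_dependence_correlation(univariate[kind], ds)
        tick(f"univariate-{kind}")

    models: dict[str, PclassModel] = {}
    batteries: dict[str, dict] = {}
    pairwise: dict[str, object] = {}
    nomograms: dict[str, pd.DataFrame] = {}
    calibration: dict[str, pd.DataFrame] = {}
    projections: dict[str, dict] = {}
    crossmethod: dict[str, dict] = {}
    score_rows: dict[str, np.ndarray] = {}
    uni_for_structure: list[UnivariateTable] = []

    for kind, ds in datasets.items():
        ref = select_reference_category(univariate[kind])
        X = ds.zscores
        model = fit_penalized_lr(X, ds.sex, ref, penalty_grid=cfg.penalty_grid, alpha=cfg.alpha)
        bootstrap_validate(
            model, X, ds.sex, n_reps=cfg.n_validation_reps,
            rng=derive_rng(_stage_seed(cfg.seed, f"validate-{kind}"), "validate"),
        )
        calibration[kind] = calibration_curve(model, X, ds.sex)
        models[kind] = model
        uni_for_structure.append(univariate[kind])

        scores = pclass_scores(model, X, ds.sex)
        bcfg = cfg.bootstrap_config(_stage_seed(cfg.seed, f"scores-{kind}"))
        batteries[kind] = score_battery(scores, bcfg)
        pairwise[kind] = pairwise_difference_summary(
            scores, bcfg, n_boot=cfg.n_boot_pairwise, pair_cap=cfg.pairwise_cap,
            rng=derive_rng(_stage_seed(cfg.seed, f"pairwise-{kind}"), "pairwise"),
        )
        nomograms[kind] = build_nomogram(model, X, sex=ds.sex)["table"]
        tick(f"classification-{kind}")

        f_mask = ds.sex.to_numpy() == "F"
        # "gm" orientation: larger projected distance always means more
        # gray matter, making the multivariate direction explicit
        proj = project_onto_center_line(X.loc[f_mask], X.loc[~f_mask], orient="gm")
        dom = projection_ps_inference(proj, bcfg)
        projections[kind] = {
            "result": proj,
            "dominance": dom,
            "r2": projection_r2(proj),
            "q": q_statistic(proj.dist_a, proj.dist_b),
        }
        xcfg = cfg.bootstrap_config(_stage_seed(cfg.seed, f"crossmethod-{kind}"))
        crossmethod[kind] = crossmethod_comparison(
            scores, proj, xcfg, sex=ds.sex, tiv=ds.tiv, n_boot_corr=cfg.n_boot_correlation
        )
        score_rows[f"pclass_{kind}"] = scores.scores.to_numpy()
        dist = np.empty(len(ds.sex))
        dist[f_mask] = proj.dist_a
        dist[~f_mask] = proj.dist_b
        score_rows[f"distance_{kind}"] = dist
        tick(f"projection-{kind}")

        if cfg.with_tiv_models:
            m_tiv = fit_tiv_augmented(X, ds.tiv, ds.sex, ref, penalty_grid=cfg.penalty_grid, alpha=cfg.alpha)
            bootstrap_validate(
                m_tiv, _augmented_matrix(X, ds.tiv), ds.sex,
                n_reps=cfg.n_validation_reps,
                rng=derive_rng(_stage_seed(cfg.seed, f"validate-{kind}-tiv"), "validate"),
            )
            models[f"{kind}+tiv"] = m_tiv
            nomograms[f"{kind}+tiv"] = build_nomogram(m_tiv, _augmented_matrix(X, ds.tiv), sex=ds.sex)["table"]
            tick(f"tiv-model-{kind}")

    structure: dict = {}
    intersections = None
    if len(models) >= 2:
        names = list(models)
        ordered = [models[n] for n in names]
        uni_map = {"raw": univariate.get("raw"), "pcp": univariate.get("pcp")}
        uni_list = [uni_map[n.split("+")[0]] for n in names]
        structure = compare_model_structure(ordered, model_names=names, uni_tables=uni_list)
        intersections = significant_predictor_intersections(ordered, model_names=names, alpha=cfg.alpha)
    tick("structure")

    scores_df = pd.DataFrame(
        {"subject_id": cohort.data["subject_id"], "sex": cohort.sex, **score_rows}
    )

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "n_subjects": cohort.n_subjects,
        "roi_labels": list(cohort.roi_labels),
        "timings_s": timings,
    }
    return ReportBundle(
        adjustment=adjustment,
        univariate=univariate,
        tiv_dependence=tiv_dep,
        models=models,
        score_batteries=batteries,
        pairwise=pairwise,
        nomograms=nomograms,
        calibration=calibration,
        projection=projections,
        crossmethod=crossmethod,
        structure=structure,
        intersections=intersections,
        scores=scores_df,
        manifest=manifest,
    )


def _augmented_matrix(X: pd.DataFrame, tiv: pd.Series) -> pd.DataFrame:
    from .tiv import robust_z_transform

    out = X.copy()
    out["TIV"] = robust_z_transform(np.asarray(tiv, dtype=float), label="TIV")
    return out


# ---------------------------------------------------------------------------
# Writing


def _model_summary_frame(models: dict[str, PclassModel]) -> pd.DataFrame:
    rows = []
    for name, m in models.items():
        for pred in m.predictors:
            w = m.wald.loc[pred]
            rows.append({"model": name, "predictor": pred, "coef": w["coef"], "se": w["se"],
                         "z": w["z"], "p": w["p"], "fdr_p": w["fdr_p"],
                         "significant": bool(w["significant"])})
    return pd.DataFrame(rows)


def _index_frame(models: dict[str, PclassModel]) -> pd.DataFrame:
    rows = []
    for name, m in models.items():
        row = {"model": name, "reference_sex": m.reference_sex, "penalty": m.penalty,
               "includes_tiv": m.includes_tiv}
        row.update({f"apparent_{k}": v for k, v in m.apparent.items()})
        if m.corrected:
            row.update({f"corrected_{k}": v for k, v in m.corrected.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _battery_frame(batteries: dict[str, dict]) -> pd.DataFrame:
    rows = []
    for kind, b in batteries.items():
        dom = b["dominance"]
        row = {
            "dataset": kind, "reference_sex": b["reference_sex"],
            "median_shift": b["global"],
            "ps_ref": dom.ps_a, "ps_other": dom.ps_b,
            "cliff_delta": dom.delta.value, "delta_ci_low": dom.delta.ci_low,
            "delta_ci_high": dom.delta.ci_high, "delta_p": dom.delta.p,
            "overlap_pct": 100 * b["overlap"].value,
            "u3_pct": b["u3"].value,
            "iqr_ratio": b["iqr"].value, "iqr_p": b["iqr"].p,
            "skew_diff": b["skewness"].value, "skew_p": b["skewness"].p,
            "kurt_diff": b["kurtosis"].value, "kurt_p": b["kurtosis"].p,
        }
        if "accuracy" in b:
            row["accuracy_pct"] = b["accuracy"]["balanced_pct"]
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise_frame(pairwise: dict[str, object]) -> pd.DataFrame:
    rows = []
    for kind, s in pairwise.items():
        row = {"dataset": kind, "percent_favoring_reference": s.percent_favoring_reference,
               "ci_low": s.ci_low, "ci_high": s.ci_high, "n_pairs": s.n_pairs, "n_ties": s.n_ties}
        for q, v in zip(np.round(DECILES, 1), s.deciles):
            row[f"decile_{q}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _projection_frame(projection: dict[str, dict], crossmethod: dict[str, dict]) -> pd.DataFrame:
    frames = []
    for kind in projection:
        tab = crossmethod[kind]["table"].copy()
        tab.insert(0, "dataset", kind)
        tab.insert(1, "statistic", tab.index)
        frames.append(tab.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def write_report_bundle(bundle: ReportBundle, outdir: str | Path, overwrite: bool = False) -> list[Path]:
    """Write the bundle as tidy CSVs plus a JSON manifest with per-file
    SHA256 checksums; refuses to clobber an existing manifest unless
    ``overwrite`` is set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace the bundle")
    if bundle.adjustment.empty:
        raise ValueError("write_report_bundle: empty bundle")

    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = outdir / name
        df.to_csv(path, index=index)
        written.append(path)

    emit("adjustment.csv", bundle.adjustment)
    for kind, uni in bundle.univariate.items():
        emit(f"univariate_global_{kind}.csv", uni.global_test)
        emit(f"univariate_overlap_{kind}.csv", uni.overlap)
        emit(f"univariate_deciles_{kind}.csv", uni.deciles, index=False)
        emit(f"univariate_dominance_{kind}.csv", uni.dominance)
        emit(f"univariate_shape_{kind}.csv", uni.shape)
        emit(f"univariate_direction_{kind}.csv", uni.direction.to_frame())
    for kind, dep in bundle.tiv_dependence.items():
        emit(f"tiv_dependence_{kind}.csv", dep)
    if bundle.models:
        emit("model_coefficients.csv", _model_summary_frame(bundle.models), index=False)
        emit("model_indexes.csv", _index_frame(bundle.models), index=False)
        emit("score_battery.csv", _battery_frame(bundle.score_batteries), index=False)
        emit("pairwise_differences.csv", _pairwise_frame(bundle.pairwise), index=False)
        for kind, nom in bundle.nomograms.items():
            emit(f"nomogram_{kind.replace('+', '_')}.csv", nom)
        for kind, cal in bundle.calibration.items():
            emit(f"calibration_{kind}.csv", cal, index=False)
    if bundle.projection:
        emit("projection_comparison.csv", _projection_frame(bundle.projection, bundle.crossmethod), index=False)
        corr_rows = []
        for kind, xm in bundle.crossmethod.items():
            for pair, res in xm["correlations"].items():
                corr_rows.append({"dataset": kind, "pair": pair, **res})
        emit("score_correlations.csv", pd.DataFrame(corr_rows), index=False)
    if bundle.structure:
        emit("structure_rho_signed.csv", bundle.structure["rho_signed"])
        emit("structure_rho_abs.csv", bundle.structure["rho_abs"])
        if "coef_vs_univariate" in bundle.structure:
            emit("structure_coef_vs_univariate.csv", bundle.structure["coef_vs_univariate"], index=False)
    if bundle.intersections:
        rows = [
            {"models": " & ".join(combo), "predictors": ";".join(preds), "cardinality": len(preds)}
            for combo, preds in bundle.intersections["exclusive_intersections"].items()
        ]
        emit("predictor_intersections.csv", pd.DataFrame(rows), index=False)
        emit("predictor_significance_counts.csv", bundle.intersections["counts"].rename("n_models").to_frame())
    emit("subject_scores.csv", bundle.scores, index=False)

    manifest = dict(bundle.manifest)
    manifest["files"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(manifest_path)
    return written
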