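"""End-to-end orchestration: generate -> score -> classify -> evaluate.

The pipeline renders a synthetic cohort to disk (TIFF views + CSV cohort
table + ground-truth JSON), scores every examination (open-beam
self-calibration, density map, detectability map, features, logistic
masking score), applies the reference-standard rules, and runs both ROC
analyses.  Every stochastic step is seeded from the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cohort_rules import build_analysis_sets
from .density_mapping import compute_density_map, estimate_open_beam, segment_breast
from .detectability import detectability_map, gaussian_signal_spectrum
from .errors import MaskScopeError, ProcessingFailure
from .evaluation import (
    ci_to_se,
    compare_proportions,
    cumulative_roc,
    independent_auc_ztest,
    paired_auc_test,
    roc_summary,
)
from .features import dmap_std, extract_exam_features, glcm_correlation_of_map
from .masking_model import (
    ModelParams,
    fit_logistic,
    load_default_model,
    load_model,
    predict_masking_score,
    save_model,
    stepwise_aic,
)
from .synthetic_cohort import (
    CohortConfig,
    RawImage,
    default_cohort_config,
    render_exam,
    sample_cohort,
)

log = logging.getLogger("maskscope")

#: AUC (and 95% CI) of the masking model on its original development
#: cohort, used as the literature reference for the independent Z-test.
ORIGINAL_AUC = 0.75
ORIGINAL_AUC_CI = (0.68, 0.82)


@dataclass
class DetectabilityParams:
    roi_size: int | None = None   # None: image_size // 4
    stride: int | None = None     # None: roi_size // 2
    sigma_les_mm: float = 2.0
    amplitude: float | None = None  # None: d'=3 on unit-variance white noise
    observer: str = "pw"

    def resolved(self, image_shape, pixel_pitch):
        min_roi = int(np.ceil(8.0 * self.sigma_les_mm / pixel_pitch))
        roi = self.roi_size or max(min(image_shape) // 4, min_roi)
        stride = self.stride or roi // 2
        amp = self.amplitude
        if amp is None:
            spec = gaussian_signal_spectrum(1.0, self.sigma_les_mm, roi, pixel_pitch)
            s2 = np.abs(spec) ** 2
            s2.flat[0] = 0.0
            amp = 3.0 / float(np.sqrt(s2.sum()))
        return roi, stride, amp


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "maskscope_run"
    n_screen: int = 200
    n_interval: int = 200
    seed: int = 0
    image_size: str = "small"           # "small" (128 px) or "full" (512 px)
    model: str = "fit"                  # "fit" | "default" | path to JSON
    supplement_b: bool = False
    laterality_mode: str = "all"        # "all" | "contralateral"
    bootstrap_B: int = 1000
    detectability: DetectabilityParams = field(default_factory=DetectabilityParams)
    original_auc: float = ORIGINAL_AUC
    original_auc_ci: tuple = ORIGINAL_AUC_CI

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectabilityParams(**raw.pop("detectability", {}))
        cfg = cls(**raw, detectability=det)
        if cfg.laterality_mode not in ("all", "contralateral"):
            raise MaskScopeError(f"bad laterality_mode {cfg.laterality_mode!r}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def cohort_config(self) -> CohortConfig:
        return default_cohort_config(
            self.n_screen, self.n_interval, self.seed, image_size=self.image_size
        )


# ---------------------------------------------------------------------------
# per-exam scoring (shared by the disk and in-memory paths)
# ---------------------------------------------------------------------------

def process_view(
    raw: RawImage,
    acq,
    det_params: DetectabilityParams,
) -> dict:
    """Calibrate and featurize one view; raises ProcessingFailure on failure."""
    mask = segment_breast(raw)
    cal = estimate_open_beam(raw, mask)
    if not cal.ok:
        raise ProcessingFailure(cal.status)
    dm = compute_density_map(
        raw,
        cal.open_beam_estimate,
        acq.mu_fat,
        acq.mu_gland,
        acq.thickness_mm,
        breast_mask=mask,
    )
    roi, stride, amp = det_params.resolved(raw.pixels.shape, raw.pixel_pitch)
    det = detectability_map(
        dm.dense_thickness,
        mask,
        roi_size=roi,
        stride=stride,
        sigma_les_mm=det_params.sigma_les_mm,
        amplitude=amp,
        pixel_pitch=raw.pixel_pitch,
        observer=det_params.observer,
    )
    return {
        "view": f"{raw.laterality}_{raw.view}",
        "dmap_std": dmap_std(det),
        "glcm_correlation": glcm_correlation_of_map(dm.dense_thickness, mask),
        "vbd": dm.vbd,
    }


def process_exam(
    views: dict,
    acq,
    det_params: DetectabilityParams,
    exam_id: str,
    age: float,
    cancer_laterality: str | None = None,
    laterality_mode: str = "all",
):
    """Featurize all usable views of one exam; returns (FeatureVector, view dicts).

    ``laterality_mode='contralateral'`` restricts to views of the breast
    opposite the cancer, eliminating any influence of the lesion itself.
    """
    per_view, failures = [], []
    for (lat, view), raw in views.items():
        if laterality_mode == "contralateral" and lat == cancer_laterality:
            continue
        try:
            per_view.append(process_view(raw, acq, det_params))
        except (ProcessingFailure, MaskScopeError) as exc:
            failures.append({"view": f"{lat}_{view}", "reason": str(exc)})
    fv = extract_exam_features(per_view, exam_id, age)  # raises if none survived
    return fv, per_view, failures


def score_cohort(
    config: CohortConfig,
    records: pd.DataFrame,
    det_params: DetectabilityParams | None = None,
    model: ModelParams | str = "fit",
    laterality_mode: str = "all",
    image_loader=None,
):
    """Render (or load), featurize and score every exam in the cohort.

    Returns (scored DataFrame, failure log DataFrame, fitted-or-given
    ModelParams).  ``model='fit'`` fits the final three-feature logistic
    model on this cohort, ``'stepwise'`` runs stepwise-AIC selection over
    the same candidates, ``'default'`` loads the shipped weights, and any
    other string is a path to a serialized model.  The masking score of
    an exam is the mean of its per-view scores.
    """
    det_params = det_params or DetectabilityParams()
    acq = config.acquisition
    feats, view_rows, fail_rows = [], {}, []
    for _, rec in records.iterrows():
        exam_id = rec["exam_id"]
        views = (
            image_loader(rec)
            if image_loader is not None
            else {k: raw for k, (ph, raw) in render_exam(config, rec).items()}
        )
        try:
            fv, per_view, failures = process_exam(
                views, acq, det_params, exam_id, rec["age"],
                cancer_laterality=rec.get("cancer_laterality"),
                laterality_mode=laterality_mode,
            )
        except ProcessingFailure as exc:
            fail_rows.append({"exam_id": exam_id, "reason": exc.reason})
            continue
        fail_rows.extend(
            {"exam_id": exam_id, **f} for f in failures
        )
        feats.append(
            {
                "exam_id": exam_id,
                "dmap_std": fv.dmap_std,
                "glcm_correlation": fv.glcm_correlation,
                "vbd_estimated": fv.vbd,
                "n_views": fv.n_views,
            }
        )
        view_rows[exam_id] = per_view
    feat_columns = [
        "exam_id", "dmap_std", "glcm_correlation", "vbd_estimated", "n_views"
    ]
    feat_df = pd.DataFrame(feats, columns=feat_columns)
    scored = records.merge(feat_df, on="exam_id", how="inner")
    if scored.empty and model == "fit":
        raise MaskScopeError("no exam processed successfully: cannot fit model")

    if isinstance(model, ModelParams):
        fitted = model
    elif model == "default":
        fitted = load_default_model()
    elif model in ("fit", "stepwise"):
        labels = (scored["group"] == "interval").astype(int).to_numpy()
        if model == "stepwise":
            fitted = stepwise_aic(
                ["dmap_std", "glcm_correlation", "age"], scored, labels
            )
        else:  # the final three-feature model
            fitted = fit_logistic(
                scored, labels,
                feature_names=["dmap_std", "glcm_correlation", "age"],
            )
        fitted.seed = config.seed
    else:
        fitted = load_model(model)

    # exam score = mean of per-view scores (view averaging of model output)
    scores = []
    for _, row in scored.iterrows():
        pv = view_rows[row["exam_id"]]
        view_scores = [
            predict_masking_score(
                fitted, {**v, "age": row["age"]}, exam_id=row["exam_id"]
            ).score
            for v in pv
        ]
        scores.append(float(np.mean(view_scores)))
    scored["masking_score"] = scores
    failure_log = pd.DataFrame(fail_rows, columns=["exam_id", "view", "reason"])
    return scored, failure_log, fitted


# ---------------------------------------------------------------------------
# disk-based subcommands
# ---------------------------------------------------------------------------

def run_generate(config: RunConfig, force: bool = False) -> Path:
    """Render the synthetic cohort to disk; returns the output directory."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise MaskScopeError(f"{out} is not empty (use force=True / --force)")
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort_config()
    records = sample_cohort(cohort_cfg)
    written = []
    truth = {}
    for _, rec in records.iterrows():
        exam = render_exam(cohort_cfg, rec)
        truth[rec["exam_id"]] = {
            "true_vbd": float(rec["vbd"]),
            "lesions": {},
        }
        for (lat, view), (phantom, raw) in exam.items():
            name = f"{rec['exam_id']}_{lat}_{view}.tif"
            tifffile.imwrite(
                img_dir / name, np.round(raw.pixels).astype(np.uint16)
            )
            written.append(f"images/{name}")
            truth[rec["exam_id"]]["lesions"][f"{lat}_{view}"] = [
                list(map(float, les)) for les in phantom.lesions
            ]
    records.to_csv(out / "cohort.csv", index=False)
    written.append("cohort.csv")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    written.append("ground_truth.json")
    config.to_yaml(out / "run_config.yaml")
    written.append("run_config.yaml")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_exams": int(len(records)),
        "acquisition": asdict(cohort_cfg.acquisition),
        "files": written + ["manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("generated %d exams in %s", len(records), out)
    return out


def _tiff_loader(img_dir: Path, acq):
    def load(rec):
        views = {}
        for lat in ("left", "right"):
            for view in ("CC", "MLO"):
                path = img_dir / f"{rec['exam_id']}_{lat}_{view}.tif"
                if not path.exists():
                    continue
                views[(lat, view)] = RawImage(
                    pixels=tifffile.imread(path).astype(float),
                    open_beam_true=acq["open_beam"],
                    saturation_level=acq["saturation_level"],
                    pixel_pitch=acq["pixel_pitch"],
                    laterality=lat,
                    view=view,
                )
        return views

    return load


def run_score(config: RunConfig) -> Path:
    """Score a generated (or user-supplied) cohort directory."""
    out = Path(config.out_dir)
    records = pd.read_csv(out / "cohort.csv")
    manifest = json.loads((out / "manifest.json").read_text())
    acq_meta = manifest["acquisition"]
    cohort_cfg = config.cohort_config()
    scored, failure_log, fitted = score_cohort(
        cohort_cfg,
        records,
        det_params=config.detectability,
        model=config.model,
        laterality_mode=config.laterality_mode,
        image_loader=_tiff_loader(out / "images", acq_meta),
    )
    scored.to_csv(out / "scored.csv", index=False)
    failure_log.to_csv(out / "failures.csv", index=False)
    save_model(fitted, out / "model.json")
    log.info(
        "scored %d/%d exams (%d failure records)",
        len(scored), len(records), len(failure_log),
    )
    return out


def run_evaluate(config: RunConfig) -> dict:
    """Both ROC analyses plus the proportions and group summaries."""
    out = Path(config.out_dir)
    scored = pd.read_csv(out / "scored.csv")
    report = evaluate_scored(
        scored,
        bootstrap_B=config.bootstrap_B,
        seed=config.seed,
        supplement_b=config.supplement_b,
        original_auc=config.original_auc,
        original_auc_ci=tuple(config.original_auc_ci),
    )
    (out / "report.json").write_text(json.dumps(report, indent=1))
    _write_roc_figures(scored, out, supplement_b=config.supplement_b)
    return report


def evaluate_scored(
    scored: pd.DataFrame,
    bootstrap_B: int = 1000,
    seed: int = 0,
    supplement_b: bool = False,
    original_auc: float = ORIGINAL_AUC,
    original_auc_ci: tuple = ORIGINAL_AUC_CI,
) -> dict:
    """Compute the full evaluation report from a scored cohort table."""
    analysis1, analysis2, excl = build_analysis_sets(
        scored, supplement_b=supplement_b
    )
    if analysis1.empty or analysis1["label"].nunique() < 2:
        raise MaskScopeError("analysis 1 requires both outcome groups")
    labels = analysis1["label"].to_numpy(int)
    mscore = analysis1["masking_score"].to_numpy(float)
    vbd = analysis1["vbd_estimated"].to_numpy(float)
    rs_model = roc_summary(mscore, labels, B=bootstrap_B, seed=seed)
    rs_vbd = roc_summary(vbd, labels, B=bootstrap_B, seed=seed + 1)
    _, _, diff, se_diff, p_paired = paired_auc_test(mscore, vbd, labels)
    z, p_orig = independent_auc_ztest(
        rs_model.auc,
        ci_to_se(rs_model.ci_low, rs_model.ci_high),
        original_auc,
        ci_to_se(*original_auc_ci),
    )
    # visible-mass proportions per group
    vis = scored.groupby("group")["mass_visible"].agg(["sum", "count"])
    p1, p2, chi2, p_prop = compare_proportions(
        int(vis.loc["screen_detected", "sum"]),
        int(vis.loc["screen_detected", "count"]),
        int(vis.loc["interval", "sum"]),
        int(vis.loc["interval", "count"]),
    )
    report = {
        "n_analysis1": int(len(analysis1)),
        "n_excluded": int(len(excl)),
        "analysis1": {
            "model": _roc_dict(rs_model),
            "vbd": _roc_dict(rs_vbd),
            "paired_diff": float(diff),
            "paired_se": float(se_diff),
            "paired_p": float(p_paired),
            "ztest_vs_original": {"z": z, "p": p_orig,
                                   "original_auc": original_auc},
        },
        "visible_mass": {
            "screen_detected_pct": p1,
            "interval_pct": p2,
            "chi2": chi2,
            "p": p_prop,
        },
        "group_summary": _group_summary(scored),
    }
    if not analysis2.empty and analysis2["category"].nunique() >= 2:
        cats = analysis2["category"].to_numpy(int)
        cr_m = cumulative_roc(
            analysis2["masking_score"].to_numpy(float), cats,
            B=bootstrap_B, seed=seed + 2,
        )
        cr_v = cumulative_roc(
            analysis2["vbd_estimated"].to_numpy(float), cats,
            B=bootstrap_B, seed=seed + 3,
        )
        report["analysis2"] = {
            "model": _cum_dict(cr_m),
            "vbd": _cum_dict(cr_v),
            "n": int(len(analysis2)),
        }
    return report


def _roc_dict(rs) -> dict:
    return {
        "auc": rs.auc,
        "ci": [rs.ci_low, rs.ci_high],
        "n_pos": rs.n_pos,
        "n_neg": rs.n_neg,
    }


def _cum_dict(cr) -> dict:
    return {
        "auc_low_vs_rest": cr.auc_low_vs_rest,
        "ci_low_vs_rest": list(cr.ci_low_vs_rest) if cr.ci_low_vs_rest else None,
        "auc_rest_vs_high": cr.auc_rest_vs_high,
        "ci_rest_vs_high": (
            list(cr.ci_rest_vs_high) if cr.ci_rest_vs_high else None
        ),
        "counts": cr.counts,
    }


def _group_summary(scored: pd.DataFrame) -> dict:
    out = {}
    for grp, sub in scored.groupby("group"):
        out[grp] = {
            "n": int(len(sub)),
            "age_median": float(sub["age"].median()),
            "vbd_median": float(sub["vbd_estimated"].median()),
            "masking_score_median": float(sub["masking_score"].median()),
            "visible_mass_rate": float(sub["mass_visible"].mean()),
        }
    return out


def _write_roc_figures(scored, out: Path, supplement_b: bool = False) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evaluation import auc_mann_whitney, roc_curve_points

    analysis1, _, _ = build_analysis_sets(scored, supplement_b=supplement_b)
    labels = analysis1["label"].to_numpy(int)
    fig, ax = plt.subplots(figsize=(5, 5))
    rows = []
    for col, name in (("masking_score", "masking model"), ("vbd_estimated", "VBD")):
        sc = analysis1[col].to_numpy(float)
        curve = roc_curve_points(sc, labels)
        ax.plot(curve[:, 0], curve[:, 1],
                label=f"{name} (AUC {auc_mann_whitney(sc, labels):.2f})")
        for fpr, tpr in curve:
            rows.append({"predictor": name, "fpr": fpr, "tpr": tpr})
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(out / "roc_analysis1.png", dpi=120)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(out / "roc_curves.csv", index=False)


def run_all(config: RunConfig, force: bool = False) -> dict:
    run_generate(config, force=force)
    run_score(config)
    return run_evaluate(config)
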