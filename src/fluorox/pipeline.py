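"""End-to-end orchestration: simulate or load, preprocess, fit, analyse.

A single :class:`RunConfig` (YAML-serializable) is the only source of
tunables; every run writes its config, per-stage provenance and the
calibration constants actually used into the output directory, so analysis-choice
knobs are auditable.  Synthetic-mode reruns with the same config and seed
are bit-stable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import DEFAULT_CALIBRATION, OxygenCalibration
from .image_io import (
    MagnitudeSeries,
    RoiSet,
    load_series,
    load_volume,
    save_series,
    save_volume,
    validate_design_table,
)
from .preprocessing import (
    DEFAULT_SMOOTH_SD_PX,
    DEFAULT_SNR_THRESHOLD,
    preprocess_session,
    roi_mean_snr,
)
from .relaxometry import fit_saturation_recovery, records_from_fits
from .stats import (
    OUTCOME_COLUMNS,
    descriptive_summary,
    fit_all_outcomes,
    posthoc_all_outcomes,
)
from .synthetic import PhantomConfig, StudyBundle, generate_study

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report", "load_run_config"]

ALPHA = 0.05


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input id."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {detail}")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    mode: str = "synthetic"                  # "synthetic" | "real"
    output_dir: str = "fluorox_run"
    seed: int = 0
    smooth_sd_px: float = DEFAULT_SMOOTH_SD_PX
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    interp_order: int = 3
    calibration_slope: float = DEFAULT_CALIBRATION.slope
    calibration_intercept: float = DEFAULT_CALIBRATION.intercept
    write_images: bool = False               # write NIfTI intermediates
    phantom: dict = field(default_factory=dict)   # PhantomConfig overrides
    real_study_yaml: str | None = None       # real mode: study.yaml path

    def calibration(self) -> OxygenCalibration:
        return OxygenCalibration(self.calibration_slope, self.calibration_intercept)

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(seed=self.seed, **self.phantom)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


def _load_real_study(config: RunConfig) -> StudyBundle:
    """Load a NIfTI-converted study described by a study.yaml file.

    Expected layout::

        rois: labels.nii.gz
        roi_labels: {1: [mother_id, placenta_id], ...}
        background_label: 999
        noise_mask_f19: noise_f19.nii.gz
        tr_list_ms: [318, 719, 1398, 5000]
        sessions:
          - {mother_id: M1, genotype: WT, oxygen_percent: 30,
             volumes: [a.nii.gz, b.nii.gz, c.nii.gz, d.nii.gz]}
    """
    if config.real_study_yaml is None:
        raise PipelineError("load", "real mode requires real_study_yaml")
    spec_path = Path(config.real_study_yaml)
    if not spec_path.exists():
        raise PipelineError("load", f"study file not found: {spec_path}")
    spec = yaml.safe_load(spec_path.read_text())
    root = spec_path.parent

    for key in ("rois", "noise_mask_f19"):
        if not (root / spec[key]).exists():
            raise PipelineError("load", f"{key} file not found: {root / spec[key]}")
    labels, affine = load_volume(root / spec["rois"])
    rois = RoiSet(
        labels=np.rint(labels).astype(np.int32),
        affine=affine,
        label_map={int(k): tuple(v) for k, v in spec["roi_labels"].items()},
        background_label=spec.get("background_label"),
    )
    noise_mask, _ = load_volume(root / spec["noise_mask_f19"])
    tr_list = spec["tr_list_ms"]

    sessions, design_rows = {}, []
    truth = pd.DataFrame()
    for sess in spec["sessions"]:
        paths = [root / p for p in sess["volumes"]]
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise PipelineError(
                "load",
                f"session ({sess['mother_id']}, {sess['oxygen_percent']}%): "
                f"missing {missing[0]}",
            )
        series = load_series(paths, tr_list, meta={"mother_id": sess["mother_id"]})
        sessions[(sess["mother_id"], float(sess["oxygen_percent"]))] = series
        design_rows.append(
            {"mother_id": sess["mother_id"], "genotype": sess["genotype"],
             "oxygen_percent": float(sess["oxygen_percent"])}
        )
    design = validate_design_table(pd.DataFrame(design_rows))
    cfg = PhantomConfig()
    return StudyBundle(
        sessions=sessions, rois=rois, noise_mask_f19=noise_mask.astype(bool),
        f19_affine=next(iter(sessions.values())).affine,
        design=design, truth=truth, config=cfg,
    )


def _records_stage(bundle: StudyBundle, config: RunConfig) -> pd.DataFrame:
    from .image_io import resample_mask_nearest

    calib = config.calibration()
    geno = dict(zip(bundle.design["mother_id"], bundle.design["genotype"]))
    rows = []
    for (mother, oxy), series in sorted(bundle.sessions.items()):
        try:
            noise_mask = bundle.noise_mask_f19
            if noise_mask.shape != series.shape:
                noise_mask = resample_mask_nearest(
                    bundle.noise_mask_f19, bundle.f19_affine,
                    series.shape, series.affine,
                ).astype(bool)
            snr = preprocess_session(
                series, noise_mask, bundle.rois.labels.shape, bundle.rois.affine,
                smooth_sd_px=config.smooth_sd_px,
                snr_threshold=config.snr_threshold,
                interp_order=config.interp_order,
            )
        except Exception as exc:
            raise PipelineError("preprocess", f"session ({mother}, {oxy}%): {exc}")
        for lab, (m, plac) in sorted(bundle.rois.label_map.items()):
            if m != mother:
                continue
            try:
                means, n = roi_mean_snr(snr, bundle.rois, lab)
                fit = (
                    fit_saturation_recovery(means, series.tr_ms)
                    if means is not None else None
                )
            except Exception as exc:
                raise PipelineError("fit", f"placenta {plac} ({mother}, {oxy}%): {exc}")
            rows.append(
                {
                    "mother_id": mother, "genotype": geno[mother],
                    "placenta_id": plac, "oxygen_percent": oxy,
                    "snr_means": means, "n_voxels": n, "fit": fit,
                }
            )
    return records_from_fits(rows, calibration=calib)


def _stats_stage(records: pd.DataFrame, outdir: Path) -> dict:
    """Full models for all outcomes; post-hoc per oxygen level when the
    PO2 interaction is significant (post-hoc tables are written for every
    level regardless, flagged by whether the interaction justified them)."""
    full_table, full_results = fit_all_outcomes(records)
    full_table.to_csv(outdir / "stats_full_model.csv", index=False)

    po2_anova = full_results["po2_mmhg"].anova.set_index("source")
    interaction_p = float(po2_anova.loc["genotype_x_oxygen", "p"])

    posthoc_tables, emm_frames = [], []
    for oxy in sorted(records["oxygen_percent"].unique()):
        table, results = posthoc_all_outcomes(records, oxy)
        table.insert(1, "oxygen_percent", oxy)
        posthoc_tables.append(table)
        for outcome, r in results.items():
            emm = r.emmeans.copy()
            emm.insert(0, "outcome", outcome)
            emm_frames.append(emm)
    pd.concat(posthoc_tables, ignore_index=True).to_csv(
        outdir / "stats_posthoc.csv", index=False
    )
    pd.concat(emm_frames, ignore_index=True).to_csv(
        outdir / "stats_emmeans.csv", index=False
    )

    descr = []
    for outcome in OUTCOME_COLUMNS:
        d = descriptive_summary(records, outcome)
        d.insert(0, "outcome", outcome)
        descr.append(d)
    pd.concat(descr, ignore_index=True).to_csv(outdir / "descriptives.csv", index=False)

    return {
        "po2_interaction_p": interaction_p,
        "po2_interaction_significant": interaction_p < ALPHA,
        "full": full_results,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline end to end; returns a result-bundle dict.

    Stages: simulate/load -> preprocess+fit (records) -> stats -> provenance.
    Any stage error aborts with the stage name and offending input id.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        try:
            bundle = generate_study(config.phantom_config())
        except Exception as exc:
            raise PipelineError("simulate", str(exc))
        bundle.truth.to_csv(outdir / "truth.csv", index=False)
        if config.write_images:
            img_dir = outdir / "images"
            for (mother, oxy), series in sorted(bundle.sessions.items()):
                save_series(series, img_dir, f"{mother}_o{int(oxy)}")
            save_volume(img_dir / "roi_labels.nii.gz", bundle.rois.labels,
                        bundle.rois.affine)
            save_volume(img_dir / "noise_roi_f19.nii.gz",
                        bundle.noise_mask_f19.astype(np.uint8), bundle.f19_affine)
    elif config.mode == "real":
        bundle = _load_real_study(config)
    else:
        raise PipelineError("config", f"unknown mode {config.mode!r}")

    bundle.design.to_csv(outdir / "design.csv", index=False)
    records = _records_stage(bundle, config)
    records.to_csv(outdir / "records.csv", index=False)

    try:
        stats_info = _stats_stage(records, outdir)
    except Exception as exc:
        raise PipelineError("stats", str(exc))

    config.to_yaml(outdir / "run_config.yaml")
    provenance = {
        "calibration": {"slope_mmhg_s": config.calibration_slope,
                        "intercept_mmhg": config.calibration_intercept,
                        "po2_formula": "PO2[mmHg] = slope/T1[s] - intercept"},
        "snr_formula": "SNR = sqrt(SI_m^2 - sigma_g^2)/sigma_g (clamped at 0)",
        "sigma_formula": "sigma_g = sigma_m/sqrt(2 - pi/2)",
        "preprocessing_order": [
            "snr_conversion", "interpolation", "smoothing", "snr_threshold"
        ],
        "seed": config.seed,
        "n_records": int(len(records)),
        "po2_interaction_p": stats_info["po2_interaction_p"],
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {
        "output_dir": str(outdir),
        "records": records,
        "design": bundle.design,
        "truth": bundle.truth,
        "stats": stats_info,
    }


def make_report(output_dir: str | Path) -> Path:
    """Write a human-readable Markdown QC report with figures.

    Includes per-placenta fit curves for a sample of records, group strip
    plots per condition, the fixed-effects tables, truth-vs-estimate
    recovery (when simulator truth is present) and surfaced QC flags.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(output_dir)
    rec_path = outdir / "records.csv"
    lines = ["# fluorox run report", ""]
    if not rec_path.exists():
        (outdir / "report.md").write_text("# fluorox run report\n\nno records\n")
        return outdir / "report.md"
    try:
        records = pd.read_csv(rec_path)
    except pd.errors.EmptyDataError:
        records = pd.DataFrame()
    if records.empty:
        (outdir / "report.md").write_text("# fluorox run report\n\nno records\n")
        return outdir / "report.md"

    # group plot per outcome (Fig.-3 style strip + mean)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, outcome, label in zip(
        axes, ("po2_mmhg", "t1_s"), ("PO2 (mmHg)", "T1 (s)")
    ):
        for g, color in (("WT", "k"), ("KO", "gray")):
            sub = records[records["genotype"] == g]
            jitter = {30.0: -2, 60.0: -2, 100.0: -2}
            off = -3 if g == "WT" else 3
            ax.scatter(sub["oxygen_percent"] + off, sub[outcome], s=12,
                       c=color, alpha=0.6, label=g)
            means = sub.groupby("oxygen_percent")[outcome].mean()
            ax.plot(means.index + off, means.values, "_", c="r", ms=18)
        ax.set_xlabel("% O2 in breathing air")
        ax.set_ylabel(label)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "group_plot.png", dpi=120)
    plt.close(fig)
    lines += ["![group plot](group_plot.png)", ""]

    # per-placenta fit curves for the first few records (Fig.-2 style)
    from .synthetic import saturation_recovery_signal

    sample = records.dropna(subset=["t1_s"]).head(6)
    if not sample.empty:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        tr_grid = np.linspace(1, 5200, 200)
        for _, r in sample.iterrows():
            snr = [r[f"snr_tr{i+1}"] for i in range(4)]
            ax.plot([318, 719, 1398, 5000], snr, "o", ms=4)
            ax.plot(tr_grid, saturation_recovery_signal(tr_grid, r["s0"], r["t1_s"]),
                    lw=1, alpha=0.7)
        ax.set_xlabel("TR (ms)")
        ax.set_ylabel("mean SNR")
        fig.tight_layout()
        fig.savefig(outdir / "fit_curves.png", dpi=120)
        plt.close(fig)
        lines += ["![fit curves](fit_curves.png)", ""]

    # stats tables
    for name, title in (
        ("stats_full_model.csv", "Fixed effects (full model)"),
        ("stats_posthoc.csv", "Post-hoc genotype tests per oxygen level"),
    ):
        p = outdir / name
        if p.exists():
            lines += [f"## {title}", "", pd.read_csv(p).round(4).to_markdown(index=False), ""]

    # truth recovery
    truth_path = outdir / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        if not truth.empty:
            merged = records.merge(
                truth, on=["mother_id", "genotype", "placenta_id", "oxygen_percent"]
            )
            err = merged["po2_mmhg"] - merged["true_po2_mmhg"]
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(merged["true_po2_mmhg"], merged["po2_mmhg"], s=12, alpha=0.6)
            lims = [merged["true_po2_mmhg"].min(), merged["true_po2_mmhg"].max()]
            ax.plot(lims, lims, "k--", lw=1)
            ax.set_xlabel("true PO2 (mmHg)")
            ax.set_ylabel("estimated PO2 (mmHg)")
            fig.tight_layout()
            fig.savefig(outdir / "truth_recovery.png", dpi=120)
            plt.close(fig)
            lines += [
                "## Truth recovery", "",
                f"- mean PO2 error: {err.mean():.1f} mmHg",
                f"- median |PO2 error|: {err.abs().median():.1f} mmHg",
                "![truth recovery](truth_recovery.png)", "",
            ]

    # QC section
    lines += ["## QC flags", ""]
    for flag in ("qc_unusable", "qc_nonconverged", "qc_po2_out_of_range"):
        n = int(records[flag].sum()) if flag in records else 0
        lines.append(f"- {flag}: {n} record(s)")
        if n:
            for _, r in records[records[flag]].iterrows():
                lines.append(
                    f"    - {r['placenta_id']} at {r['oxygen_percent']}% O2"
                )
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
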