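"""Stage functions orchestrating the full analysis.

Each stage consumes and produces plain CSV artifacts so stages can be run
independently (and re-run deterministically): raw recordings -> trial
segments -> per-subject feature table -> screening / fusion / ROC reports.
Subjects whose automatic segmentation fails are written to a
needs-manual-review file and excluded from cohort statistics unless a
manual-override file resolves them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import fuse_average, roc_analysis, roc_report, utest_report, utest_screen
from .errors import MissingArtifactError, SegmentationFailure, ValidationError
from .features import distance_features, extract_feature_vector
from .io import CohortTable, Group, read_feature_table, read_recording, write_feature_table
from .preprocess import DEFAULT_CUTOFF_HZ, DEFAULT_ORDER, fuse_axes, lowpass_filter
from .segmentation import apply_manual_segments, segment_tugs
from .synthetic import generate_cohort_recordings

log = logging.getLogger(__name__)


def _require(path: Path, what: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"missing {what}: expected file {path}")
    return path


def simulate_stage(
    out_dir,
    n_fallers: int = 18,
    n_non_fallers: int = 18,
    seed: int = 0,
    **spec_overrides,
) -> dict:
    """Write a synthetic cohort: per-subject recording CSVs, metadata and
    ground-truth segment schedule."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort_recordings(n_fallers, n_non_fallers, seed=seed, **spec_overrides)
    meta_rows, truth_rows = [], []
    for rec, truth in cohort:
        fname = f"{rec.subject_id}.csv"
        pd.DataFrame({"x": rec.x, "y": rec.y, "z": rec.z}).to_csv(out_dir / fname, index=False)
        meta_rows.append(
            {"subject_id": rec.subject_id, "group": rec.group.value, "file": fname, "rate": rec.rate}
        )
        for start, end, name in truth:
            truth_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "start_s": start / rec.rate,
                    "end_s": end / rec.rate,
                    "name": name,
                }
            )
    pd.DataFrame(meta_rows).to_csv(out_dir / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "true_segments.csv", index=False)
    return {"n_subjects": len(cohort), "out_dir": str(out_dir)}


def _load_cohort_recordings(recordings_dir: Path, metadata_path: Path):
    meta = pd.read_csv(_require(metadata_path, "cohort metadata"))
    for _, row in meta.iterrows():
        path = _require(Path(recordings_dir) / row["file"], f"recording for {row['subject_id']}")
        yield read_recording(
            path,
            rate=float(row.get("rate", 200.0)),
            subject_id=str(row["subject_id"]),
            group=row["group"],
        )


def segment_stage(
    recordings_dir,
    metadata_path,
    out_segments,
    review_path,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    overrides_path=None,
    **seg_params,
) -> dict:
    """Segment every recording; write segments CSV and a review list.

    ``overrides_path`` may name a manual-override CSV
    (``subject_id,start_s,end_s,name``) applied to subjects the automatic
    algorithm cannot segment.
    """
    overrides: dict[str, list[tuple[float, float]]] = {}
    if overrides_path is not None and Path(overrides_path).exists():
        odf = pd.read_csv(overrides_path)
        for sid, grp in odf.groupby("subject_id"):
            grp = grp.sort_values("start_s")
            overrides[str(sid)] = list(zip(grp["start_s"], grp["end_s"]))

    rows, review = [], []
    n_ok = 0
    for rec in _load_cohort_recordings(recordings_dir, metadata_path):
        sig = lowpass_filter(fuse_axes(rec), cutoff=cutoff_hz, order=order)
        try:
            if rec.subject_id in overrides:
                result = apply_manual_segments(sig, overrides[rec.subject_id])
            else:
                result = segment_tugs(sig, **seg_params)
        except (SegmentationFailure, ValidationError) as exc:
            review.append({"subject_id": rec.subject_id, "reason": str(exc)})
            continue
        n_ok += 1
        for seg in result.segments:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "start_s": seg.start / rec.rate,
                    "end_s": seg.end / rec.rate,
                    "name": seg.name,
                }
            )
    pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s", "name"]).to_csv(
        out_segments, index=False
    )
    pd.DataFrame(review, columns=["subject_id", "reason"]).to_csv(review_path, index=False)
    return {"n_segmented": n_ok, "n_review": len(review)}


def features_stage(recordings_dir, metadata_path, segments_path, out_table) -> dict:
    """Extract the 40 spectral features plus distance features per subject."""
    segs = pd.read_csv(_require(segments_path, "segments table"))
    rows = []
    for rec in _load_cohort_recordings(recordings_dir, metadata_path):
        sub = segs[segs["subject_id"].astype(str) == rec.subject_id].sort_values("start_s")
        if len(sub) != 3:
            log.info("skipping %s: %d segments on file", rec.subject_id, len(sub))
            continue
        sig = lowpass_filter(fuse_axes(rec))
        result = apply_manual_segments(sig, list(zip(sub["start_s"], sub["end_s"])))
        fv = extract_feature_vector(sig, result)
        fv.update(distance_features(fv))
        rows.append({"subject_id": rec.subject_id, "group": rec.group.value, **fv})
    if not rows:
        raise ValidationError("no subject had three usable segments")
    table = CohortTable(pd.DataFrame(rows))
    write_feature_table(table, out_table)
    return {"n_subjects": table.n_subjects, "n_features": len(table.feature_names)}


def analyze_stage(
    features_path,
    out_dir,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict:
    """Mann-Whitney screening, fusion of significant features, ROC reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(_require(features_path, "feature table"))

    screen = utest_screen(table, alpha=alpha)
    utest_report(screen).to_csv(out_dir / "utest.csv", index=False)

    significant = [r.feature for r in screen if r.significant]
    labels = table.data["group"].to_numpy()
    roc_results = {}
    for feat in significant:
        roc_results[feat] = roc_analysis(
            table.data[feat].to_numpy(float), labels, n_boot=n_boot, seed=seed
        )
    if len(significant) >= 2:
        fused = fuse_average(table, significant)
        fused.values.rename_axis("subject_id").to_frame("fused").to_csv(out_dir / "fused.csv")
        roc_results["fused"] = roc_analysis(
            fused.values.to_numpy(), labels, n_boot=n_boot, seed=seed
        )
    else:
        log.info("fewer than 2 significant features at alpha=%g; fusion skipped", alpha)
    roc_report(roc_results).to_csv(out_dir / "roc.csv", index=False)
    return {
        "n_features": len(table.feature_names),
        "n_significant": len(significant),
        "fused": len(significant) >= 2,
    }


def report_stage(analysis_dir) -> str:
    """Human-readable summary of an analyze-stage output directory."""
    analysis_dir = Path(analysis_dir)
    utest = pd.read_csv(_require(analysis_dir / "utest.csv", "screening report"))
    roc = pd.read_csv(_require(analysis_dir / "roc.csv", "ROC report"))
    lines = [
        f"tugait {__version__} analysis summary",
        f"features screened: {len(utest)}; significant: {int(utest['significant'].sum())}",
        "",
        "variable discrimination (faller vs non-faller):",
    ]
    for _, r in roc.iterrows():
        lines.append(
            f"  {r['variable']}: AUC={r['AUC']:.3f} "
            f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}), "
            f"sens={r['TPR']:.2f}, spec={r['one_minus_FPR']:.2f}, f1={r['f1_score']:.2f}"
        )
    return "\n".join(lines)


def run_pipeline(config: dict) -> dict:
    """Run simulate (optional) -> segment -> features -> analyze -> report.

    ``config`` keys: ``out_dir`` (required), ``seed``, ``recordings_dir``
    and ``metadata`` (omit to simulate a cohort instead), plus optional
    ``simulate``, ``filter``, ``segmentation``, ``cohort`` sub-dicts whose
    entries are passed to the corresponding stage.  Every parameter that
    was used is recorded in ``run_log.json`` in the output directory.
    """
    if "out_dir" not in config:
        raise ValidationError("config must name an out_dir")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    used = {"seed": seed, "version": __version__}

    if config.get("recordings_dir"):
        rec_dir = Path(config["recordings_dir"])
        metadata = Path(config.get("metadata", rec_dir / "metadata.csv"))
    else:
        sim_cfg = dict(config.get("simulate", {}))
        rec_dir = out_dir / "recordings"
        used["simulate"] = simulate_stage(rec_dir, seed=seed, **sim_cfg) | sim_cfg
        metadata = rec_dir / "metadata.csv"

    filt = dict(config.get("filter", {}))
    segp = dict(config.get("segmentation", {}))
    used["segment"] = segment_stage(
        rec_dir,
        metadata,
        out_dir / "segments.csv",
        out_dir / "needs_manual_review.csv",
        overrides_path=config.get("overrides"),
        **filt,
        **segp,
    )
    used["features"] = features_stage(
        rec_dir, metadata, out_dir / "segments.csv", out_dir / "features.csv"
    )
    coh = dict(config.get("cohort", {}))
    used["analyze"] = analyze_stage(out_dir / "features.csv", out_dir, seed=seed, **coh)
    summary = report_stage(out_dir)
    (out_dir / "summary.txt").write_text(summary + "\n")
    (out_dir / "run_log.json").write_text(json.dumps(used, indent=2, default=str) + "\n")
    return used
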