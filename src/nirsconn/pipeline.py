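"""End-to-end orchestration: raw optical densities → group statistics on disk.

Stages, in order, per subject: modified Beer–Lambert conversion → motion
artifact detection on the unfiltered hemoglobin series → band-pass
(0.01–0.08 Hz) → excision of artifact windows → QC on retained duration →
pairwise Fisher-z connectivity.  Group level: one-sample maps per group,
preterm-vs-full-term comparison, and within-group PMA trends.  A JSON
manifest records the configuration hash, seed and package versions so that
a rerun with identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .artifacts import artifact_census, build_analysis_window, detect_artifacts, qc_subject
from .connectivity import ConnectivityMatrix, pair_index, pairwise_correlation
from .hemodynamics import OpticalRecording, bandpass, mbll_inverse
from .inference import GroupComparison, OneSampleZMap, PMATrend
from .io import (
    PipelineConfig,
    read_metadata,
    read_recording,
    write_config,
    write_matrix,
)
from .layout import default_layout, read_layout

log = logging.getLogger("nirsconn")


@dataclasses.dataclass
class SubjectResult:
    subject_id: str
    group: str
    pma_weeks: float
    included: bool
    reason: str
    n_artifacts: int
    retained_s: float
    matrix: ConnectivityMatrix | None


def process_subject(recording: OpticalRecording, config: PipelineConfig) -> tuple:
    """Run the per-subject preprocessing chain; returns (matrix|None, window, events)."""
    hemo = mbll_inverse(recording)
    events = detect_artifacts(hemo, config.artifact)
    window = build_analysis_window(hemo, events, config.artifact)
    include, reason = qc_subject(window, config.artifact)
    matrix = None
    if include:
        filtered = bandpass(hemo, config.filter)
        matrix = pairwise_correlation(filtered, window)
    return matrix, window, events, include, reason


def run_pipeline(
    recordings: list[OpticalRecording] | str | Path,
    metadata,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full pipeline and write the result bundle to ``config.output_dir``.

    ``recordings`` is either a list of in-memory recordings or a directory
    of delimited recording files named ``<subject_id>.csv``; ``metadata``
    is a list of SubjectRecord or a metadata CSV path.
    """
    config = config if config is not None else PipelineConfig()
    if not isinstance(metadata, list):
        metadata = read_metadata(metadata)
    subjects = {s.subject_id: s for s in metadata}

    if not isinstance(recordings, list):
        rec_dir = Path(recordings)
        paths = sorted(rec_dir.glob("*.csv"))
        if not paths:
            raise ValueError(f"no recording files found in {rec_dir}")
        recordings = [read_recording(p) for p in paths]

    missing = [r.subject_id for r in recordings if r.subject_id not in subjects]
    if missing:
        raise ValueError(f"recordings without metadata rows: {missing}")

    layout = (
        read_layout(config.layout_path)
        if config.layout_path
        else default_layout(recordings[0].n_channels)
    )
    if layout.n_channels != recordings[0].n_channels:
        raise ValueError(
            f"layout has {layout.n_channels} channels but recordings have "
            f"{recordings[0].n_channels}"
        )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    results: list[SubjectResult] = []
    windows = []
    for rec in recordings:
        meta = subjects[rec.subject_id]
        matrix, window, events, include, reason = process_subject(rec, config)
        if not include:
            log.warning("excluded %s: %s", rec.subject_id, reason)
        windows.append(window)
        results.append(
            SubjectResult(
                subject_id=rec.subject_id,
                group=meta.group,
                pma_weeks=meta.pma_weeks,
                included=include,
                reason=reason,
                n_artifacts=len(events),
                retained_s=window.retained_duration_s,
                matrix=matrix,
            )
        )

    qc = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "pma_weeks": r.pma_weeks,
                "n_artifacts": r.n_artifacts,
                "retained_s": r.retained_s,
                "included": r.included,
                "reason": r.reason,
            }
            for r in results
        ]
    )
    qc.to_csv(out / "qc_report.csv", index=False)
    census = artifact_census(windows, {r.subject_id: r.group for r in results})
    census.to_csv(out / "artifact_census.csv", index=False)

    included = [r for r in results if r.included]
    by_group = {
        g: [r for r in included if r.group == g] for g in ("preterm", "fullterm")
    }
    for g, rows in by_group.items():
        if len(rows) < 3:
            raise RuntimeError(
                f"group '{g}' has only {len(rows)} subjects after QC; need >= 3"
            )

    mat_dir = out / "connectivity"
    mat_dir.mkdir(exist_ok=True)
    for r in included:
        write_matrix(r.matrix, mat_dir / f"{r.subject_id}_z.csv", which="z")

    iu, ju = pair_index(layout.n_channels)
    stacks = {
        g: np.stack([r.matrix.z[iu, ju] for r in rows])
        for g, rows in by_group.items()
    }

    n_ch = layout.n_channels
    group_maps = {}
    for g, Z in stacks.items():
        omap = OneSampleZMap(config=config.inference).fit(Z)
        group_maps[g] = omap
        zmat = np.full((n_ch, n_ch), np.nan)
        zmat[iu, ju] = omap.z_
        zmat[ju, iu] = omap.z_
        pd.DataFrame(zmat, columns=[str(i) for i in range(1, n_ch + 1)]).to_csv(
            out / f"group_map_{g}.csv", index=False, float_format="%.6g"
        )

    comp = GroupComparison(config=config.inference).fit(
        stacks["preterm"], stacks["fullterm"]
    )
    comp.to_frame(n_ch).to_csv(out / "edge_comparisons.csv", index=False)

    trends = {}
    for g, rows in by_group.items():
        if len(rows) < 5:
            log.warning("group '%s' has %d subjects; PMA trend needs >= 5, skipped",
                        g, len(rows))
            continue
        trend = PMATrend(config=config.inference).fit(
            stacks[g], np.array([r.pma_weeks for r in rows])
        )
        trends[g] = trend
        trend.to_frame(n_ch, group=g).to_csv(
            out / f"pma_trend_{g}.csv", index=False
        )

    manifest = {
        "package": "nirsconn",
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": len(results),
        "n_included": len(included),
        "n_channels": n_ch,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    write_config(config.to_flat(), out / "config.txt")

    return {
        "qc": qc,
        "census": census,
        "group_maps": group_maps,
        "comparison": comp,
        "trends": trends,
        "results": results,
        "manifest": manifest,
    }
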