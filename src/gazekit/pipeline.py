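"""End-to-end orchestration: QC -> fixation detection -> AOI metrics ->
transitions -> toggle intervals -> condition statistics.

The pipeline consumes a study directory::

    study/
      layout.json          AOI layout
      sessions.csv         participant_id,image_id,condition,recording_index,
                           gaze_file,toggle_file,stimulus_error
      gaze/*.csv           one gaze CSV per recording
      toggles/*.csv        one toggle CSV per AI recording (may be empty)

and writes a report bundle (ledger, metric table, comparison table,
pooled per-condition transition matrices, toggle summaries and a run
manifest with per-stage record counts, the seed and a config hash).
`run_study` performs the same computation on an in-memory
:class:`~gazekit.synth.StudyData`, and is what the CLI ``run`` command
calls after loading the directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aoi as aoi_mod
from . import qc as qc_mod
from .errors import PipelineError, ValidationError
from .events import IVTParams, detect_fixations
from .geometry import ViewingGeometry
from .io import (
    Condition,
    GazeRecording,
    read_aoi_layout,
    read_gaze_csv,
    read_toggle_log,
    write_aoi_layout,
    write_gaze_csv,
    write_toggle_log,
)
from .stats import compare_all
from .synth import StudyData, generate_study
from .toggles import ToggleState, build_intervals, summarize_toggles
from .transitions import TransitionMatrix, pool_matrices, transitions

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_study",
    "run_pipeline",
    "save_study",
    "load_study",
    "write_report",
]


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    data_dir: str = "study"
    out_dir: str = "report"
    velocity_threshold: float = 30.0
    min_fix_duration: float = 60.0
    max_gap_bridge: float = 25.0
    pad_deg: float = 3.0
    quality_threshold: float = 0.60
    grouping: str = "per_recording"
    seed: int = 0
    res_x: int = 1920
    res_y: int = 1080
    screen_w: float = 531.0
    screen_h: float = 299.0
    distance: float = 700.0
    outside_breaks_chain: bool = True
    overlap_mode: str = "all_pairs"
    holm: bool = False
    write_fixations: bool = False

    def validate(self) -> None:
        """Check every parameter against the owning module's preconditions
        before any stage runs."""
        if not (0 < self.quality_threshold <= 1):
            raise ValidationError("quality_threshold must lie in (0, 1]")
        if self.pad_deg < 0:
            raise ValidationError("pad_deg must be non-negative")
        if self.grouping not in ("per_recording", "per_participant_mean"):
            raise ValidationError(f"unknown grouping {self.grouping!r}")
        if self.overlap_mode not in ("all_pairs", "priority"):
            raise ValidationError(f"unknown overlap_mode {self.overlap_mode!r}")
        self.ivt_params()  # IVTParams and ViewingGeometry validate themselves

    def geometry(self) -> ViewingGeometry:
        return ViewingGeometry(
            res_x=self.res_x,
            res_y=self.res_y,
            screen_w=self.screen_w,
            screen_h=self.screen_h,
            distance=self.distance,
        )

    def ivt_params(self) -> IVTParams:
        return IVTParams(
            velocity_threshold=self.velocity_threshold,
            min_fix_duration=self.min_fix_duration,
            max_gap_bridge=self.max_gap_bridge,
            geometry=self.geometry(),
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


@dataclass
class PipelineResult:
    ledger: pd.DataFrame
    fixations: dict
    assignments: dict
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    transition_matrices: dict[str, TransitionMatrix]
    toggle_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_study(study: StudyData, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every analysis stage on an in-memory study."""
    config = config or PipelineConfig()
    config.validate()
    geom = config.geometry()
    params = config.ivt_params()
    layout = study.layout
    manifest: dict = {"seed": config.seed, "config_hash": config.hash(), "stages": {}}

    # --- stage 1: quality control -----------------------------------------
    ledger = qc_mod.apply_exclusions(
        study.recordings,
        quality_threshold=config.quality_threshold,
        error_flags=study.error_flags,
    )
    funnel = qc_mod.funnel_counts(ledger)
    manifest["stages"]["qc"] = funnel
    status_by_key = {
        (row.participant_id, row.image_id, row.recording_index): row.status
        for row in ledger.itertuples()
    }
    included = [
        r for r in study.recordings if status_by_key[r.key] == qc_mod.STATUS_INCLUDED
    ]

    # --- stage 2: fixation detection --------------------------------------
    fixations = {}
    for rec in included:
        try:
            fixations[rec.key] = detect_fixations(rec, params)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineError(f"stage detect failed for {rec.key}: {exc}") from exc
    manifest["stages"]["detect"] = {
        "recordings": len(included),
        "fixations": int(sum(len(f) for f in fixations.values())),
    }

    # --- stage 3: AOI assignment and metrics ------------------------------
    padded = aoi_mod.pad_aois(layout, geom, pad_deg=config.pad_deg)
    assignments = {}
    rows = []
    for rec in included:
        try:
            asg = aoi_mod.assign_fixations(fixations[rec.key], padded)
            assignments[rec.key] = asg
            rows.append(aoi_mod.compute_metrics(fixations[rec.key], asg, rec, layout))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage metrics failed for {rec.key}: {exc}") from exc
    metrics = aoi_mod.metric_table(rows)
    manifest["stages"]["metrics"] = {"rows": len(metrics)}

    # --- stage 4: transition matrices pooled per condition ----------------
    transition_matrices = {}
    for cond in (Condition.AI, Condition.NO_AI):
        mats = [
            transitions(
                assignments[rec.key],
                labels=layout.names,
                outside_breaks_chain=config.outside_breaks_chain,
                overlap_mode=config.overlap_mode,
            )
            for rec in included
            if rec.condition is cond
        ]
        if mats:
            transition_matrices[cond.value] = pool_matrices(mats)
    manifest["stages"]["transitions"] = {
        cond: m.total for cond, m in transition_matrices.items()
    }

    # --- stage 5: toggle intervals (AI condition only) --------------------
    ui_names = set(layout.names) - {layout.bitewing.name}
    toggle_rows = []
    for rec in included:
        if rec.condition is not Condition.AI:
            continue
        try:
            ivs = build_intervals(study.toggles.get(rec.key, []), rec.duration_ms)
            summ = summarize_toggles(
                ivs, fixations[rec.key], assignments[rec.key], ui_names
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage intervals failed for {rec.key}: {exc}") from exc
        on = summ.by_state[ToggleState.ON]
        off = summ.by_state[ToggleState.OFF]
        toggle_rows.append(
            {
                "participant_id": rec.participant_id,
                "image_id": rec.image_id,
                "recording_index": rec.recording_index,
                "n_activations": summ.n_activations,
                "total_on_ms": summ.total_on,
                "pct_on": summ.pct_on,
                "first_on_latency_ms": summ.first_on_latency,
                "first_on_pct": summ.first_on_pct,
                "on_fix_count": on.fix_count,
                "off_fix_count": off.fix_count,
                "on_median_fix_duration": on.median_fix_duration,
                "off_median_fix_duration": off.median_fix_duration,
                "on_fix_frequency": on.fix_frequency,
                "off_fix_frequency": off.fix_frequency,
            }
        )
    toggle_table = pd.DataFrame(toggle_rows)
    manifest["stages"]["intervals"] = {"rows": len(toggle_table)}

    # --- stage 6: condition comparisons -----------------------------------
    comparisons = compare_all(metrics, grouping=config.grouping, holm=config.holm)
    manifest["stages"]["compare"] = {"rows": len(comparisons)}

    return PipelineResult(
        ledger=ledger,
        fixations=fixations,
        assignments=assignments,
        metrics=metrics,
        comparisons=comparisons,
        transition_matrices=transition_matrices,
        toggle_table=toggle_table,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# disk layout


def _rec_stem(key: tuple[str, str, int]) -> str:
    return f"{key[0]}_{key[1]}_{key[2]}"


def save_study(study: StudyData, directory) -> Path:
    """Write a study to the documented directory layout."""
    root = Path(directory)
    (root / "gaze").mkdir(parents=True, exist_ok=True)
    (root / "toggles").mkdir(exist_ok=True)
    write_aoi_layout(study.layout, root / "layout.json")
    rows = []
    for rec in study.recordings:
        stem = _rec_stem(rec.key)
        gaze_file = f"gaze/{stem}.csv"
        write_gaze_csv(rec, root / gaze_file)
        toggle_file = ""
        if rec.condition is Condition.AI:
            toggle_file = f"toggles/{stem}.csv"
            write_toggle_log(study.toggles.get(rec.key, []), root / toggle_file)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "image_id": rec.image_id,
                "condition": rec.condition.value,
                "recording_index": rec.recording_index,
                "gaze_file": gaze_file,
                "toggle_file": toggle_file,
                "stimulus_error": int(
                    (rec.participant_id, rec.image_id) in study.error_flags
                ),
            }
        )
    pd.DataFrame(rows).to_csv(root / "sessions.csv", index=False)
    return root


def load_study(directory) -> StudyData:
    """Load a study directory written by :func:`save_study` (or by hand)."""
    root = Path(directory)
    layout = read_aoi_layout(root / "layout.json")
    sessions = pd.read_csv(root / "sessions.csv", keep_default_na=False)
    recordings = []
    toggles = {}
    error_flags = set()
    for row in sessions.itertuples():
        rec = read_gaze_csv(
            root / row.gaze_file,
            participant_id=str(row.participant_id),
            image_id=str(row.image_id),
            condition=Condition(row.condition),
            recording_index=int(row.recording_index),
        )
        recordings.append(rec)
        if str(row.toggle_file):
            toggles[rec.key] = read_toggle_log(root / row.toggle_file)
        if int(row.stimulus_error):
            error_flags.add((rec.participant_id, rec.image_id))
    return StudyData(
        layout=layout,
        recordings=recordings,
        toggles=toggles,
        error_flags=frozenset(error_flags),
        truths={},
        seed=None,
    )


def write_report(result: PipelineResult, out_dir, config: PipelineConfig) -> Path:
    """Write the report bundle; every file sits beside manifest.json, which
    carries the config hash, seed and per-stage record counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.ledger.to_csv(out / "ledger.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    result.toggle_table.to_csv(out / "toggle_summaries.csv", index=False)
    for cond, mat in result.transition_matrices.items():
        mat.to_dataframe().to_csv(out / f"transitions_{cond}.csv")
    if config.write_fixations:
        from .io import write_fixation_csv

        fixdir = out / "fixations"
        fixdir.mkdir(exist_ok=True)
        for key, fixes in result.fixations.items():
            write_fixation_csv(fixes, fixdir / f"{_rec_stem(key)}.csv")
    manifest = dict(result.manifest)
    manifest["config"] = asdict(config)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
        fh.write("\n")
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load the configured study directory, run all stages, write the report."""
    config.validate()
    study = load_study(config.data_dir)
    result = run_study(study, config)
    write_report(result, config.out_dir, config)
    return result
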