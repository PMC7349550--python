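"""End-to-end orchestration: simulate -> preprocess -> information
profiles -> synchronize & window -> features -> selection -> evaluation.

A single :class:`RunConfig` (constructible from YAML) drives every
stage; each stage is also callable on its own.  ``run_all`` writes the
intermediate artifacts (windows, feature tables), the final results
table and a manifest recording the seeds, configuration and artifact
checksums, so a rerun with the same config is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import CHANNELS, __version__
from .evalharness import run_matrix
from .featx import FrameSpec, extract_frames
from .infoquant import XafcmConfig, signal_information_profile
from .preprocess import preprocess_session
from .syncwin import (WindowSelection, select_window, smooth_profile,
                      synchronize)
from .synthio import CohortSpec, RecordingSession, generate_cohort, scaled_down_spec

__all__ = ["RunConfig", "PipelineError", "session_window", "cohort_features",
           "run_all", "default_scaled_down_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending session."""

    def __init__(self, stage: str, session: str | None, cause: Exception):
        self.stage = stage
        self.session = session
        msg = f"stage {stage!r} failed"
        if session:
            msg += f" on session {session}"
        super().__init__(f"{msg}: {cause}")


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    xafcm: XafcmConfig = field(default_factory=XafcmConfig)
    frame_lengths: tuple[int, ...] = (30, 60)
    signal_sets: tuple[str, ...] = ("all", "ecg", "emgz", "emgmf", "emg", "eda")
    conditions: tuple[str, ...] = ("a", "b", "c")
    classifiers: tuple[str, ...] = ("rf", "nn")
    max_lag_s: int = 120
    window_s: int = 300
    profile_warmup_s: int = 60
    profile_smooth_s: int = 3
    n_test_subjects: int = 12
    n_iterations: int = 10
    n_inner_folds: int = 10
    rf_trees: int | None = None
    corr_threshold: float = 0.9
    var_threshold: float | None = None
    do_selection: bool = True
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["subject_sd"] = dataclasses.asdict(self.cohort.subject_sd)
        d["cohort"]["effects"] = {
            k: dataclasses.asdict(v) for k, v in self.cohort.effects.items()}
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            c.pop("effects", None)
            c.pop("subject_sd", None)
            if "conditions" in c:
                c["conditions"] = tuple(c["conditions"])
            kwargs["cohort"] = CohortSpec(**c)
        if "xafcm" in kwargs:
            x = dict(kwargs["xafcm"])
            if "clip_percentiles" in x:
                x["clip_percentiles"] = tuple(x["clip_percentiles"])
            kwargs["xafcm"] = XafcmConfig(**x)
        for key in ("frame_lengths", "signal_sets", "conditions", "classifiers"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def default_scaled_down_config(seed: int = 0) -> RunConfig:
    """Desk-scale defaults: 12 subjects x 3 conditions x 12-min sessions,
    4 test subjects, random forests reduced to 500 trees."""
    return RunConfig(
        cohort=scaled_down_spec(seed=seed),
        n_test_subjects=4,
        rf_trees=500,
        master_seed=seed,
    )


def session_window(session: RecordingSession, xafcm: XafcmConfig,
                   max_lag_s: int, window_s: int = 300,
                   warmup_s: int = 60, smooth_s: int = 3) -> WindowSelection:
    """Information profiles -> lag synchronization -> window selection
    for one (already preprocessed) session.

    The first ``warmup_s`` seconds of every profile are excluded (the
    adaptive coder's learning transient would otherwise out-compete real
    activation structure) and profiles are smoothed with a ``smooth_s``
    moving average before lag estimation; the returned per-channel
    offsets map back to original session seconds."""
    profiles = {
        ch: smooth_profile(
            signal_information_profile(session.channels[ch], session.fs,
                                       xafcm, channel=ch)
            .bits_per_second[warmup_s:], smooth_s)
        for ch in CHANNELS
    }
    sync = synchronize(profiles, reference="ecg", max_lag_s=max_lag_s)
    win = select_window(sync, length_s=window_s)
    win.channel_offsets = {ch: off + warmup_s
                           for ch, off in win.channel_offsets.items()}
    return win


def cohort_features(sessions: list[RecordingSession], config: RunConfig
                    ) -> tuple[dict[int, pd.DataFrame], dict[str, dict]]:
    """Preprocess every session, select its window and extract feature
    tables for each configured frame length."""
    windows: dict[str, dict] = {}
    per_len: dict[int, list[pd.DataFrame]] = {f: [] for f in config.frame_lengths}
    for s in sessions:
        sid = f"{s.subject_id}/{s.condition}"
        try:
            filtered = preprocess_session(s)
        except Exception as e:  # pragma: no cover - defensive
            raise PipelineError("preprocess", sid, e) from e
        try:
            win = session_window(filtered, config.xafcm, config.max_lag_s,
                                 config.window_s, config.profile_warmup_s,
                                 config.profile_smooth_s)
        except Exception as e:
            raise PipelineError("window", sid, e) from e
        windows[sid] = {
            "start_s": win.start_s,
            "channel_offsets": win.channel_offsets,
        }
        for frame_s in config.frame_lengths:
            try:
                df = extract_frames(filtered, win, FrameSpec(frame_s))
            except Exception as e:
                raise PipelineError("features", sid, e) from e
            per_len[frame_s].append(df)
    tables = {f: pd.concat(dfs, ignore_index=True)
              for f, dfs in per_len.items()}
    return tables, windows


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write artifacts + manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        sessions = generate_cohort(config.cohort)
    except Exception as e:
        raise PipelineError("simulate", None, e) from e
    log.info("generated %d sessions", len(sessions))

    tables, windows = cohort_features(sessions, config)
    (out / "windows.json").write_text(json.dumps(windows, indent=1))
    for frame_s, df in tables.items():
        df.to_csv(out / f"features_{frame_s}s.csv", index=False)

    try:
        results = run_matrix(
            tables,
            signal_sets=config.signal_sets,
            conditions=config.conditions,
            classifiers=config.classifiers,
            master_seed=config.master_seed,
            n_test_subjects=config.n_test_subjects,
            n_iterations=config.n_iterations,
            rf_trees=config.rf_trees,
            do_selection=config.do_selection,
            n_inner=config.n_inner_folds,
        )
    except Exception as e:
        raise PipelineError("evaluate", None, e) from e
    results.to_csv(out / "results.csv", index=False)
    (out / "results.json").write_text(
        results.to_json(orient="records", indent=1))

    artifacts = sorted(p.name for p in out.iterdir()
                       if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "runtime_s": round(time.time() - t0, 2),
        "checksums": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
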