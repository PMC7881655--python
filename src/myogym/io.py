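"""Session manifests, command logs and report files.

All artefacts are plain text: CSV signal files with JSON sidecars
(:mod:`myogym.recording`), JSON model files (:class:`EmgRegressor`), a JSON
session manifest listing procedures and file paths, CSV command logs and
Motion-Test/metric reports, and JSON-lines game-episode logs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .control import DOF_NAMES, StreamResult
from .protocols import MotionTestTrial
from .recording import Procedure, read_recording, write_recording


def write_session(procedures: Sequence[Procedure], out_dir: str | Path,
                  extra_meta: dict | None = None) -> Path:
    """Write every recording of a session and a manifest.json indexing it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema_version": 1, "procedures": []}
    if extra_meta:
        manifest.update(extra_meta)
    for proc in procedures:
        proc_dir = out_dir / f"procedure{proc.index:02d}"
        proc_dir.mkdir(exist_ok=True)
        paths = []
        for i, rec in enumerate(proc.recordings):
            name = f"{i:02d}_{rec.movement}_{int(rec.level * 100):03d}.csv"
            write_recording(rec, proc_dir / name)
            paths.append(str(Path(proc_dir.name) / name))
        manifest["procedures"].append(
            {"index": proc.index, "posture": proc.posture, "recordings": paths}
        )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return out_dir / "manifest.json"


def read_session(manifest_path: str | Path) -> list[Procedure]:
    """Load a session written by :func:`write_session`."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed manifest {manifest_path}: {exc}") from exc
    if "procedures" not in manifest:
        raise ValueError(f"manifest {manifest_path} missing 'procedures'")
    root = manifest_path.parent
    procedures = []
    for entry in manifest["procedures"]:
        recs = [read_recording(root / p) for p in entry["recordings"]]
        procedures.append(
            Procedure(index=entry["index"], posture=entry["posture"],
                      recordings=recs)
        )
    return procedures


def write_command_log(result: StreamResult, path: str | Path) -> Path:
    """Command stream as CSV: timestamp_ms, pinch, rotation, flex_ext, open."""
    df = pd.DataFrame(result.commands, columns=list(DOF_NAMES))
    df.insert(0, "timestamp_ms", result.t_ms)
    df.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


def write_motion_test_report(trials: Sequence[MotionTestTrial],
                             path: str | Path) -> Path:
    """Motion Test report CSV: movement, level, outcome, time_s."""
    df = pd.DataFrame(
        [
            {"movement": t.movement, "level": t.level,
             "outcome": "success" if t.success else "failure",
             "time_s": t.time_s}
            for t in trials
        ]
    )
    df.to_csv(path, index=False, float_format="%.3f")
    return Path(path)


def write_episode_log(records: Sequence[dict], path: str | Path,
                      config: dict | None = None) -> Path:
    """Replayable JSON-lines episode log, config echoed on the first line."""
    path = Path(path)
    with path.open("w") as fh:
        if config is not None:
            fh.write(json.dumps({"config": config}) + "\n")
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return path
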