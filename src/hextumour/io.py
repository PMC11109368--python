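"""Tabular output writers and the run manifest.

All outputs are plain tab-separated tables so any downstream tool can read
them; the manifest is a JSON record (config snapshot, seed, package version,
per-file SHA-256 checksums) from which every output can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import ScenarioConfig
from .geostats import StepRecord

HISTORY_COLUMNS = [
    "step", "n_cancer", "delta_N", "n_mutualistic_advantaged",
    "n_immune_active", "general_G", "moran_I", "geary_C",
    "n_clone1", "n_clone2", "n_boosted", "n_births", "n_deaths",
    "n_kills", "n_mutualism_events",
]

EVENT_COLUMNS = ["step", "event_type", "agent_a", "agent_b", "q", "r"]

SNAPSHOT_COLUMNS = ["q", "r", "agent_type", "clone_id", "oncoprotein",
                    "mutualistic_flag", "immune_state"]


def history_frame(records: Sequence[StepRecord]) -> pd.DataFrame:
    """Per-step history as a DataFrame (undefined statistics are NaN)."""
    return pd.DataFrame(
        [{col: getattr(r, col) for col in HISTORY_COLUMNS} for r in records],
        columns=HISTORY_COLUMNS,
    )


def events_frame(events: Iterable[tuple]) -> pd.DataFrame:
    return pd.DataFrame(list(events), columns=EVENT_COLUMNS)


def snapshot_frame(state) -> pd.DataFrame:
    """One row per occupied site of the current lattice."""
    rows = []
    for cell in state.cancers.values():
        rows.append({
            "q": cell.position[0], "r": cell.position[1],
            "agent_type": cell.kind, "clone_id": cell.clone,
            "oncoprotein": cell.oncoprotein,
            "mutualistic_flag": int(cell.boost_consumed),
            "immune_state": "",
        })
    for imm in state.immunes.values():
        rows.append({
            "q": imm.position[0], "r": imm.position[1],
            "agent_type": "immune", "clone_id": "",
            "oncoprotein": "",
            "mutualistic_flag": "",
            "immune_state": ("attached" if imm.target is not None
                             else "active" if imm.active else "inactive"),
        })
    frame = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
    return frame.sort_values(["q", "r"]).reset_index(drop=True)


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g",
                 na_rep="NA", lineterminator="\n")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: ScenarioConfig, seed: int,
                   outputs: Sequence[str | Path]) -> Path:
    """Write ``manifest.json`` describing one run and its output files."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package": "hextumour",
        "version": __version__,
        "master_seed": int(seed),
        "config": _jsonable(config.to_dict()),
        "outputs": {Path(p).name: _sha256(Path(p)) for p in outputs},
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
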