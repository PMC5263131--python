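"""Exporting run logs: one CSV per monitor channel plus a run manifest."""

from __future__ import annotations

import datetime
import json
from pathlib import Path

from ..tf import MonitorLog

__all__ = ["export_run"]


def export_run(monitor: MonitorLog, directory, *, config_hash: str = "",
               seed: int = 0, duration_ms: float = 0.0) -> dict[str, Path]:
    """Write one CSV per monitor channel and a ``manifest.json``.

    CSV content depends only on the run (byte-identical under identical
    seeds); the manifest carries the config hash, seed, duration and a
    wall-clock timestamp. Returns a mapping channel -> written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for channel in monitor.channels:
        path = directory / (channel.replace("/", "_") + ".csv")
        path.write_text(monitor.to_csv(channel))
        written[channel] = path
    manifest = {
        "config_hash": config_hash,
        "seed": int(seed),
        "duration_ms": float(duration_ms),
        "channels": list(monitor.channels),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = directory / "manifest.json"
    return written
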