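"""Run manifests: enough metadata beside every CLI output to reproduce
it exactly (resolved configuration, master seed, package version)."""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Any


def write_manifest(
    out_path: str | Path,
    command: str,
    config: dict[str, Any],
    master_seed: int | None,
    outputs: list[str],
) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "master_seed": master_seed,
        "package": "relapsim",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": outputs,
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
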