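"""Run manifests: config snapshot, input digests, seed, version, timestamps."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__

MANIFEST_NAME = "manifest.json"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    params: dict,
    inputs: list,
    seed: int | None = None,
) -> Path:
    """Write (or overwrite) the single manifest of an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "params": {k: v for k, v in sorted(params.items())},
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).exists()
        },
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
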