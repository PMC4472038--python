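"""Run manifests: resolved parameters, input digests, seed, version."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    params: dict,
    inputs: dict,
    seed: int | None,
) -> Path:
    """Write ``manifest.json`` next to a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in sorted(params.items())},
        "inputs": {
            name: {"path": str(p), "sha256": _digest(Path(p))}
            for name, p in sorted(inputs.items())
            if p is not None
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
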