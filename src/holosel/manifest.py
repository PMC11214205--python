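"""Run manifests: config snapshot, seeds and output checksums."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int | None, files: list[str | Path]) -> dict:
    """Write a JSON manifest listing the config, seed and checksums of outputs."""
    from . import __version__

    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "outputs": {str(f): sha256_file(f) for f in files},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
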