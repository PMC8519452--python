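"""Run manifests: config snapshot, seed, version, output checksums."""

from __future__ import annotations

import hashlib
import json
import os
from typing import Any, Mapping, Optional, Sequence


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str,
    subcommand: str,
    config: Mapping[str, Any],
    outputs: Sequence[str],
    seed: Optional[int] = None,
) -> str:
    """Write manifest.json into out_dir, checksumming every listed output."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "config": dict(config),
        "seed": seed,
        "version": __version__,
        "outputs": [
            {"path": os.path.relpath(p, out_dir), "sha256": _sha256(p)}
            for p in outputs
        ],
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
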