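"""Run manifests: provenance metadata embedded in every analysis output."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import metadata as _im


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def package_version() -> str:
    try:
        return _im.version("tracerkin")
    except _im.PackageNotFoundError:
        return "unknown"


def make_manifest(argv, inputs=None, seed=None, config=None) -> dict:
    """Build the manifest for one command invocation.

    ``inputs`` maps role names to file paths (digested with SHA-256);
    ``config`` is any JSON-serialisable options object (hashed).  The
    timestamp is the only field expected to vary between identical runs.
    """
    manifest = {
        "command": list(argv),
        "package": "tracerkin",
        "version": package_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if seed is not None:
        manifest["seed"] = seed
    if inputs:
        manifest["inputs"] = {name: {"path": str(p), "sha256": _digest(p)}
                              for name, p in inputs.items()}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        manifest["config_sha256"] = hashlib.sha256(blob).hexdigest()
    return manifest
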