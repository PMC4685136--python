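"""Reproducible run manifests.

Every CLI run writes a ``manifest.json`` next to its outputs recording the
effective configuration, SHA-256 checksums of the input files, the seed,
the package version and a timestamp.  Re-running with an identical
manifest (same inputs, config and seed) reproduces the outputs exactly —
the whole pipeline is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["RunManifest", "write_manifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return repr(obj)
    return obj


@dataclasses.dataclass
class RunManifest:
    command: str
    config: dict
    inputs: dict[str, str]
    seed: int | None
    version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config, input_paths: dict[str, str | Path], seed: int | None) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=_jsonable(config),
            inputs={name: _sha256(Path(p)) for name, p in input_paths.items()},
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return out
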