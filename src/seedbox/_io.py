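"""Artifact serialization with provenance headers.

Every CSV artifact begins with ``#``-prefixed provenance lines (package
version, root seed, config hash). No timestamps are written, so re-running
a stage with the same seed reproduces its outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["config_hash", "write_csv", "read_csv"]


def config_hash(config) -> str:
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# seedbox-version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config-sha256: {cfg_hash}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
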