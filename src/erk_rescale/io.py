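"""CSV interchange with provenance headers.

Every stage output is long-format CSV prefixed with ``#``-comment lines
recording the producing stage, the configuration hash and the seed, so a
run directory is self-describing and diff-able.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, stage: str = "", cfg_hash: str = "", seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage}\n# config_hash={cfg_hash}\n# seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
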