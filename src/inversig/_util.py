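"""Small shared helpers: seeding, hashing, deterministic TSV output."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed.

    Stable across runs and platforms: SHA-256 of ``"<master>:<stage>"``,
    reduced below 2**31 so it is usable everywhere numpy accepts a seed.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a TSV deterministically (fixed float format, LF line endings)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format, lineterminator="\n")


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
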