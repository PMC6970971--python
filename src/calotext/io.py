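"""Reading and writing the pipeline's line-delimited formats.

Posts travel as JSON-lines (one object per line with keys ``id``,
``text``, ``region``, ``timestamp``) or as a CSV with the same header;
cleaned posts as JSON-lines with ``id``, ``region``, ``tokens`` and
sentence ``boundaries``.  Every pipeline run writes a manifest (config
hash, seed, versions) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cleaning import CleanPost, RawPost
from .errors import SchemaError

__all__ = [
    "read_posts",
    "write_posts",
    "read_clean_posts",
    "write_clean_posts",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def read_posts(path: str | Path, skip_malformed: bool = False) -> tuple[list[RawPost], list[int]]:
    """Read raw posts from JSON-lines or CSV.

    Returns (posts, skipped line numbers).  Malformed records raise
    :class:`SchemaError` unless ``skip_malformed``, in which case they are
    skipped with a logged id/line.
    """
    path = Path(path)
    posts: list[RawPost] = []
    skipped: list[int] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("id", "text", "region"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column '{col}'")
        for i, row in df.iterrows():
            posts.append(
                RawPost(
                    id=str(row["id"]),
                    text=str(row["text"]),
                    region=str(row["region"]),
                    timestamp=str(row["timestamp"]) if "timestamp" in df.columns else None,
                )
            )
        return posts, skipped
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            posts.append(
                RawPost(
                    id=str(obj["id"]),
                    text=str(obj["text"]),
                    region=str(obj.get("region", "all")),
                    timestamp=obj.get("timestamp"),
                )
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            if not skip_malformed:
                raise SchemaError(f"{path}:{lineno}: malformed post record ({exc})") from exc
            logger.warning("skipping malformed record at %s:%d", path, lineno)
            skipped.append(lineno)
    return posts, skipped


def write_posts(posts: list[RawPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"id": p.id, "text": p.text, "region": p.region, "timestamp": p.timestamp}
                )
                + "\n"
            )


def write_clean_posts(posts: list[CleanPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {
                        "id": p.id,
                        "region": p.region,
                        "tokens": list(p.tokens),
                        "boundaries": list(p.boundaries),
                    }
                )
                + "\n"
            )


def read_clean_posts(path: str | Path) -> list[CleanPost]:
    posts = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        posts.append(
            CleanPost(
                id=str(obj["id"]),
                region=str(obj["region"]),
                tokens=tuple(obj["tokens"]),
                boundaries=tuple(obj.get("boundaries", ())),
            )
        )
    return posts


def write_manifest(path: str | Path, command: str, params: dict, seed: int | None = None) -> dict:
    """Write a reproducibility manifest next to a command's outputs."""
    serializable = {k: v for k, v in sorted(params.items())}
    blob = json.dumps(serializable, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "params": serializable,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "calotext_version": __version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
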