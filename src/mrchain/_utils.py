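"""Small shared helpers: seed derivation and content hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def derive_seed(seed: int, label: str) -> int:
    """Deterministically derive a stage seed from a global seed and a label.

    Hash-based so adding a new stage never perturbs the randomness consumed by
    existing stages. Result fits in a signed 32-bit integer.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(obj) -> str:
    """Stable hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()
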