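"""Image and table I/O helpers with provenance headers.

Tabular outputs are UTF-8 CSV with a leading ``#``-comment provenance line
(package version, seed, config hash) so every artifact records how it was
produced; readers skip comment lines.  Images are 8-bit PNG/TIFF via PIL.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import FormatError

VERSION = "0.1.0"


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return arr


def read_mask(path) -> np.ndarray:
    """Read a single-channel region mask with values {0, 1, 2}."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise FormatError(f"{path}: region mask must be single-channel")
    if not np.isin(arr, (0, 1, 2)).all():
        raise FormatError(f"{path}: region mask values must be in {{0,1,2}}")
    return arr.astype(np.uint8)


def write_image(path, arr: np.ndarray) -> None:
    Image.fromarray(np.asarray(arr)).save(path)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def provenance_line(seed: int, cfg_hash: str) -> str:
    return f"# ihcquant={VERSION} seed={seed} config={cfg_hash}"


def write_table(path, df: pd.DataFrame, seed: int = 0, cfg_hash: str = "-") -> None:
    """CSV with a provenance comment header; empty cells encode missing."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed, cfg_hash) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
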