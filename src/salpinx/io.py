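"""Reading tiles, manifests and plain-text configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterator, List, Optional

import numpy as np
import pandas as pd

from .stain import Group, Region, RGBTile

__all__ = ["read_tile", "read_manifest", "iter_manifest_tiles", "read_config"]


def read_tile(
    path: Path, case_id: str, group: str, region: str = "unspecified"
) -> RGBTile:
    """Load one 8-bit RGB tile from a PNG or TIFF file."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RGBTile(arr.astype(np.uint8), case_id=case_id, group=Group(group), region=Region(region))


def read_manifest(path: Path) -> pd.DataFrame:
    """Read the tile manifest CSV (tile_path, case_id, group, region)."""
    df = pd.read_csv(path)
    required = {"tile_path", "case_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "region" not in df.columns:
        df["region"] = "unspecified"
    return df


def iter_manifest_tiles(manifest: pd.DataFrame, root: Path) -> Iterator[RGBTile]:
    """Yield tiles listed in a manifest, paths resolved against ``root``."""
    root = Path(root)
    for row in manifest.itertuples(index=False):
        yield read_tile(root / row.tile_path, str(row.case_id), str(row.group), str(row.region))


def read_config(path: Path) -> Dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; values stay strings and
    are interpreted by the consumer.
    """
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
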