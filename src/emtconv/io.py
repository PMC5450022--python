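"""Readers and writers for the pipeline's file formats.

Movies are 16-bit multi-page TIFF label stacks (or per-frame PNG);
tables are TSV with an optional ``#``-comment header carrying the
config hash and seed; gene sets are GMT (see :mod:`emtconv.scoring`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .morphology import CellObservation


def write_label_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) label stack as 16-bit multi-page TIFF."""
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    tifffile.imwrite(str(path), stack.astype(np.uint16),
                     photometric="minisblack")


def read_label_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_png_frames(stack: np.ndarray, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write each frame as a 16-bit PNG (frame index zero-padded)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(stack):
        p = directory / f"{prefix}_{t:04d}.png"
        iio.imwrite(p, frame.astype(np.uint16))
        paths.append(p)
    return paths


def read_png_frames(directory: str | Path, prefix: str = "frame") -> np.ndarray:
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob(f"{prefix}_*.png"))
    if not paths:
        raise FileNotFoundError(f"no {prefix}_*.png frames under {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_table(df: pd.DataFrame, path: str | Path,
                header_comment: Optional[str] = None) -> None:
    """TSV writer with an optional leading ``#`` comment line."""
    path = Path(path)
    with open(path, "w") as f:
        if header_comment:
            for line in header_comment.splitlines():
                f.write(f"# {line}\n")
        df.to_csv(f, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def observations_to_table(
    observations: Sequence[Sequence[CellObservation]],
) -> pd.DataFrame:
    """Flatten per-frame observations into one table (documented
    columns; one row per cell per frame)."""
    rows = []
    for frame_obs in observations:
        for o in frame_obs:
            rows.append(
                (o.frame, o.label, o.centroid[0], o.centroid[1], o.area,
                 o.perimeter, o.perimeter_to_area, o.length, o.width,
                 o.length_to_width, o.neurite_count, o.nucleus_area,
                 o.nucleus_to_cytosol, o.assigned_class)
            )
    return pd.DataFrame(
        rows,
        columns=["frame", "label", "row", "col", "area", "perimeter",
                 "perimeter_to_area", "length", "width", "length_to_width",
                 "neurite_count", "nucleus_area", "nucleus_to_cytosol",
                 "assigned_class"],
    )


def expression_to_tsv(expr: pd.DataFrame, meta: pd.DataFrame,
                      expr_path: str | Path, meta_path: str | Path) -> None:
    """Expression matrix (genes × samples, header row = sample ids) plus
    the sample-metadata sidecar marking control/treatment/replicate."""
    expr.rename_axis("gene").to_csv(expr_path, sep="\t")
    meta.to_csv(meta_path, sep="\t", index=False)


def expression_from_tsv(expr_path: str | Path, meta_path: str | Path,
                        dataset_id: str, scale: str = "linear"):
    from .meta import RawDataset

    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    return RawDataset(dataset_id, expr, meta, scale=scale)
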