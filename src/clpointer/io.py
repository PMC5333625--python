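"""File plumbing: 16-bit TIFF images, coordinate CSVs, transform/field JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .register import DistortionField, SimilarityTransform
from .simulate import RasterImage

__all__ = [
    "write_image", "read_image",
    "write_coords_csv", "read_coords_csv",
    "write_transform", "read_transform",
    "write_field", "read_field",
]


def write_image(path: str | Path, image: RasterImage) -> None:
    """Write as 16-bit grayscale TIFF with pixel size and frame in metadata."""
    px = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path), px,
        metadata={"pixel_size_nm": image.pixel_size_nm, "frame": image.frame})


def read_image(path: str | Path, pixel_size_nm: float | None = None,
               frame: str | None = None) -> RasterImage:
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    ps = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    fr = frame if frame is not None else meta.get("frame", "FM")
    if ps is None:
        raise ValueError(f"{path}: pixel size missing from metadata; pass pixel_size_nm")
    return RasterImage(pixels, float(ps), str(fr))


def write_coords_csv(path: str | Path, coords: np.ndarray, frame: str,
                     ids: np.ndarray | None = None) -> None:
    coords = np.atleast_2d(coords)
    if ids is None:
        ids = np.arange(coords.shape[0])
    pd.DataFrame({"id": ids, "x_px": coords[:, 0], "y_px": coords[:, 1],
                  "frame": frame}).to_csv(path, index=False)


def read_coords_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"id", "x_px", "y_px"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_transform(path: str | Path, t: SimilarityTransform,
                    fm_pixel_size_nm: float | None = None,
                    em_pixel_size_nm: float | None = None,
                    extra: dict | None = None) -> None:
    d = t.to_dict(fm_pixel_size_nm, em_pixel_size_nm)
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_transform(path: str | Path) -> SimilarityTransform:
    return SimilarityTransform.from_dict(json.loads(Path(path).read_text()))


def write_field(path: str | Path, field: DistortionField) -> None:
    Path(path).write_text(json.dumps(field.to_dict(), indent=1) + "\n")


def read_field(path: str | Path) -> DistortionField:
    return DistortionField.from_dict(json.loads(Path(path).read_text()))
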