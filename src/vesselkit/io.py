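"""Reading and writing the pipeline's on-disk formats.

Images and masks travel as multi-page TIFF (one page per z-slice), graphs as
JSON, per-segment tables as CSV.  Voxel spacing is written into the TIFF in
ImageJ style (x/y resolution tags + ``spacing`` for z) so stacks round-trip
with their physical calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, Spacing, VesselSegment, as_binary


def write_image(path, stack: ImageStack) -> None:
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def write_mask(path, mask: np.ndarray, voxel_size_um: Spacing = (1.0, 1.0, 1.0)) -> None:
    mask = as_binary(mask) * np.uint8(255)
    dz, dy, dx = voxel_size_um
    tifffile.imwrite(
        path,
        mask,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def _spacing_from_tiff(tf: tifffile.TiffFile) -> Spacing:
    dz = dy = dx = 1.0
    try:
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            dz = float(tf.imagej_metadata["spacing"])
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                dx = den / num
        if yres is not None:
            num, den = yres.value
            if num:
                dy = den / num
    except Exception:
        pass
    return (dz, dy, dx)


def read_image(path, voxel_size_um: Spacing | None = None) -> ImageStack:
    """Read a multi-page TIFF stack; spacing from metadata unless given."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = voxel_size_um or _spacing_from_tiff(tf)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(np.asarray(data, dtype=np.float32), spacing)


def read_mask(path) -> np.ndarray:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return as_binary(data)


def segments_to_frame(segments: list[VesselSegment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        (z0, y0, x0), (z1, y1, x1) = s.endpoints
        rows.append(
            {
                "edge_id": s.edge_id,
                "length_um": s.length_um,
                "diameter_um": s.diameter_um,
                "tortuosity": s.tortuosity,
                "end0_z": z0, "end0_y": y0, "end0_x": x0,
                "end1_z": z1, "end1_y": y1, "end1_x": x1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "edge_id", "length_um", "diameter_um", "tortuosity",
            "end0_z", "end0_y", "end0_x", "end1_z", "end1_y", "end1_x",
        ],
    )


def write_segments_csv(path, segments: list[VesselSegment]) -> None:
    segments_to_frame(segments).to_csv(path, index=False)
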