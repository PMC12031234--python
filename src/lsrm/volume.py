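"""Z-stack assembly: axial interpolation and maximum intensity projections."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .image_io import ImageSlice, ImageStack

__all__ = ["interpolate_z", "max_intensity_projection", "render_volume"]


def interpolate_z(stack: ImageStack, factor: int) -> ImageStack:
    """Insert ``factor - 1`` linearly interpolated planes between neighbours.

    Output has ``(n - 1) * factor + 1`` slices with the Z step divided by
    ``factor``; interpolated values lie between the neighbouring slice
    values pixelwise.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if stack.n_slices < 2:
        raise ValueError("interpolation requires at least 2 slices")
    if factor == 1:
        return ImageStack(list(stack.slices), stack.z_step_um)
    data = stack.data
    pitch = stack.pixel_pitch_um
    out: list[ImageSlice] = []
    for i in range(stack.n_slices - 1):
        for j in range(factor):
            t = j / factor
            plane = (1.0 - t) * data[i] + t * data[i + 1]
            out.append(ImageSlice.from_array(plane, pitch))
    out.append(ImageSlice.from_array(data[-1], pitch))
    return ImageStack(out, stack.z_step_um / factor)


def max_intensity_projection(stack: ImageStack, axis: str = "z") -> ImageSlice:
    """Per-pixel maximum along the chosen axis.

    Axis ``"z"`` projects onto the image plane; ``"y"``/``"x"`` give side
    views whose row direction is Z (display aspect ratio is
    ``z_step / pixel_pitch``, handled at render time).
    """
    ax = {"z": 0, "y": 1, "x": 2}.get(axis.lower())
    if ax is None:
        raise ValueError("axis must be one of 'z', 'y', 'x'")
    proj = stack.data.max(axis=ax)
    return ImageSlice.from_array(proj, stack.pixel_pitch_um)


def _to_png(pixels: np.ndarray, path: Path, z_aspect: int = 1) -> None:
    img = np.clip(pixels, 0.0, 1.0)
    if z_aspect > 1:  # stretch the Z rows to physical aspect
        img = np.repeat(img, z_aspect, axis=0)
    Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(path)


def render_volume(
    stack: ImageStack, output_dir: str | Path, prefix: str = "volume"
) -> dict[str, Path]:
    """Write top-view and side-view projections plus an orthogonal triptych.

    Output is three grayscale PNGs; side views are stretched along Z by the
    rounded ``z_step / pixel_pitch`` ratio so voxels render near-isotropic.
    Purely presentational and byte-deterministic for fixed input.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    z_aspect = max(1, round(stack.z_step_um / stack.pixel_pitch_um))

    top = max_intensity_projection(stack, "z").pixels
    side_y = max_intensity_projection(stack, "y").pixels
    side_x = max_intensity_projection(stack, "x").pixels

    paths = {
        "top": output_dir / f"{prefix}_mip_top.png",
        "side": output_dir / f"{prefix}_mip_side.png",
        "triptych": output_dir / f"{prefix}_triptych.png",
    }
    _to_png(top, paths["top"])
    _to_png(side_y, paths["side"], z_aspect)

    side_y_s = np.repeat(side_y, z_aspect, axis=0)
    side_x_s = np.repeat(side_x, z_aspect, axis=0)
    gap_v = np.zeros((top.shape[0], 4))
    row1 = np.concatenate([top, gap_v, np.ones((top.shape[0], 0))], axis=1)
    width = max(row1.shape[1], side_y_s.shape[1] + 4 + side_x_s.shape[1])

    def _fit(block: np.ndarray) -> np.ndarray:
        padded = np.zeros((block.shape[0], width))
        padded[:, : block.shape[1]] = block
        return padded

    row2 = np.concatenate([side_y_s, np.zeros((side_y_s.shape[0], 4)), side_x_s], axis=1)
    gap_h = np.zeros((4, width))
    canvas = np.concatenate([_fit(row1), gap_h, _fit(row2)], axis=0)
    _to_png(canvas, paths["triptych"])
    return paths
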