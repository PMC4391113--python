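"""Grey-scale rendering of a visual field.

A minimal analogue of the familiar perimetric grey-scale plot: sensitivity
is linearly interpolated between the tested locations onto a raster over
the central 30 degrees and mapped to grey levels, darker = lower dB.  The
rendering is fully deterministic for a given field.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from scipy.interpolate import griddata

from .field import VisualField
from .grid import GRID_30_2

__all__ = ["greyscale_render"]

#: dB range mapped onto black..white.
_DB_LO, _DB_HI = 0.0, 40.0


def greyscale_render(field: VisualField, size: int = 128) -> Image.Image:
    """Render a right-eye field as a ``size`` x ``size`` grey-scale image.

    Linear interpolation inside the tested area, nearest-neighbour fill
    outside it; 0 dB maps to black, 40 dB to white.  Note the image y axis
    points down, so the top rows show the superior field.
    """
    if field.eye != "right":
        raise ValueError("render expects right-eye format; mirror first")
    mask = GRID_30_2.analysable_mask
    pts = np.column_stack([GRID_30_2.x[mask], GRID_30_2.y[mask]])
    vals = field.sensitivities[mask]

    xs = np.linspace(-30, 30, size)
    ys = np.linspace(30, -30, size)  # top of image = superior field
    gx, gy = np.meshgrid(xs, ys)
    lin = griddata(pts, vals, (gx, gy), method="linear")
    near = griddata(pts, vals, (gx, gy), method="nearest")
    img = np.where(np.isnan(lin), near, lin)
    # snap away interpolation noise (~1e-13 dB) so grey levels that land
    # exactly on a rounding boundary resolve identically at every pixel
    img = np.round(img, 6)

    grey = np.clip((img - _DB_LO) / (_DB_HI - _DB_LO), 0.0, 1.0)
    return Image.fromarray(np.round(grey * 255).astype(np.uint8), mode="L")
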