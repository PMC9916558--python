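"""Shared DAB color model.

Immunoreactivity (IR) of a pixel is defined as ``255 - luminance`` with the
Rec.601 luminance ``0.299 R + 0.587 G + 0.114 B``, anchoring 0 at no staining
(white) and 255 at full saturation (black). The synthetic section generator
and the IR quantifier both use this mapping so that the generator is exactly
invertible by the quantifier.
"""

from __future__ import annotations

import numpy as np

#: Reference DAB brown at full chroma; luminance ~78.
DAB_BROWN = np.array([120.0, 66.0, 30.0])

_LUM_W = np.array([0.299, 0.587, 0.114])
_WHITE = np.array([255.0, 255.0, 255.0])
_BROWN_LUM = float(_LUM_W @ DAB_BROWN)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec.601 luminance of an ``(..., 3)`` RGB array (float, unrounded)."""
    return np.asarray(rgb, dtype=float) @ _LUM_W


def ir_to_rgb(ir: float) -> np.ndarray:
    """RGB triplet of a DAB-brown pixel with the requested IR.

    Light staining (IR below ``255 - lum(brown)``) blends white toward brown;
    stronger staining darkens the brown toward black. IR 0 maps to white,
    IR 255 to black.
    """
    ir = float(ir)
    if not 0.0 <= ir <= 255.0:
        raise ValueError(f"IR must be in [0, 255], got {ir}")
    ir_at_brown = 255.0 - _BROWN_LUM
    if ir <= ir_at_brown:
        t = ir / ir_at_brown
        rgb = _WHITE + t * (DAB_BROWN - _WHITE)
    else:
        s = (255.0 - ir) / _BROWN_LUM
        rgb = DAB_BROWN * s
    return rgb


def pixel_ir(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel IR: 255 minus per-pixel-rounded luminance."""
    return 255.0 - np.rint(luminance(rgb))
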