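"""Inference helpers: size-safe prediction on arbitrary images."""

from __future__ import annotations

import numpy as np


def pad_to_divisible(image: np.ndarray, factor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad an (H, W, C) image so both spatial dims divide ``factor``.

    Returns the padded image and the original (H, W) for cropping back.
    """
    h, w = image.shape[:2]
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return image, (h, w)


def predict_image(model, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability for one (H, W, 3) image in [0, 1].

    Inputs whose size does not divide 2**(depth-1) are reflect-padded for
    the forward pass and the output cropped back, so the result always has
    the input's shape.
    """
    factor = 2 ** (model.config.depth - 1)
    padded, (h, w) = pad_to_divisible(np.asarray(image, dtype=np.float32), factor)
    batch = np.transpose(padded, (2, 0, 1))[None]
    prob = model.predict_proba(batch)[0, 0]
    return prob[:h, :w]
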