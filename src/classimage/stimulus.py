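"""Stimulus construction: noisy faces and prototype reconstruction.

A stimulus is the template image blended with a rescaled noise image:

    stimulus = (1 - blend) * template + blend * rescale(noise)

where ``rescale`` maps the noise affinely so that its theoretical amplitude
range [-B, B] spans [0, 1] (B is the basis amplitude bound).  Because the
bound is hard, the blend keeps every pixel inside [0, 1] and no clipping
ever fires for blend <= 1; analysis therefore sees an exactly linear
function of the noise parameters.  Quantization to 8 bits happens only on
export for presentation.

Prototypes render the inferred class appearance explicit: the classification
image is rescaled to a target peak amplitude and added to (female) or
subtracted from (male) the template.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "load_template",
    "save_image",
    "superimpose",
    "make_prototypes",
    "export_stimulus_set",
]

DEFAULT_BLEND = 0.5


def load_template(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float image in [0, 1]."""
    img = Image.open(path).convert("L")
    arr = np.asarray(img, dtype=float) / 255.0
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"template must be square, got {arr.shape}")
    return arr


def save_image(image: np.ndarray, path) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def rescale_noise(noise: np.ndarray, amplitude_bound: float) -> np.ndarray:
    """Affine map of the noise from [-bound, bound] onto [0, 1]."""
    if amplitude_bound <= 0:
        raise ValueError("amplitude_bound must be positive")
    return (np.asarray(noise, dtype=float) + amplitude_bound) / (2.0 * amplitude_bound)


def superimpose(template: np.ndarray, noise: np.ndarray, blend: float = DEFAULT_BLEND,
                amplitude_bound: float = 60.0) -> np.ndarray:
    """Blend a noise image onto the template.

    Parameters
    ----------
    template : array in [0, 1], same shape as the noise.
    noise : raw (un-rescaled) noise image from the basis.
    blend : noise weight in (0, 1]; 0.5 gives the 50/50 mixture used for
        the heavy-noise classification task.
    amplitude_bound : theoretical |noise| bound used for rescaling; pass
        ``basis.amplitude_bound`` for the generating basis (default 60 is
        the bound of the default 5-scale, 6-orientation, 2-phase basis).
    """
    template = np.asarray(template, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if template.shape != noise.shape:
        raise ValueError(
            f"template shape {template.shape} != noise shape {noise.shape}"
        )
    if not (0.0 < blend <= 1.0):
        raise ValueError(f"blend must be in (0, 1], got {blend}")
    stim = (1.0 - blend) * template + blend * rescale_noise(noise, amplitude_bound)
    return np.clip(stim, 0.0, 1.0)


def make_prototypes(template: np.ndarray, ci_pixels: np.ndarray,
                    peak: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Female and male prototype images from a classification image.

    The CI (female-minus-male convention) is rescaled so its maximum
    absolute pixel value equals ``peak``, then added to the template for
    the female prototype and subtracted for the male one; results are
    clipped to [0, 1].
    """
    template = np.asarray(template, dtype=float)
    ci_pixels = np.asarray(ci_pixels, dtype=float)
    if template.shape != ci_pixels.shape:
        raise ValueError(
            f"template shape {template.shape} != CI shape {ci_pixels.shape}"
        )
    m = np.max(np.abs(ci_pixels))
    if m == 0:
        raise ValueError("all-zero classification image: no direction to rescale")
    scaled = ci_pixels * (peak / m)
    female = np.clip(template + scaled, 0.0, 1.0)
    male = np.clip(template - scaled, 0.0, 1.0)
    return female, male


def export_stimulus_set(stimuli, directory, pv_ids=None, seed=None,
                        blend: float = DEFAULT_BLEND) -> pd.DataFrame:
    """Write stimuli as 8-bit PNGs plus a CSV manifest.

    ``stimuli`` is an iterable of float images in [0, 1]; ``pv_ids`` gives
    the parameter-vector id of each stimulus (defaults to the position).
    Returns the manifest (stimulus_id, pv_id, filename, seed, blend), also
    written to ``manifest.csv`` in the directory.  The written PNGs
    round-trip bit-exactly through 8 bits.
    """
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, stim in enumerate(stimuli):
        pv = int(pv_ids[i]) if pv_ids is not None else i
        fname = f"stimulus_{i:06d}.png"
        try:
            save_image(stim, directory / fname)
        except OSError as exc:
            raise OSError(f"failed writing stimulus to {directory / fname}: {exc}") from exc
        rows.append((i, pv, fname, seed, blend))
    manifest = pd.DataFrame(
        rows, columns=["stimulus_id", "pv_id", "filename", "seed", "blend"]
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
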