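"""One-layer CI classifier: class separation of CI-weighted activations.

A classification image doubles as the weight map of a one-layer network
with a single output unit: the activation of an input face is the inner
product of the (mean-centered) image with the CI pixels.  If the CI truly
captures the female/male difference, the activation distributions of
female and male face populations separate; the separation is summarized by
Cohen's d with the sign of female-mean minus male-mean.  A pixel-permuted
CI provides the chance baseline: it preserves the weight histogram but
destroys the spatial structure, so activations of the two classes should
overlap.

Mean-centering each input image removes overall-brightness confounds; it
is the default and can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationDistribution",
    "ci_activation",
    "separation",
    "randomized_ci_baseline",
    "load_class_images",
]


def load_class_images(directory) -> np.ndarray:
    """Read a directory of 8-bit grayscale PNGs as an (n, N, N) stack in [0, 1].

    Files are read in sorted name order; all images must share one shape.
    This is the on-disk layout one class of a population uses (see
    ``classimage.synthetic.export_population``).
    """
    from pathlib import Path

    from .stimulus import load_template

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG images in {directory}")
    return np.stack([load_template(p) for p in paths])


@dataclass
class ActivationDistribution:
    """Per-class activations and their standardized separation."""

    activations_female: np.ndarray
    activations_male: np.ndarray
    mean_female: float
    mean_male: float
    pooled_sd: float
    cohens_d: float               # sign: female mean minus male mean


def ci_activation(ci_pixels: np.ndarray, image: np.ndarray,
                  center: bool = True) -> float:
    """Activation of one image under the CI weight map.

    ``sum((image - image mean) * ci_pixels)`` — a full-image inner product,
    not a sliding convolution; equivalently one output unit with the CI as
    its incoming weights.  With ``center`` the activation is invariant to
    adding a constant to the image and is exactly 0 for constant images.
    """
    ci_pixels = np.asarray(ci_pixels, dtype=float)
    image = np.asarray(image, dtype=float)
    if ci_pixels.shape != image.shape:
        raise ValueError(
            f"image shape {image.shape} != CI shape {ci_pixels.shape}"
        )
    if center:
        image = image - image.mean()
    return float(np.sum(image * ci_pixels))


def _activations(ci: np.ndarray, images: np.ndarray, center: bool) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    X = images.reshape(images.shape[0], -1)
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    return X @ np.asarray(ci, dtype=float).ravel()


def _cohens_d(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    sp = float(np.sqrt(sp2))
    if sp == 0:
        raise ValueError("degenerate pooled SD: activations are constant")
    return (float(a.mean()) - float(b.mean())) / sp, sp


def separation(ci: np.ndarray, female_images: np.ndarray,
               male_images: np.ndarray, center: bool = True) -> ActivationDistribution:
    """Activation distributions and Cohen's d between the two classes.

    ``female_images`` / ``male_images`` are (n, N, N) stacks (n >= 2 each)
    of pre-aligned grayscale images in [0, 1].
    """
    female_images = np.asarray(female_images, dtype=float)
    male_images = np.asarray(male_images, dtype=float)
    if len(female_images) < 2 or len(male_images) < 2:
        raise ValueError("need at least 2 images per class")
    af = _activations(ci, female_images, center)
    am = _activations(ci, male_images, center)
    d, sp = _cohens_d(af, am)
    return ActivationDistribution(
        activations_female=af,
        activations_male=am,
        mean_female=float(af.mean()),
        mean_male=float(am.mean()),
        pooled_sd=sp,
        cohens_d=d,
    )


def randomized_ci_baseline(ci: np.ndarray, female_images: np.ndarray,
                           male_images: np.ndarray, n_perm: int = 200,
                           seed: int = 0, center: bool = True) -> dict:
    """Chance-level separation from pixel-permuted CIs.

    Each permutation shuffles the CI pixels uniformly at random (seeded),
    keeping the weight histogram; Cohen's d is recomputed per permutation.
    Returns the per-permutation d values with their mean |d| and the 95th
    percentile of |d|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ci_flat = np.asarray(ci, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    f = np.asarray(female_images, dtype=float).reshape(len(female_images), -1)
    m = np.asarray(male_images, dtype=float).reshape(len(male_images), -1)
    if center:
        f = f - f.mean(axis=1, keepdims=True)
        m = m - m.mean(axis=1, keepdims=True)
    ds = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(ci_flat.size)
        af = f @ ci_flat[perm]
        am = m @ ci_flat[perm]
        ds[i], _ = _cohens_d(af, am)
    abs_d = np.abs(ds)
    return {
        "d_values": ds,
        "mean_abs_d": float(abs_d.mean()),
        "q95_abs_d": float(np.percentile(abs_d, 95)),
        "n_perm": n_perm,
        "seed": seed,
    }
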