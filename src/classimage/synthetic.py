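"""Synthetic study inputs: templates, ground-truth axes, face populations.

Everything the pipeline needs can be generated here with a known ground
truth, standing in for the assets a real study would supply (a morphed
gender-neutral template face, the observers' internal gender template, and
populations of aligned face photographs):

* a *template* image — flat mid-gray, smooth radial, or a schematic face
  (the schematic style is for documentation figures; analysis is
  template-agnostic);
* a *ground-truth axis* — a known sparse combination of basis components,
  unit-normalized in pixel space, that drives a linear template observer.
  The low-frequency preset places >= 80% of the squared coefficient mass
  at the two coarsest scales, emulating the finding that class-diagnostic
  face-gender information concentrates at low spatial frequencies;
* a *population* of class-labelled images, class mean = template +/-
  effect_size x axis with i.i.d. Gaussian pixel noise — pre-aligned by
  construction, as the CI classifier requires.

All randomness derives from one integer seed per call via per-stage
substreams, so every recipe regenerates bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise import NoiseBasis, sample_parameters
from .observers import ObserverSpec, classify_from_parameters
from .stimulus import DEFAULT_BLEND

__all__ = [
    "GroundTruthAxis",
    "SyntheticPopulation",
    "make_axis",
    "make_template",
    "make_population",
    "export_population",
    "simulate_linear_observer_run",
]


@dataclass
class GroundTruthAxis:
    """A known sparse linear-template axis, exactly reconstructible."""

    pixels: np.ndarray            # unit L2 norm pixel image
    coefficients: np.ndarray      # (K,) basis coefficients of `pixels`
    component_indices: np.ndarray
    scale_mass: dict              # scale -> squared-coefficient mass fraction


@dataclass
class SyntheticPopulation:
    """Two class-labelled image stacks plus the recipe that made them."""

    images_female: np.ndarray     # (n, N, N)
    images_male: np.ndarray
    recipe: dict = field(default_factory=dict)


DEFAULT_SCALE_WEIGHTS = (0.6, 0.3, 0.1)


def _preset_counts(n: int, weights, pools) -> list[int]:
    """Largest-remainder apportionment of n components across scale pools."""
    w = np.zeros(len(pools))
    w[:min(len(weights), len(pools))] = weights[:len(pools)]
    if w.sum() == 0:
        w[:] = 1.0
    w = w / w.sum()
    counts = np.floor(w * n).astype(int)
    frac = w * n - counts
    for i in np.argsort(-frac):
        if counts.sum() >= n:
            break
        counts[i] += 1
    # respect pool sizes, pushing overflow toward coarser scales first
    for i in range(len(pools)):
        over = counts[i] - len(pools[i])
        if over > 0:
            counts[i] -= over
            for j in list(range(i)) + list(range(i + 1, len(pools))):
                room = len(pools[j]) - counts[j]
                take = min(room, over)
                counts[j] += take
                over -= take
                if over == 0:
                    break
    return counts.tolist()


def make_axis(basis: NoiseBasis, components=None, coefficients=None,
              preset: str | None = None, n_components: int = 10,
              scale_weights=DEFAULT_SCALE_WEIGHTS,
              seed: int = 0) -> GroundTruthAxis:
    """Build a ground-truth axis from explicit components or a preset draw.

    Either pass explicit ``components`` (parameter indices, with optional
    ``coefficients``, default all 1) or a ``preset``:

    * ``"low_freq"`` — fixes the per-scale composition deterministically
      from ``scale_weights`` (default 0.6/0.3/0.1 on the three coarsest
      scales, i.e. >= 80% of the squared unit-magnitude coefficient mass
      at the two lowest scales) and draws only the component identities
      and +/-1 signs at random.  Dominance of the coarsest scale reflects
      the coarse-scale concentration of class-diagnostic information this
      generator emulates, and keeps the axis well recoverable: cross-talk
      between hard-windowed gratings biases classification images toward
      coarse scales, so fine-scale axis content is recovered with lower
      fidelity;
    * ``"uniform"`` — components drawn uniformly over all K parameters.

    The synthesized pixel image is normalized to unit L2 norm and the
    stored coefficients are rescaled accordingly, so
    ``basis.synthesize(axis.coefficients)`` reproduces ``axis.pixels``.
    """
    rng = np.random.default_rng((seed, 101))
    k = basis.n_params
    if components is not None:
        idx = np.asarray(components, dtype=int)
        if idx.size == 0:
            raise ValueError("empty component spec")
        if idx.min() < 0 or idx.max() >= k:
            raise ValueError(f"component indices out of range [0, {k})")
        coef = (np.ones(idx.size) if coefficients is None
                else np.asarray(coefficients, dtype=float))
        if coef.shape != idx.shape:
            raise ValueError("coefficients must match component indices")
    elif preset is not None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if preset == "low_freq":
            pools = [basis.scale_indices(s) for s in basis.config.scales]
            counts = _preset_counts(n_components, scale_weights, pools)
            idx = np.concatenate([
                rng.choice(pool, size=c, replace=False)
                for pool, c in zip(pools, counts) if c > 0
            ])
        elif preset == "uniform":
            idx = rng.choice(k, size=min(n_components, k), replace=False)
        else:
            raise ValueError(f"unknown preset {preset!r}")
        coef = rng.choice([-1.0, 1.0], size=idx.size)
    else:
        raise ValueError("pass either explicit components or a preset")

    values = np.zeros(k)
    values[idx] = coef
    pixels = basis.synthesize(values)
    norm = float(np.linalg.norm(pixels))
    if norm == 0:
        raise ValueError("axis synthesized to the zero image")
    pixels /= norm
    values /= norm
    sq = values**2
    total = sq.sum()
    mass = {
        s: float(sq[basis.scale_indices(s)].sum() / total)
        for s in basis.config.scales
    }
    return GroundTruthAxis(
        pixels=pixels,
        coefficients=values,
        component_indices=np.sort(idx),
        scale_mass=mass,
    )


def make_template(size: int, style: str = "flat", seed: int = 0) -> np.ndarray:
    """Smooth mid-gray-dominant template image in [0, 1]."""
    if style == "flat":
        return np.full((size, size), 0.5)
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    radial = 0.4 + 0.25 * np.exp(-r2 / (2.0 * (0.35 * size) ** 2))
    if style == "radial":
        return np.clip(radial, 0.0, 1.0)
    if style == "schematic-face":
        img = radial.copy()

        def ellipse(cx_f, cy_f, rx_f, ry_f, depth):
            m = (((xx - cx_f * size) / (rx_f * size)) ** 2
                 + ((yy - cy_f * size) / (ry_f * size)) ** 2) <= 1.0
            img[m] -= depth

        ellipse(0.35, 0.40, 0.07, 0.035, 0.2)   # left eye
        ellipse(0.65, 0.40, 0.07, 0.035, 0.2)   # right eye
        ellipse(0.50, 0.58, 0.035, 0.07, 0.12)  # nose
        ellipse(0.50, 0.75, 0.10, 0.03, 0.18)   # mouth
        return np.clip(img, 0.0, 1.0)
    raise ValueError(f"unknown template style {style!r}")


def make_population(template: np.ndarray, axis: GroundTruthAxis | np.ndarray,
                    effect_size: float = 0.1, noise_sd: float = 0.05,
                    n_per_class: int = 500, seed: int = 0) -> SyntheticPopulation:
    """Generate two classes of pre-aligned images around the template.

    class-female image i = clip(template + effect_size * axis + eps_i),
    class-male  image i = clip(template - effect_size * axis + eps_i),
    eps i.i.d. N(0, noise_sd^2) per pixel.  Defaults (effect 0.1, noise
    0.05, 500 per class) give a strongly separable population for a
    matched CI while keeping clipping negligible.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    template = np.asarray(template, dtype=float)
    ax = axis.pixels if isinstance(axis, GroundTruthAxis) else np.asarray(axis, dtype=float)
    if ax.shape != template.shape:
        raise ValueError(
            f"axis shape {ax.shape} != template shape {template.shape}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng((seed, 202))
    shape = (n_per_class,) + template.shape
    fem = np.clip(template + effect_size * ax + rng.normal(0.0, noise_sd, shape),
                  0.0, 1.0)
    mal = np.clip(template - effect_size * ax + rng.normal(0.0, noise_sd, shape),
                  0.0, 1.0)
    recipe = {
        "effect_size": effect_size,
        "noise_sd": noise_sd,
        "n_per_class": n_per_class,
        "seed": seed,
    }
    return SyntheticPopulation(images_female=fem, images_male=mal, recipe=recipe)


def export_population(pop: SyntheticPopulation, directory) -> dict:
    """Write a population to the per-class PNG directory layout.

    Creates ``female/`` and ``male/`` subdirectories of 8-bit grayscale
    PNGs plus a ``recipe.json``; the layout is what
    ``classimage.classifier.load_class_images`` reads back.
    """
    import json
    from pathlib import Path

    from .stimulus import save_image

    directory = Path(directory)
    paths = {}
    for label, stack in (("female", pop.images_female), ("male", pop.images_male)):
        sub = directory / label
        sub.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(stack):
            save_image(img, sub / f"{label}_{i:05d}.png")
        paths[label] = sub
    with open(directory / "recipe.json", "w") as fh:
        json.dump(pop.recipe, fh, indent=2, default=float)
    return paths


def simulate_linear_observer_run(basis: NoiseBasis, axis, template: np.ndarray,
                                 n_trials: int, sigma: float = 0.0,
                                 theta: float = 0.0,
                                 criterion: str = "fixed_threshold",
                                 blend: float = DEFAULT_BLEND,
                                 seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Full synthetic experiment: sample amplitudes, classify all trials.

    Returns the (n, K) amplitude matrix and the trial table produced by a
    linear template observer with the given ground-truth ``axis`` — the
    backbone used to validate CI recovery.  Amplitude sampling and the
    observer's internal noise use distinct substreams of ``seed``.
    """
    ax = axis.pixels if isinstance(axis, GroundTruthAxis) else np.asarray(axis, dtype=float)
    params = sample_parameters(basis, n_trials, seed=(seed, 1))
    observer = ObserverSpec(
        kind="linear_template", axis=ax, template=np.asarray(template, dtype=float),
        sigma=sigma, theta=theta, criterion=criterion, seed=int(seed) * 2 + 1,
    )
    trials = classify_from_parameters(observer, basis, params, blend=blend)
    return params, trials
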