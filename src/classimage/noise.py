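"""Sinusoid noise basis for reverse-correlation experiments.

The noise dictionary is a fixed bank of localized sinusoid gratings
("sinusoid patches") organized in square grids at several spatial scales.
At scale *s* (labelled in cycles/image) the image is divided into a
``g × g`` grid of patches and every patch carries one sinusoid per
(orientation, phase) pair, windowed hard to its patch rectangle.  With the
default two cycles per patch, grid dimensions 1, 2, 4, 8, 16 produce
gratings of 2, 4, 8, 16, 32 cycles/image — the scale labels.

A noise image is a weighted sum of the K components with i.i.d. uniform
amplitudes in [-1, 1].  The default configuration has

    K = (1 + 4 + 16 + 64 + 256) x 6 orientations x 2 phases = 4092

parameters, split (12, 48, 192, 768, 3072) across the five scales.

Orientation is measured in degrees counterclockwise from the horizontal
image axis; pixel row 0 is the top of the image.  Each component has peak
amplitude 1 before weighting, so amplitudes are comparable across scales.
Synthesis is exactly linear in the amplitudes; no clipping or quantization
happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BasisConfig",
    "NoiseBasis",
    "build_basis",
    "sample_parameters",
    "synthesize_noise",
    "project_to_scale",
]


@dataclass(frozen=True)
class BasisConfig:
    """Structural description of the sinusoid noise dictionary.

    Parameters
    ----------
    image_size : int
        Pixels per side of the (square) noise image.  Must be divisible by
        every grid dimension.
    scales : tuple of int
        Scale labels in cycles/image, one per patch layer.
    grid_dims : tuple of int
        Patches per side at each scale; ``grid_dims[i]`` pairs with
        ``scales[i]``.
    orientations : tuple of float
        Grating orientations in degrees, CCW from horizontal.
    phases : tuple of float
        Grating phases in radians.
    cycles_per_patch : float
        Sinusoid cycles spanning one patch side.  The default of 2 makes the
        grid dimensions 1..16 correspond to 2..32 cycles/image.
    """

    image_size: int = 512
    scales: tuple = (2, 4, 8, 16, 32)
    grid_dims: tuple = (1, 2, 4, 8, 16)
    orientations: tuple = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    phases: tuple = (0.0, np.pi / 2)
    cycles_per_patch: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "scales", tuple(self.scales))
        object.__setattr__(self, "grid_dims", tuple(self.grid_dims))
        object.__setattr__(self, "orientations", tuple(float(o) for o in self.orientations))
        object.__setattr__(self, "phases", tuple(float(p) for p in self.phases))
        if len(self.scales) != len(self.grid_dims):
            raise ValueError(
                f"scales and grid_dims must align: {len(self.scales)} scales "
                f"vs {len(self.grid_dims)} grid dims"
            )
        if self.image_size <= 0:
            raise ValueError("image_size must be a positive integer")
        for s, g in zip(self.scales, self.grid_dims):
            if g <= 0 or self.image_size % g != 0:
                raise ValueError(
                    f"grid dimension {g} at scale {s} cycles/image does not "
                    f"divide image_size={self.image_size}"
                )

    @property
    def n_params(self) -> int:
        """Total parameter count K."""
        per = len(self.orientations) * len(self.phases)
        return sum(g * g * per for g in self.grid_dims)

    @property
    def params_per_scale(self) -> tuple:
        per = len(self.orientations) * len(self.phases)
        return tuple(g * g * per for g in self.grid_dims)

    @property
    def amplitude_bound(self) -> float:
        """Hard bound on |noise| at any pixel for amplitudes in [-1, 1].

        Each pixel is covered by exactly one patch per scale and receives
        every (orientation, phase) component of that patch, each bounded by
        1 in absolute value.
        """
        return float(len(self.scales) * len(self.orientations) * len(self.phases))

    def to_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "scales": list(self.scales),
            "grid_dims": list(self.grid_dims),
            "orientations": list(self.orientations),
            "phases": list(self.phases),
            "cycles_per_patch": self.cycles_per_patch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisConfig":
        return cls(**d)


def _patch_sinusoid(patch_side: int, cycles: float, orientation_deg: float,
                    phase: float) -> np.ndarray:
    """One sinusoid patch tile of shape (patch_side, patch_side)."""
    theta = np.deg2rad(orientation_deg)
    u = np.arange(patch_side) / patch_side        # column coordinate in [0,1)
    v = np.arange(patch_side) / patch_side        # row coordinate, row 0 at top
    U, V = np.meshgrid(u, v)
    arg = 2.0 * np.pi * cycles * (U * np.cos(theta) + V * np.sin(theta)) + phase
    return np.sin(arg)


@dataclass
class NoiseBasis:
    """Materialized sinusoid dictionary: index table plus cached patch tiles.

    Component images are generated on demand; synthesis and projection use
    the tiled-patch structure instead of an explicit (K, N, N) stack, which
    is value-identical but far cheaper.
    """

    config: BasisConfig
    index: pd.DataFrame = field(repr=False)
    _tiles: dict = field(default_factory=dict, repr=False)

    @property
    def n_params(self) -> int:
        return self.config.n_params

    @property
    def image_size(self) -> int:
        return self.config.image_size

    @property
    def amplitude_bound(self) -> float:
        return self.config.amplitude_bound

    # -- index structure ---------------------------------------------------

    def scale_indices(self, scale: int) -> np.ndarray:
        """Parameter indices belonging to one scale (cycles/image label)."""
        if scale not in self.config.scales:
            raise ValueError(
                f"unknown scale {scale}; basis scales are {self.config.scales}"
            )
        return self.index.index[self.index["scale"] == scale].to_numpy()

    def _tile(self, scale_i: int, ori_i: int, phase_i: int) -> np.ndarray:
        key = (scale_i, ori_i, phase_i)
        if key not in self._tiles:
            cfg = self.config
            g = cfg.grid_dims[scale_i]
            self._tiles[key] = _patch_sinusoid(
                cfg.image_size // g,
                cfg.cycles_per_patch,
                cfg.orientations[ori_i],
                cfg.phases[phase_i],
            )
        return self._tiles[key]

    def component_image(self, k: int) -> np.ndarray:
        """Pixel image of component k: its sinusoid patch, zero elsewhere."""
        row = self.index.iloc[k]
        cfg = self.config
        si = cfg.scales.index(row["scale"])
        g = cfg.grid_dims[si]
        P = cfg.image_size // g
        tile = self._tile(si, int(row["orientation_i"]), int(row["phase_i"]))
        img = np.zeros((cfg.image_size, cfg.image_size))
        r, c = int(row["patch_row"]), int(row["patch_col"])
        img[r * P:(r + 1) * P, c * P:(c + 1) * P] = tile
        return img

    # -- synthesis / analysis ---------------------------------------------

    def synthesize(self, values: np.ndarray) -> np.ndarray:
        """Noise image = sum_k values[k] * component_k (exactly linear)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector has shape {values.shape}, expected "
                f"({self.n_params},)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("parameter vector contains non-finite values")
        cfg = self.config
        N = cfg.image_size
        n_ori, n_ph = len(cfg.orientations), len(cfg.phases)
        img = np.zeros((N, N))
        offset = 0
        for si, g in enumerate(cfg.grid_dims):
            P = N // g
            block = values[offset:offset + g * g * n_ori * n_ph]
            amps = block.reshape(g, g, n_ori, n_ph)
            for oi in range(n_ori):
                for pi in range(n_ph):
                    a = amps[:, :, oi, pi]
                    if not np.any(a):
                        continue
                    up = np.repeat(np.repeat(a, P, axis=0), P, axis=1)
                    img += up * np.tile(self._tile(si, oi, pi), (g, g))
            offset += g * g * n_ori * n_ph
        return img

    def project_image(self, image: np.ndarray) -> np.ndarray:
        """Inner products <component_k, image> for all k (adjoint of synthesize)."""
        image = np.asarray(image, dtype=float)
        N = self.config.image_size
        if image.shape != (N, N):
            raise ValueError(f"image has shape {image.shape}, expected ({N}, {N})")
        cfg = self.config
        n_ori, n_ph = len(cfg.orientations), len(cfg.phases)
        out = np.empty(self.n_params)
        offset = 0
        for si, g in enumerate(cfg.grid_dims):
            P = N // g
            block = np.empty((g, g, n_ori, n_ph))
            for oi in range(n_ori):
                for pi in range(n_ph):
                    w = image * np.tile(self._tile(si, oi, pi), (g, g))
                    block[:, :, oi, pi] = w.reshape(g, P, g, P).sum(axis=(1, 3))
            out[offset:offset + block.size] = block.ravel()
            offset += block.size
        return out

    def synthesize_scale(self, values: np.ndarray, scale: int) -> np.ndarray:
        """Synthesis restricted to one scale's components."""
        idx = self.scale_indices(scale)
        restricted = np.zeros(self.n_params)
        restricted[idx] = np.asarray(values, dtype=float)[idx]
        return self.synthesize(restricted)


def build_basis(config: BasisConfig | None = None) -> NoiseBasis:
    """Construct the sinusoid noise basis for a configuration.

    The index table maps parameter index k to its (scale, patch_row,
    patch_col, orientation, phase) coordinates; the layout iterates scales
    outermost, then patch rows, columns, orientations and phases.
    """
    cfg = config if config is not None else BasisConfig()
    rows = []
    for si, (s, g) in enumerate(zip(cfg.scales, cfg.grid_dims)):
        for r in range(g):
            for c in range(g):
                for oi, ori in enumerate(cfg.orientations):
                    for pi, ph in enumerate(cfg.phases):
                        rows.append((s, g, r, c, ori, oi, ph, pi))
    index = pd.DataFrame(
        rows,
        columns=["scale", "grid_dim", "patch_row", "patch_col",
                 "orientation", "orientation_i", "phase", "phase_i"],
    )
    index.index.name = "param"
    assert len(index) == cfg.n_params
    return NoiseBasis(config=cfg, index=index)


def sample_parameters(basis: NoiseBasis, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. amplitude vectors, entries ~ Uniform(-1, 1).

    Returns an (n, K) array; row i is the parameter vector of trial i.
    Reproducible: the same seed yields the same array.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(n, basis.n_params))


def synthesize_noise(basis: NoiseBasis, params: np.ndarray) -> np.ndarray:
    """Pixel noise image for one parameter vector (module-level convenience)."""
    return basis.synthesize(params)


def project_to_scale(basis: NoiseBasis, params: np.ndarray, scale: int) -> np.ndarray:
    """Synthesis using only the components of one scale.

    Summing the projections over all scales reproduces the full synthesis,
    because the scales partition the dictionary.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (basis.n_params,):
        raise ValueError(
            f"parameter vector has shape {params.shape}, expected "
            f"({basis.n_params},)"
        )
    return basis.synthesize_scale(params, scale)
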