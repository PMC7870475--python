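"""Classification-image estimation, scale decomposition and comparison.

A classification image (CI) is the difference between the average noise of
trials labelled "female" and the average noise of trials labelled "male".
It is computed in parameter space — K mean amplitudes per class, subtracted
— and synthesized through the basis into pixel space; by linearity of the
synthesis the two representations carry the same information.  The sign
convention is female-minus-male throughout, so adding the (rescaled) CI to
the template yields the female prototype.

Because the basis partitions into disjoint per-scale component sets, the
CI decomposes exactly into per-scale images that sum to the full pixel CI.
Similarity between two CIs is the Pearson correlation of the flattened
pixel images (default) or of the K-vectors, optionally per scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .noise import NoiseBasis
from .observers import FEMALE, MALE, TrialRecord, trials_to_frame

__all__ = [
    "ClassificationImage",
    "compute_ci",
    "ci_by_scale",
    "ci_similarity",
    "normalize_ci_for_display",
]


@dataclass
class ClassificationImage:
    """Parameter-space and pixel-space CI plus class counts."""

    param_ci: np.ndarray      # (K,) mean(params | female) - mean(params | male)
    pixel_ci: np.ndarray      # (N, N) synthesis of param_ci
    n_female: int
    n_male: int
    basis: NoiseBasis

    @property
    def n_trials(self) -> int:
        return self.n_female + self.n_male


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    if len(trials) and isinstance(trials[0], TrialRecord):
        return trials_to_frame(trials)
    return pd.DataFrame(trials)


def compute_ci(trials, params: np.ndarray, basis: NoiseBasis) -> ClassificationImage:
    """Estimate the CI from a trial table and its parameter store.

    ``trials`` is a DataFrame (or TrialRecord list) with columns ``label``
    and ``pv_id``; ``params`` is the (n, K) amplitude matrix indexed by
    pv_id.  Requires at least one trial of each class.
    """
    frame = _as_frame(trials)
    params = np.asarray(params, dtype=float)
    fem = frame.loc[frame["label"] == FEMALE, "pv_id"].to_numpy(dtype=int)
    mal = frame.loc[frame["label"] == MALE, "pv_id"].to_numpy(dtype=int)
    for name, idx in ((FEMALE, fem), (MALE, mal)):
        if idx.size == 0:
            raise ValueError(f"no trials labelled {name!r}: CI undefined")
    param_ci = params[fem].mean(axis=0) - params[mal].mean(axis=0)
    return ClassificationImage(
        param_ci=param_ci,
        pixel_ci=basis.synthesize(param_ci),
        n_female=int(fem.size),
        n_male=int(mal.size),
        basis=basis,
    )


def ci_by_scale(ci: ClassificationImage, scale: int) -> np.ndarray:
    """Pixel CI restricted to one scale's components.

    The per-scale images over all scales sum to ``ci.pixel_ci`` exactly
    (up to float roundoff), because the scales partition the basis.
    """
    return ci.basis.synthesize_scale(ci.param_ci, scale)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")      # undefined, reported as such (never as 0)
    return float(np.corrcoef(a, b)[0, 1])


def ci_similarity(ci_a: ClassificationImage, ci_b: ClassificationImage,
                  space: str = "pixel", per_scale: bool = False) -> dict:
    """Pearson correlation between two CIs.

    Returns ``{"overall": r}`` and, with ``per_scale``, ``{"per_scale":
    {scale: r}}`` computed on the per-scale pixel images (or per-scale
    parameter sub-vectors for ``space="parameter"``).  Pearson r is
    invariant to the affine display normalization, so raw and normalized
    CIs give the same r.
    """
    if ci_a.basis.config != ci_b.basis.config:
        raise ValueError("CIs come from different bases; similarity undefined")
    if space not in ("pixel", "parameter"):
        raise ValueError(f"space must be 'pixel' or 'parameter', got {space!r}")
    if space == "pixel":
        overall = _pearson(ci_a.pixel_ci, ci_b.pixel_ci)
    else:
        overall = _pearson(ci_a.param_ci, ci_b.param_ci)
    report = {"overall": overall, "space": space}
    if per_scale:
        per = {}
        for s in ci_a.basis.config.scales:
            if space == "pixel":
                per[s] = _pearson(ci_by_scale(ci_a, s), ci_by_scale(ci_b, s))
            else:
                idx = ci_a.basis.scale_indices(s)
                per[s] = _pearson(ci_a.param_ci[idx], ci_b.param_ci[idx])
        report["per_scale"] = per
    return report


def normalize_ci_for_display(ci, as_uint8: bool = True) -> np.ndarray:
    """Affine map of the pixel CI to [0, 1] (then 8 bits) for display only.

    Analysis never uses the normalized copy: the map is monotone affine,
    so it preserves pixel ranking and leaves Pearson correlations
    unchanged, but it destroys the physical zero of the CI.
    """
    pixels = ci.pixel_ci if isinstance(ci, ClassificationImage) else np.asarray(ci, dtype=float)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        raise ValueError("constant CI cannot be normalized for display")
    unit = (pixels - lo) / (hi - lo)
    if as_uint8:
        return np.round(unit * 255.0).astype(np.uint8)
    return unit
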