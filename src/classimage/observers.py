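"""Observer models: the contract that turns stimuli into trial records.

The central synthetic observer is the *linear template observer*: it
computes a decision variable

    v = sum_pixels (stimulus - template) * axis + eps,   eps ~ N(0, sigma^2)

and labels the trial "female" iff v > theta (ties go to "male", fixed for
determinism).  Subtracting the template makes the observer respond to the
noise content only, which is what makes classification-image recovery of
the axis exact for sigma = 0.  A *random* observer labels trials by a fair
coin; *external* classifiers (e.g. a DCNN gender unit pair) are wrapped by
an adapter that maps their two class scores onto the same contract.

Two decision criteria are supported.  ``fixed_threshold`` compares v to a
constant theta.  ``mean_activation`` compares v to the mean decision
variable over the whole stimulus batch — the bias-correction criterion
used for classifiers with a constant response offset; it requires a batch
and equals ``fixed_threshold`` with theta set to the empirical batch mean.

Internal noise is drawn from a per-trial substream seeded by
``(observer seed, trial index)``, so single-trial and batch classification
agree exactly and reruns are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .noise import NoiseBasis
from .stimulus import DEFAULT_BLEND

__all__ = [
    "ObserverSpec",
    "TrialRecord",
    "classify",
    "classify_batch",
    "classify_from_parameters",
    "external_adapter",
    "trials_to_frame",
]

FEMALE = "female"
MALE = "male"


@dataclass
class ObserverSpec:
    """Configuration of a synthetic or adapted observer."""

    kind: str = "linear_template"          # linear_template | random | external
    axis: np.ndarray | None = None         # ground-truth pixel template
    template: np.ndarray | None = None     # stimulus template (subtracted)
    sigma: float = 0.0                     # internal noise SD
    theta: float = 0.0                     # decision threshold
    criterion: str = "fixed_threshold"     # fixed_threshold | mean_activation
    confidence_threshold: float | None = None
    seed: int = 0
    scorer: Callable | None = None         # external classifiers only
    label_map: dict = field(default_factory=lambda: {0: FEMALE, 1: MALE})

    def __post_init__(self):
        if self.kind not in ("linear_template", "random", "external"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if self.criterion not in ("fixed_threshold", "mean_activation"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "linear_template" and self.axis is None:
            raise ValueError("linear_template observer needs an axis image")
        if self.kind == "external" and self.scorer is None:
            raise ValueError("external observer needs a scorer callable")
        if set(self.label_map.values()) != {FEMALE, MALE}:
            raise ValueError("label_map must map the two score indices to female/male")


@dataclass
class TrialRecord:
    """One stimulus presentation and the observer's response."""

    trial_id: int
    pv_id: int
    label: str                       # binary response: female | male
    response4: str | None = None     # probably/possibly x female/male
    decision_var: float | None = None
    extras: dict | None = None


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate a trial stream (the CSV layout used throughout)."""
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in records],
            "pv_id": [r.pv_id for r in records],
            "label": [r.label for r in records],
            "response4": [r.response4 for r in records],
            "decision_var": [r.decision_var for r in records],
        }
    )


def _internal_noise(observer: ObserverSpec, trial_index: int) -> float:
    if observer.sigma == 0:
        return 0.0
    rng = np.random.default_rng((observer.seed, int(trial_index)))
    return float(rng.normal(0.0, observer.sigma))


def _decision_variable(observer: ObserverSpec, stimulus: np.ndarray,
                       trial_index: int) -> tuple[float, dict | None]:
    if observer.kind == "linear_template":
        if observer.template is None:
            raise ValueError("linear_template observer needs the stimulus template")
        v = float(np.sum((stimulus - observer.template) * observer.axis))
        return v + _internal_noise(observer, trial_index), None
    if observer.kind == "external":
        out = observer.scorer(stimulus)
        try:
            s0, s1 = float(out[0]), float(out[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise ValueError(
                f"external classifier returned malformed output {out!r}; "
                "expected two class scores"
            ) from exc
        scores = {observer.label_map[0]: s0, observer.label_map[1]: s1}
        v = scores[FEMALE] - scores[MALE] + _internal_noise(observer, trial_index)
        return v, {"score_0": s0, "score_1": s1}
    raise ValueError(f"no decision variable for observer kind {observer.kind!r}")


def _label(v: float, theta: float) -> str:
    # tie at v == theta is assigned "male" by convention
    return FEMALE if v > theta else MALE


def _response4(v: float, theta: float, conf: float, label: str) -> str:
    grade = "probably" if abs(v - theta) >= conf else "possibly"
    return f"{grade}_{label}"


def classify(observer: ObserverSpec, stimulus: np.ndarray, trial_index: int = 0,
             pv_id: int | None = None) -> TrialRecord:
    """Classify a single stimulus.

    Deterministic given the observer seed and the trial index.  The
    mean_activation criterion is batch-defined and is rejected here.
    """
    if observer.criterion == "mean_activation":
        raise ValueError(
            "mean_activation is defined over a stimulus batch; use classify_batch"
        )
    pv = pv_id if pv_id is not None else trial_index
    if observer.kind == "random":
        rng = np.random.default_rng((observer.seed, int(trial_index)))
        label = FEMALE if rng.random() < 0.5 else MALE
        return TrialRecord(trial_index, pv, label)
    v, extras = _decision_variable(observer, stimulus, trial_index)
    label = _label(v, observer.theta)
    resp4 = None
    if observer.confidence_threshold is not None:
        resp4 = _response4(v, observer.theta, observer.confidence_threshold, label)
    return TrialRecord(trial_index, pv, label, resp4, v, extras)


def classify_batch(observer: ObserverSpec, stimuli: Sequence[np.ndarray],
                   pv_ids: Sequence[int] | None = None) -> list[TrialRecord]:
    """Classify a batch of stimuli under the observer's criterion.

    For ``mean_activation`` the threshold is the batch mean of the decision
    variable (two passes over the batch); otherwise this is elementwise
    :func:`classify`.  Confidence grades, when no explicit threshold is
    configured, split at the within-batch median of |v - theta|.
    """
    n = len(stimuli)
    if n == 0:
        raise ValueError("classify_batch needs a non-empty stimulus list")
    pvs = list(pv_ids) if pv_ids is not None else list(range(n))
    if observer.kind == "random":
        return [classify_spec_random(observer, i, pvs[i]) for i in range(n)]

    vs = np.empty(n)
    extras = [None] * n
    for i in range(n):
        vs[i], extras[i] = _decision_variable(observer, stimuli[i], i)
    theta = float(np.mean(vs)) if observer.criterion == "mean_activation" else observer.theta
    conf = observer.confidence_threshold
    if conf is None:
        conf = float(np.median(np.abs(vs - theta)))
    records = []
    for i in range(n):
        label = _label(vs[i], theta)
        records.append(
            TrialRecord(i, pvs[i], label, _response4(vs[i], theta, conf, label),
                        float(vs[i]), extras[i])
        )
    return records


def classify_spec_random(observer: ObserverSpec, trial_index: int,
                         pv_id: int) -> TrialRecord:
    rng = np.random.default_rng((observer.seed, int(trial_index)))
    label = FEMALE if rng.random() < 0.5 else MALE
    return TrialRecord(trial_index, pv_id, label)


def classify_from_parameters(observer: ObserverSpec, basis: NoiseBasis,
                             params: np.ndarray,
                             blend: float = DEFAULT_BLEND) -> pd.DataFrame:
    """Vectorized batch classification straight from amplitude vectors.

    Produces labels identical to building each stimulus with
    :func:`classimage.stimulus.superimpose` and calling
    :func:`classify_batch`, but without materializing images: because the
    stimulus is an exactly linear, unclipped function of the amplitudes,

        v_i = blend * (params_i . w / (2 B) + <0.5 - template, axis>) + eps_i

    where ``w = basis.project_image(axis)`` and B is the basis amplitude
    bound.  This is the bulk path for experiment-scale runs (e.g. 20,000
    trials).  Supports linear_template and random observers.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    n = params.shape[0]
    if n == 0:
        raise ValueError("empty parameter batch")
    if observer.kind == "random":
        labels = [
            FEMALE if np.random.default_rng((observer.seed, i)).random() < 0.5 else MALE
            for i in range(n)
        ]
        return pd.DataFrame(
            {"trial_id": np.arange(n), "pv_id": np.arange(n),
             "label": labels, "response4": None, "decision_var": np.nan}
        )
    if observer.kind != "linear_template":
        raise ValueError(
            "classify_from_parameters supports linear_template and random "
            "observers; external classifiers need pixel stimuli"
        )
    if observer.template is None:
        raise ValueError("linear_template observer needs the stimulus template")
    w = basis.project_image(observer.axis)
    offset = float(np.sum((0.5 - observer.template) * observer.axis))
    vs = blend * (params @ w / (2.0 * basis.amplitude_bound) + offset)
    if observer.sigma > 0:
        vs = vs + np.array([_internal_noise(observer, i) for i in range(n)])
    theta = float(np.mean(vs)) if observer.criterion == "mean_activation" else observer.theta
    conf = observer.confidence_threshold
    if conf is None:
        conf = float(np.median(np.abs(vs - theta)))
    labels = np.where(vs > theta, FEMALE, MALE)
    grades = np.where(np.abs(vs - theta) >= conf, "probably", "possibly")
    resp4 = np.char.add(np.char.add(grades.astype(str), "_"), labels.astype(str))
    return pd.DataFrame(
        {"trial_id": np.arange(n), "pv_id": np.arange(n),
         "label": labels, "response4": resp4, "decision_var": vs}
    )


def external_adapter(scorer: Callable, label_map: dict | None = None,
                     criterion: str = "fixed_threshold", sigma: float = 0.0,
                     seed: int = 0) -> ObserverSpec:
    """Wrap an external two-class classifier under the observer contract.

    ``scorer`` takes a stimulus image (2-D float array in [0, 1]) and
    returns two class scores; ``label_map`` maps score index to
    "female"/"male" (default: index 0 is female).  The decision variable is
    the female score minus the male score, so with ``fixed_threshold`` and
    theta = 0 the trial is labelled male exactly when the male unit's
    activation is at least the female unit's.  Raw scores are recorded in
    the trial extras.
    """
    return ObserverSpec(
        kind="external",
        scorer=scorer,
        label_map=label_map if label_map is not None else {0: FEMALE, 1: MALE},
        criterion=criterion,
        sigma=sigma,
        seed=seed,
    )
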