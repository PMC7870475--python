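"""Experiment orchestration: configured, seeded, reproducible runs.

A *run* is a directory produced from a :class:`RunConfig`: one shared set
of noise parameter vectors (the stimuli), one trial table per observer
collected on those same stimuli (the paired-observer design: every
observer sees identical stimuli), and an analysis bundle (classification
images, per-scale decompositions, contribution tables, prototypes,
similarity reports).  Every table carries the config hash and seed, and a
rerun with the same config is byte-identical.

Observer axes are specified by recipe (explicit components or a preset
draw), never by raw pixels, so a run is fully described by its YAML
config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import revcorr, contributions
from .noise import BasisConfig, build_basis, sample_parameters
from .observers import ObserverSpec, classify_from_parameters
from .stimulus import DEFAULT_BLEND, load_template, make_prototypes, save_image
from .synthetic import make_axis, make_template

__all__ = ["RunConfig", "run_experiment", "run_analysis", "compare_runs",
           "prepare_run", "classify_run"]


@dataclass
class RunConfig:
    """Everything needed to reproduce an experiment and its analysis."""

    basis: BasisConfig = field(default_factory=BasisConfig)
    template: str = "flat"            # style name or path to a PNG
    blend: float = DEFAULT_BLEND
    observers: dict = field(default_factory=dict)   # name -> observer recipe
    n_trials: int = 1000
    seed: int = 0
    alpha: float = 0.05
    top_fraction: float = 0.8
    similarity_space: str = "pixel"
    prototype_peak: float = 0.2

    def to_dict(self) -> dict:
        d = {
            "basis": self.basis.to_dict(),
            "template": self.template,
            "blend": self.blend,
            "observers": self.observers,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "alpha": self.alpha,
            "top_fraction": self.top_fraction,
            "similarity_space": self.similarity_space,
            "prototype_peak": self.prototype_peak,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("config_hash", None)
        d["basis"] = BasisConfig.from_dict(d.get("basis", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        d = self.to_dict()
        d["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# named presets mirroring the two study arms: one long machine-observer
# run vs. many short sessions
PRESET_CONFIGS = {
    "dcnn-scale": {"n_trials": 20000},
    "human-scale": {"n_trials": 1000},
}


def _resolve_template(config: RunConfig) -> np.ndarray:
    size = config.basis.image_size
    if config.template in ("flat", "radial", "schematic-face"):
        return make_template(size, style=config.template, seed=config.seed)
    tmpl = load_template(config.template)
    if tmpl.shape != (size, size):
        raise ValueError(
            f"template {config.template} has shape {tmpl.shape}, basis "
            f"expects ({size}, {size})"
        )
    return tmpl


def _build_observer(name: str, recipe: dict, basis, template: np.ndarray,
                    run_seed: int) -> ObserverSpec:
    recipe = dict(recipe)
    kind = recipe.pop("kind", "linear_template")
    seed = recipe.pop("seed", None)
    if seed is None:
        digest = hashlib.sha256(f"{run_seed}:{name}".encode()).digest()
        seed = int.from_bytes(digest[:4], "big") % (2**31 - 1)
    if kind == "random":
        return ObserverSpec(kind="random", seed=seed, **recipe)
    if kind == "linear_template":
        axis_spec = dict(recipe.pop("axis", {"preset": "low_freq"}))
        axis_spec.setdefault("seed", seed)
        axis = make_axis(basis, **axis_spec)
        return ObserverSpec(kind="linear_template", axis=axis.pixels,
                            template=template, seed=seed, **recipe)
    raise ValueError(
        f"observer {name!r}: kind {kind!r} is not runnable from a config "
        "(external observers are attached programmatically)"
    )


def prepare_run(config: RunConfig, outdir) -> Path:
    """Generate the shared stimuli (parameters, manifest, template)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    basis = build_basis(config.basis)
    template = _resolve_template(config)
    params = sample_parameters(basis, config.n_trials, seed=(config.seed, 1))
    np.save(outdir / "params.npy", params)
    save_image(template, outdir / "template.png")
    manifest = pd.DataFrame({
        "pv_id": np.arange(config.n_trials),
        "seed": config.seed,
        "blend": config.blend,
        "config_hash": config.config_hash,
    })
    manifest.to_csv(outdir / "stimuli.csv", index=False)
    config.save(outdir / "config.yaml")
    return outdir


def classify_run(run_dir, observer_name: str | None = None,
                 observer: ObserverSpec | None = None) -> list[Path]:
    """Collect trials for one observer (or all configured ones).

    Pass ``observer`` to attach a programmatic (e.g. external-adapter)
    observer under ``observer_name``; otherwise observers are built from
    the run config's recipes.  All observers classify the same stimuli.
    """
    run_dir = Path(run_dir)
    config = RunConfig.from_yaml(run_dir / "config.yaml")
    basis = build_basis(config.basis)
    template = _resolve_template(config)
    params = np.load(run_dir / "params.npy")
    names = ([observer_name] if observer_name is not None
             else list(config.observers))
    if not names:
        raise ValueError("no observers configured for this run")
    written = []
    for name in names:
        if observer is not None:
            obs = observer
        else:
            if name not in config.observers:
                raise KeyError(f"observer {name!r} not in run config")
            obs = _build_observer(name, config.observers[name], basis,
                                  template, config.seed)
        trials = classify_from_parameters(obs, basis, params, blend=config.blend)
        trials["config_hash"] = config.config_hash
        trials["seed"] = config.seed
        path = run_dir / f"trials_{name}.csv"
        trials.to_csv(path, index=False)
        written.append(path)
    return written


def run_experiment(config: RunConfig, outdir) -> Path:
    """Full data-collection stage: stimuli plus every observer's trials."""
    prepare_run(config, outdir)
    classify_run(outdir)
    return Path(outdir)


def _analyze_observer(name: str, run_dir: Path, out: Path, config: RunConfig,
                      basis, template: np.ndarray, params: np.ndarray) -> dict:
    trials = pd.read_csv(run_dir / f"trials_{name}.csv")
    ci = revcorr.compute_ci(trials, params, basis)
    obs_dir = out / name
    obs_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"param": np.arange(basis.n_params), "ci": ci.param_ci}).to_csv(
        obs_dir / "ci_params.csv", index=False)
    np.save(obs_dir / "ci_pixels.npy", ci.pixel_ci)
    if ci.pixel_ci.max() > ci.pixel_ci.min():
        save_image(revcorr.normalize_ci_for_display(ci, as_uint8=False),
                   obs_dir / "ci.png")
        for s in config.basis.scales:
            img = revcorr.ci_by_scale(ci, s)
            if img.max() > img.min():
                save_image(revcorr.normalize_ci_for_display(img, as_uint8=False),
                           obs_dir / f"ci_scale_{s}.png")
        female, male = make_prototypes(template, ci.pixel_ci,
                                       peak=config.prototype_peak)
        save_image(female, obs_dir / "prototype_female.png")
        save_image(male, obs_dir / "prototype_male.png")
    table = contributions.parameter_tests(trials, params, basis,
                                          alpha=config.alpha)
    table.to_csv(obs_dir / "contributions.csv", index=True)
    contributions.manhattan_plot(table, obs_dir / "manhattan.png")
    scale_summary = contributions.per_scale_summary(table)
    scale_summary.to_csv(obs_dir / "per_scale_summary.csv", index=False)
    return {
        "ci": ci,
        "table": table,
        "summary": {
            "n_female": ci.n_female,
            "n_male": ci.n_male,
            "n_significant": int(table["significant"].sum()),
            "per_scale": scale_summary.to_dict(orient="records"),
        },
    }


def run_analysis(run_dir) -> dict:
    """Analyze every observer's trials in a run; returns the report bundle.

    Writes per-observer CI artifacts, contribution tables and prototypes
    under ``analysis/``, plus pairwise similarity when the run holds
    several observers, and a markdown report.  Purely a function of the
    trial CSVs and config: rerunning reproduces identical numbers.
    """
    run_dir = Path(run_dir)
    config = RunConfig.from_yaml(run_dir / "config.yaml")
    basis = build_basis(config.basis)
    template = _resolve_template(config)
    params = np.load(run_dir / "params.npy")
    out = run_dir / "analysis"
    out.mkdir(exist_ok=True)
    names = sorted(p.stem.removeprefix("trials_")
                   for p in run_dir.glob("trials_*.csv"))
    if not names:
        raise FileNotFoundError(f"no trial tables found in {run_dir}")
    results = {n: _analyze_observer(n, run_dir, out, config, basis, template,
                                    params) for n in names}

    summary = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "observers": {n: results[n]["summary"] for n in names},
    }
    if len(names) >= 2:
        pairs = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                sim = revcorr.ci_similarity(results[a]["ci"], results[b]["ci"],
                                            space=config.similarity_space,
                                            per_scale=True)
                try:
                    top = contributions.top_contributors(
                        results[a]["table"], config.top_fraction)
                    rho = contributions.contribution_correlation(
                        results[a]["table"], results[b]["table"],
                        subset=top, per_scale=True)
                except ValueError:
                    rho = None
                pairs[f"{a}__vs__{b}"] = {"ci_similarity": sim,
                                          "contribution_spearman": rho}
        summary["comparisons"] = pairs
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    _write_report(out / "report.md", summary)
    return summary


def _write_report(path: Path, summary: dict) -> None:
    lines = ["# Run analysis report", "",
             f"- config hash: `{summary['config_hash']}`",
             f"- seed: {summary['seed']}", ""]
    for name, s in summary["observers"].items():
        lines += [f"## Observer `{name}`", "",
                  f"- trials: {s['n_female']} female / {s['n_male']} male",
                  f"- significant parameters (Bonferroni): {s['n_significant']}",
                  "", "| scale (c/img) | params | significant | % |",
                  "|---|---|---|---|"]
        for row in s["per_scale"]:
            lines.append(f"| {row['scale']} | {row['n_params']} | "
                         f"{row['n_significant']} | {row['pct_significant']:.1f} |")
        lines.append("")
    for pair, c in summary.get("comparisons", {}).items():
        lines += [f"## Comparison `{pair}`", "",
                  f"- CI similarity (overall): r = {c['ci_similarity']['overall']:.3f}"]
        per = c["ci_similarity"].get("per_scale", {})
        if per:
            lines += ["", "| scale (c/img) | r |", "|---|---|"]
            lines += [f"| {s} | {r:.3f} |" for s, r in per.items()]
        if c.get("contribution_spearman"):
            lines.append(
                f"- contribution Spearman (top set, overall): "
                f"rho = {c['contribution_spearman']['overall']:.3f}")
        lines.append("")
    path.write_text("\n".join(lines))


def compare_runs(run_a, run_b) -> dict:
    """Compare the lead observers of two analyzed runs.

    Both runs must share an identical basis configuration (hard error
    otherwise: the parameter spaces would not align).  Returns CI
    similarity (overall and per scale) and the contribution Spearman
    report for every observer pairing across the runs.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    cfg_a = RunConfig.from_yaml(run_a / "config.yaml")
    cfg_b = RunConfig.from_yaml(run_b / "config.yaml")
    if cfg_a.basis != cfg_b.basis:
        raise ValueError("runs use different basis configs; comparison undefined")
    basis = build_basis(cfg_a.basis)

    def load(run_dir, cfg):
        out = {}
        for p in sorted((run_dir / "analysis").glob("*/ci_params.csv")):
            name = p.parent.name
            param_ci = pd.read_csv(p)["ci"].to_numpy()
            trials = pd.read_csv(run_dir / f"trials_{name}.csv")
            nf = int((trials["label"] == "female").sum())
            ci = revcorr.ClassificationImage(
                param_ci=param_ci, pixel_ci=basis.synthesize(param_ci),
                n_female=nf, n_male=len(trials) - nf, basis=basis)
            table = pd.read_csv(p.parent / "contributions.csv", index_col=0)
            out[name] = (ci, table)
        if not out:
            raise FileNotFoundError(f"{run_dir} has no analysis outputs")
        return out

    obs_a, obs_b = load(run_a, cfg_a), load(run_b, cfg_b)
    report = {}
    for na, (ci_a, tab_a) in obs_a.items():
        for nb, (ci_b, tab_b) in obs_b.items():
            sim = revcorr.ci_similarity(ci_a, ci_b, space=cfg_a.similarity_space,
                                        per_scale=True)
            try:
                top = contributions.top_contributors(tab_a, cfg_a.top_fraction)
                rho = contributions.contribution_correlation(
                    tab_a, tab_b, subset=top, per_scale=True)
            except ValueError:
                rho = None
            report[f"{na}__vs__{nb}"] = {"ci_similarity": sim,
                                         "contribution_spearman": rho}
    return report
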