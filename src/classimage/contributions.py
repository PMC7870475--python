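"""Per-parameter contribution statistics for classification.

For every amplitude parameter k the female-trial and male-trial amplitude
samples are compared with a classic pooled-variance two-sample t-test
(two-sided), and the standardized mean difference

    d_k = (mean_female - mean_male) / pooled SD

is reported as |d_k|, the contribution index of parameter k.  Pooled
(Student) rather than Welch variance keeps t and d consistent, and class
sizes in these experiments are near-equal.  Significance is controlled
familywise by Bonferroni over all K parameters jointly: p <= alpha / K.

The whole table is computed in one vectorized pass over the (n, K)
amplitude matrix; rows with zero pooled variance are flagged degenerate
and never significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .noise import NoiseBasis
from .observers import FEMALE, MALE

__all__ = [
    "parameter_tests",
    "per_scale_summary",
    "top_contributors",
    "contribution_correlation",
    "manhattan_plot",
]


def parameter_tests(trials, params: np.ndarray, basis: NoiseBasis,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Pooled-variance t-test and |Cohen's d| for every parameter.

    Returns a K-row table with columns t, p, abs_d, significant,
    degenerate plus the basis metadata (scale, patch, orientation, phase).
    ``alpha`` is the familywise level; the per-test Bonferroni threshold
    is alpha / K.
    """
    from .revcorr import _as_frame

    frame = _as_frame(trials)
    params = np.asarray(params, dtype=float)
    f_idx = frame.loc[frame["label"] == FEMALE, "pv_id"].to_numpy(dtype=int)
    m_idx = frame.loc[frame["label"] == MALE, "pv_id"].to_numpy(dtype=int)
    nf, nm = f_idx.size, m_idx.size
    if nf < 2 or nm < 2:
        raise ValueError(
            f"need >=2 trials per class, got female={nf}, male={nm}"
        )
    F, M = params[f_idx], params[m_idx]
    diff = F.mean(axis=0) - M.mean(axis=0)
    sp2 = ((nf - 1) * F.var(axis=0, ddof=1) + (nm - 1) * M.var(axis=0, ddof=1)) / (nf + nm - 2)
    sp = np.sqrt(sp2)
    degenerate = sp == 0
    safe_sp = np.where(degenerate, 1.0, sp)
    t = diff / (safe_sp * np.sqrt(1.0 / nf + 1.0 / nm))
    p = 2.0 * stats.t.sf(np.abs(t), df=nf + nm - 2)
    abs_d = np.abs(diff) / safe_sp
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    abs_d[degenerate] = 0.0

    k = basis.n_params
    table = basis.index.copy()
    table["t"] = t
    table["p"] = p
    table["abs_d"] = abs_d
    table["degenerate"] = degenerate
    table["significant"] = (p <= alpha / k) & ~degenerate
    table.attrs["alpha"] = alpha
    table.attrs["bonferroni_threshold"] = alpha / k
    table.attrs["n_female"] = nf
    table.attrs["n_male"] = nm
    return table


def per_scale_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Significant-parameter counts and percentages per spatial scale."""
    grouped = table.groupby("scale", sort=True)["significant"]
    out = pd.DataFrame(
        {
            "n_params": grouped.size(),
            "n_significant": grouped.sum().astype(int),
        }
    )
    out["pct_significant"] = 100.0 * out["n_significant"] / out["n_params"]
    return out.reset_index()


def top_contributors(table: pd.DataFrame, fraction: float) -> np.ndarray:
    """Smallest |d|-descending prefix reaching a share of total contribution.

    Parameters are sorted by |d| descending (ties broken by ascending
    parameter index); the returned index array is the shortest prefix
    whose |d| sum reaches ``fraction`` of the total |d| sum.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    d = table["abs_d"].to_numpy()
    total = d.sum()
    if total == 0:
        raise ValueError("all contributions are zero; top set undefined")
    order = np.lexsort((table.index.to_numpy(), -d))
    csum = np.cumsum(d[order])
    n_keep = int(np.searchsorted(csum, fraction * total - 1e-12) + 1)
    return table.index.to_numpy()[order[:n_keep]]


def contribution_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                             subset=None, per_scale: bool = False) -> dict:
    """Spearman rank correlation of |d| between two contribution tables.

    Restricted to ``subset`` (parameter indices) when given, e.g. the
    highly-contributing set from :func:`top_contributors`.  Scales with
    fewer than 3 subset parameters are reported as NaN (undefined).
    """
    if len(table_a) != len(table_b):
        raise ValueError("contribution tables have different parameter counts")
    if subset is None:
        subset = table_a.index.to_numpy()
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty parameter subset")
    da = table_a.loc[subset, "abs_d"].to_numpy()
    db = table_b.loc[subset, "abs_d"].to_numpy()
    rho = float(stats.spearmanr(da, db).statistic) if subset.size >= 3 else float("nan")
    report = {"overall": rho, "n": int(subset.size)}
    if per_scale:
        per, per_n = {}, {}
        scales = table_a.loc[subset, "scale"]
        for s in sorted(int(v) for v in table_a["scale"].unique()):
            sel = subset[(scales == s).to_numpy()]
            per_n[s] = int(sel.size)
            if sel.size < 3:
                per[s] = float("nan")
            else:
                per[s] = float(stats.spearmanr(
                    table_a.loc[sel, "abs_d"], table_b.loc[sel, "abs_d"]
                ).statistic)
        report["per_scale"] = per
        report["per_scale_n"] = per_n
    return report


def manhattan_plot(table: pd.DataFrame, path, alpha: float | None = None) -> None:
    """Parameter index vs |d|, colored by scale, with the Bonferroni line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    for s in sorted(table["scale"].unique()):
        sub = table[table["scale"] == s]
        ax.scatter(sub.index, sub["abs_d"], s=4, label=f"{s} c/img")
    if alpha is None:
        alpha = table.attrs.get("alpha", 0.05)
    # |d| threshold implied by the Bonferroni p cut at these class sizes
    nf = table.attrs.get("n_female")
    nm = table.attrs.get("n_male")
    if nf and nm:
        from scipy.stats import t as tdist
        tcrit = tdist.isf(alpha / len(table) / 2.0, df=nf + nm - 2)
        dcrit = tcrit * np.sqrt(1.0 / nf + 1.0 / nm)
        ax.axhline(dcrit, color="k", ls="--", lw=0.8, label="Bonferroni")
    ax.set_xlabel("parameter index")
    ax.set_ylabel("|Cohen's d|")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
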