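"""Optional figures: score densities, CDFs, and nomogram scales."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

_COLORS = {"F": "#c0392b", "M": "#2980b9"}


def plot_score_density(scores_f, scores_m, title: str, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    grid = np.linspace(
        min(scores_f.min(), scores_m.min()), max(scores_f.max(), scores_m.max()), 400
    )
    for code, vals in (("F", scores_f), ("M", scores_m)):
        kde = stats.gaussian_kde(vals, bw_method="silverman")
        ax.fill_between(grid, kde(grid), alpha=0.4, color=_COLORS[code], label=code)
    ax.set_title(title)
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_score_cdf(scores_f, scores_m, title: str, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for code, vals in (("F", scores_f), ("M", scores_m)):
        x = np.sort(vals)
        ax.step(x, np.arange(1, x.size + 1) / x.size, color=_COLORS[code], label=code)
    ax.set_title(title)
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_nomogram(table, title: str, path: Path) -> Path:
    tab = table.sort_values("max_points", ascending=True)
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1.5))
    y = np.arange(len(tab))
    ax.barh(y, tab["max_points"], color="#f39c12", alpha=0.7)
    if "median_points_F" in tab:
        ax.scatter(tab["median_points_F"], y, color=_COLORS["F"], zorder=3, label="F median")
        ax.scatter(tab["median_points_M"], y, color=_COLORS["M"], zorder=3, label="M median")
        ax.legend(fontsize=7)
    ax.set_yticks(y, tab.index)
    ax.set_xlabel("points (0-100 scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_plots(bundle, outdir: Path) -> list[Path]:
    """Write the standard figure set for a report bundle."""
    written: list[Path] = []
    sex = bundle.scores["sex"].to_numpy()
    for kind in bundle.univariate:
        col = f"pclass_{kind}"
        if col in bundle.scores:
            s = bundle.scores[col].to_numpy()
            written.append(
                plot_score_density(s[sex == "F"], s[sex == "M"],
                                   f"Pclass scores ({kind})", outdir / f"density_pclass_{kind}.png")
            )
            written.append(
                plot_score_cdf(s[sex == "F"], s[sex == "M"],
                               f"Pclass CDF ({kind})", outdir / f"cdf_pclass_{kind}.png")
            )
    for name, nom in bundle.nomograms.items():
        written.append(
            plot_nomogram(nom, f"Nomogram ({name})", outdir / f"nomogram_{name.replace('+', '_')}.png")
        )
    return written
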