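"""Optional SVG plot outputs: Kaplan-Meier curves and forest plots.

Deterministic output: the SVG hash salt is pinned and date metadata is
suppressed so identical inputs yield identical files.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "dspsig"

import matplotlib.pyplot as plt  # noqa: E402

from .survival import KMCurve, SurvivalFit  # noqa: E402

GROUP_COLORS = {"low": "#1f77b4", "mid": "#7f7f7f", "high": "#d62728"}


def plot_km_curves(curves: dict[str, KMCurve], path, title: str = "") -> None:
    """Step-style Kaplan-Meier curves, one line per tertile group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in sorted(curves.items()):
        ax.step(
            curve.times,
            curve.survival,
            where="post",
            label=f"{name} (n at risk {int(curve.at_risk[0])})",
            color=GROUP_COLORS.get(name),
        )
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def plot_forest(fits: dict[str, SurvivalFit], path, title: str = "") -> None:
    """Log-scale forest plot of hazard ratios with 95% CIs."""
    fig, ax = plt.subplots(figsize=(5, 0.6 * max(len(fits), 2) + 1.2))
    names = list(fits)
    for i, name in enumerate(names):
        fit = fits[name]
        ax.plot([fit.ci_low, fit.ci_high], [i, i], color="black", lw=1)
        ax.plot(fit.hr, i, "s", color="#d62728")
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("hazard ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
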