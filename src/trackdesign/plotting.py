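"""Plot helpers for design reports: relative error vs m with threshold guides."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .design import DesignReport

__all__ = ["plot_reports"]


def plot_reports(
    reports: Sequence[DesignReport],
    target: str = "area",
    facet_by: str = "duration",
    path=None,
):
    """Mean relative error (%) vs population sample size m, faceted by design.

    One facet per distinct duration (or interval), points are the mean RE
    across replicates with their CI bars; dotted guides mark the +/-
    threshold band.  Returns the matplotlib figure.
    """
    key = (
        (lambda r: r.design.schedule.duration)
        if facet_by == "duration"
        else (lambda r: r.design.schedule.interval)
    )
    facets = sorted({key(r) for r in reports})
    fig, axes = plt.subplots(
        1, len(facets), figsize=(3.2 * len(facets), 3.2), sharey=True, squeeze=False
    )
    thr = reports[0].design.error_threshold
    for ax, fval in zip(axes[0], facets):
        sub = sorted((r for r in reports if key(r) == fval), key=lambda r: r.design.m)
        ms = [r.design.m for r in sub]
        means = [r.summaries[target].mean_re for r in sub]
        cis = [r.summaries[target].re_ci for r in sub]
        ok = [r.verdict(target) for r in sub]
        colors = ["tab:blue" if o else "tab:red" for o in ok]
        for m, mean, (lo, hi), c in zip(ms, means, cis, colors):
            ax.errorbar(
                [m], [mean],
                yerr=[[mean - lo], [hi - mean]],
                fmt="o", color=c, capsize=3,
            )
        ax.axhline(thr, ls=":", c="k", lw=0.8)
        ax.axhline(-thr, ls=":", c="k", lw=0.8)
        ax.axhline(0, ls="-", c="0.8", lw=0.6)
        label = fval / 86400.0
        ax.set_title(
            f"T = {label:g} d" if facet_by == "duration" else f"dt = {fval/3600:g} h"
        )
        ax.set_xlabel("population sample size m")
    axes[0][0].set_ylabel("relative error (%)")
    fig.suptitle(f"{target} — mean relative error vs m")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
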