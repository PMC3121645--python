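"""Per-marker diagnostic figures.

Upper panel: histogram of the tetraploid signal ratios with the fitted
mixture density drawn on the ratio scale (the normal mixture lives on the
transformed scale, so the plotted curve carries the Jacobian of the inverse
transform), optionally with the diploid samples' histogram superimposed for
visual comparison.  Lower panel: assigned dosage against signal ratio with
unassigned samples marked separately.  Diploid records never enter fitting.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .em import MixtureFit
from .model import asr_transform
from .pipeline import MISSING, MarkerResult

logger = logging.getLogger("tetracall")


def mixture_density_on_ratio_scale(fit: MixtureFit, ratios: np.ndarray) -> np.ndarray:
    """Fitted mixture density expressed as a density of the raw ratio.

    With y = arcsin(sqrt(f)), dy/df = 1 / (2 sqrt(f (1 - f))), so
    p_f(f) = p_y(asr(f)) * dy/df.
    """
    f = np.clip(np.asarray(ratios, dtype=float), 1e-9, 1.0 - 1e-9)
    y = asr_transform(f)
    dens_y = np.zeros_like(f)
    for j in range(5):
        z = (y - fit.mu[j]) / fit.sigma
        dens_y += fit.pi[j] * np.exp(-0.5 * z**2) / (fit.sigma * np.sqrt(2 * np.pi))
    return dens_y / (2.0 * np.sqrt(f * (1.0 - f)))


def plot_marker(result: MarkerResult, path, diploid_ratios=None) -> None:
    """Write the two-panel diagnostic figure for one marker."""
    if result.ratios is None or len(result.ratios) == 0:
        logger.warning("marker %s: no data to plot", result.marker_id)
        return
    fig, (ax_hist, ax_calls) = plt.subplots(
        2, 1, figsize=(7, 6), sharex=True, height_ratios=[2, 1]
    )
    bins = np.linspace(0.0, 1.0, 41)
    ax_hist.hist(
        result.ratios, bins=bins, color="white", edgecolor="black", label="tetraploid"
    )
    if diploid_ratios is not None and len(diploid_ratios):
        ax_hist.hist(
            diploid_ratios, bins=bins, color="gray", alpha=0.6, label="diploid (overlay)"
        )
    fit = result.selected_fit
    if fit is not None:
        grid = np.linspace(1e-4, 1.0 - 1e-4, 400)
        dens = mixture_density_on_ratio_scale(fit, grid)
        scale = len(result.ratios) * (bins[1] - bins[0])
        ax_hist.plot(grid, dens * scale, color="green", lw=1.5, label="fitted mixture")
    title = f"{result.marker_id}"
    if result.status == "rejected":
        title += f"  (rejected: {result.rejection_reason})"
    ax_hist.set_title(title)
    ax_hist.set_ylabel("samples")
    ax_hist.legend(loc="best", fontsize=8)

    if result.calls is not None:
        calls = np.asarray(result.calls)
        assigned = calls != MISSING
        ax_calls.scatter(
            result.ratios[assigned], calls[assigned], s=12, color="black", label="assigned"
        )
        ax_calls.scatter(
            result.ratios[~assigned],
            np.full((~assigned).sum(), -0.5),
            s=12,
            color="red",
            label="unassigned",
        )
    ax_calls.set_ylim(-1, 4.5)
    ax_calls.set_yticks(range(5))
    ax_calls.set_xlabel("allele signal ratio  a / (a + b)")
    ax_calls.set_ylabel("dosage")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
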