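"""Three-panel effect plot: group posteriors, contrast with HDI, superiority."""

from __future__ import annotations

import numpy as np


def plot_contrast_panels(results, figsize=(12, 3.5)):
    """Plot (1) posterior mean-yield distributions of both groups, (2) the
    contrast distribution annotated with its HDI, and (3) the share of
    contrast mass above zero — the probability that a treated measurement
    beats its matched control."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=figsize)
    c = results.contrast_result

    ax = axes[0]
    for label, post, color in (("test", results.test_posterior, "tab:green"),
                               ("control", results.control_posterior, "tab:brown")):
        ax.hist(post.mu_flat, bins=60, density=True, alpha=0.6,
                color=color, label=f"{label} (mean {post.mu_flat.mean():.0f})")
    ax.set_xlabel("posterior mean yield (kg/ha)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    ax.set_title("group posteriors")

    ax = axes[1]
    ax.hist(c.draws, bins=60, density=True, color="tab:blue", alpha=0.7)
    ax.axvline(c.contrast_mean, color="k", lw=1,
               label=f"mean {c.contrast_mean:.0f}")
    ax.axvspan(c.hdi_low, c.hdi_high, color="orange", alpha=0.25,
               label=f"{100 * c.hdi_mass:.0f}% HDI "
                     f"[{c.hdi_low:.0f}, {c.hdi_high:.0f}]")
    ax.set_xlabel("contrast (kg/ha)")
    ax.legend(fontsize=8)
    ax.set_title(f"contrast distribution ({c.mode})")

    ax = axes[2]
    positive = c.draws > 0
    ax.hist(c.draws[~positive], bins=40, color="0.7", density=False)
    ax.hist(c.draws[positive], bins=40, color="tab:green", density=False)
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("contrast (kg/ha)")
    ax.set_title(f"P(test > control) = {100 * c.superiority_prob:.1f}%")

    fig.suptitle(results.model.location or "", y=1.02)
    fig.tight_layout()
    return fig
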