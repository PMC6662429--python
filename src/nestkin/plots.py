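"""Matplotlib figures for the spatial analyses (K/L envelopes, edge thinning)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_k_envelope", "plot_thinning"]


def plot_k_envelope(estimate, envelope, title: str = ""):
    """Two-panel figure: (a) K(r) with theoretical curve and envelope bounds,
    (b) the variance-stabilized L(r) - r transform."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    r = envelope.r_grid
    ax1.fill_between(r, envelope.k_lo, envelope.k_hi, color="0.85", label="envelope")
    ax1.plot(r, envelope.k_theo, "r--", label=r"$K_{theo}(r)=\pi r^2$")
    ax1.plot(r, envelope.k_obs, "k-", label=r"$\hat K_{obs}(r)$")
    ax1.set_xlabel("r (m)")
    ax1.set_ylabel("K(r)")
    ax1.legend(fontsize=8)
    ax2.axhline(0.0, color="r", ls="--")
    ax2.plot(estimate.r_grid, estimate.l_minus_r, "k-")
    ax2.set_xlabel("r (m)")
    ax2.set_ylabel("L(r) − r")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_thinning(profile, plateaus=(), title: str = ""):
    """Step plot of connected-component count against link distance, with
    detected threshold distances as dotted verticals."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(profile.r_steps, profile.n_clusters, where="post", color="k")
    for td in plateaus:
        ax.axvline(td.td, ls=":", color="0.5")
    ax.set_xlabel("link distance r (m)")
    ax.set_ylabel("number of clusters")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
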