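"""ISD chart rendering.

Two figures are produced per comparison: the normalised ISD chart (isodose
level on x, ISD % on y, straight tolerance lines at +/-100 %, a dashed
vertical divider at ISO_mr separating the "Normal Tissue" and "PTV"
regions) and the raw chart showing the un-normalised Bray-Curtis values
against their level-dependent, asymmetric acceptance limits.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import ISDCurve

__all__ = ["plot_isd_chart", "plot_raw_chart"]


def _levels_and(curve: ISDCurve, attr: str):
    entries = sorted(curve.entries, key=lambda e: e.level)
    return (
        np.array([e.level for e in entries]),
        np.array([getattr(e, attr) for e in entries]),
    )


def plot_isd_chart(curve: ISDCurve, path=None, title: str | None = None):
    """Normalised ISD chart with +/-100 % tolerance lines and region split."""
    levels, isd = _levels_and(curve, "isd_percent")
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.axhline(100, color="red", lw=1.2)
    ax.axhline(-100, color="red", lw=1.2)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.plot(levels, isd, "o-", color="tab:blue", label="ISD")
    ax.axvline(curve.iso_mr, color="black", ls="--", lw=1.0)
    ymax = max(120.0, 1.1 * float(np.abs(isd).max()))
    ax.set_ylim(-ymax, ymax)
    ax.text(
        curve.iso_mr - 1, ymax * 0.9, "Normal Tissue", ha="right", fontsize=9
    )
    ax.text(curve.iso_mr + 1, ymax * 0.9, "PTV", ha="left", fontsize=9)
    ax.set_xlabel("Isodose level (%)")
    ax.set_ylabel("ISD (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_raw_chart(curve: ISDCurve, path=None, title: str | None = None):
    """Raw Bray-Curtis values with their asymmetric per-level limits."""
    levels, bc = _levels_and(curve, "bc")
    _, lo = _levels_and(curve, "bc_limit_low")
    _, up = _levels_and(curve, "bc_limit_up")
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(levels, bc, "o-", color="tab:blue", label="BC(eval vs ref)")
    ax.plot(levels, up, "s--", color="tab:red", label="BC_ISOup limit")
    ax.plot(levels, lo, "^--", color="tab:orange", label="BC_ISOlow limit")
    ax.axvline(curve.iso_mr, color="black", ls="--", lw=1.0)
    ax.set_xlabel("Isodose level (%)")
    ax.set_ylabel("Bray-Curtis dissimilarity")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
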