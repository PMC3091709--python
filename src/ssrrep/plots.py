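"""Optional figure rendering (requires matplotlib).

Three views mirror the standard presentation of representativeness
analyses: observed one-way counts against the binomial envelope of the
reference; a dot matrix of per-cell deviations with dot area scaled by
-log10 of the adjusted p-value; and bootstrap confidence-interval curves
of chi2/df against the number of resampled chromosomes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install ssrrep[plot])") from exc
    return plt


def envelope_plot(labels, observed, lower, upper, title: str, path: str) -> None:
    """Observed counts (black) over the reference 95% envelope (red)."""
    plt = _plt()
    x = np.arange(len(labels))
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(labels)), 3.2))
    ax.vlines(x, lower, upper, color="red", lw=3, alpha=0.6, label="reference 95% envelope")
    ax.plot(x, observed, "ko", ms=4, label="observed")
    ax.set_xticks(x, [str(l) for l in labels], rotation=90, fontsize=7)
    ax.set_ylabel("microsatellite count")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cell_dot_matrix(cells, shape, title: str, path: str, alpha: float = 0.05) -> None:
    """Red/blue dot matrix of significant over/under-represented cells.

    Dot area grows with -log10(adjusted p), so size is inversely related
    to the p-value and comparable across panels.
    """
    plt = _plt()
    fig, ax = plt.subplots(figsize=(0.35 * shape[1] + 2, 0.35 * shape[0] + 2))
    for cell in cells:
        if cell.direction == "none":
            continue
        a, b = cell.index
        size = 8 + 18 * min(-np.log10(max(cell.p_adjusted, 1e-12)), 12)
        ax.scatter(b, a, s=size, c="red" if cell.direction == "over" else "blue")
    ax.set_xlim(-0.5, shape[1] - 0.5)
    ax.set_ylim(shape[0] - 0.5, -0.5)
    ax.set_title(f"{title} (BH-FDR {alpha})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bootstrap_curve(cis: Sequence, title: str, path: str) -> None:
    """95% CI of chi2/df against the number of bootstrapped chromosomes."""
    plt = _plt()
    r = [ci.r for ci in cis]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.fill_between(r, [ci.lower for ci in cis], [ci.upper for ci in cis], alpha=0.3)
    ax.plot(r, [np.median(ci.replicates) for ci in cis], "o-", ms=3)
    ax.set_xlabel("bootstrapped chromosomes r")
    ax.set_ylabel("chi2 / df")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
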