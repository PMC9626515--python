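"""Optional diagnostic plots (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluate import RecoveryReport, hdi


def _mpl():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as e:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the 'plot' extra)") from e
    return plt


def plot_recovery(report: RecoveryReport, out_path: str | Path) -> Path:
    """Scatter of true vs recovered subject-level posterior means."""
    plt = _mpl()
    fig, axes = plt.subplots(1, len(report.parameters), figsize=(4 * len(report.parameters), 4))
    for ax, p in zip(np.atleast_1d(axes), report.parameters):
        x = report.true_means[p]
        y = report.recovered_means[p]
        ax.scatter(x, y, s=18, alpha=0.7)
        lims = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"true {p}")
        ax.set_ylabel(f"recovered {p}")
        ax.set_title(f"r = {report.correlations[p]:.2f}")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_difference_density(diff_draws: np.ndarray, out_path: str | Path,
                            label: str = "difference") -> Path:
    """Histogram of a posterior-difference distribution with its 95% HDI."""
    plt = _mpl()
    iv = hdi(diff_draws)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(diff_draws, bins=60, density=True, alpha=0.75)
    ax.axvline(0, color="k", lw=1)
    ax.hlines(0, iv.lower, iv.upper, color="crimson", lw=5,
              label=f"95% HDI [{iv.lower:.3f}, {iv.upper:.3f}]")
    ax.set_xlabel(label)
    ax.legend(frameon=False)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
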