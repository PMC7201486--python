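"""Optional matplotlib figures for cohort reports."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort_stats import TruncationCurve


def plot_score_scatter(cohort: pd.DataFrame, path: str | Path) -> Path:
    """SPB-vs-AG scatter coloured by TQCE."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(cohort["SPB"], cohort["AG"], c=cohort["TQCE"], cmap="viridis", s=30)
    fig.colorbar(sc, ax=ax, label="TQCE")
    ax.set_xlabel("SPB (z-score)")
    ax.set_ylabel("AG (z-score)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_truncation_curve(curve: TruncationCurve, path: str | Path) -> Path:
    """Model-vs-TQCE Spearman correlation per allowed test time."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.times, curve.r_cv, "o-", label="SPB+AG+DT model")
    ax.plot(curve.times, curve.r_dt, "s-", label="DT-only model")
    ax.set_xlabel("test time (s)")
    ax.set_ylabel("Spearman r (fitted vs TQCE)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
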