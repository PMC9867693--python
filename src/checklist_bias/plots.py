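"""Duration-vs-bias figures: points, fitted power curve, 95% band, parity line."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .effort import CurveBand, PowerFitResult


def plot_bias_curve(
    records: pd.DataFrame,
    fit: PowerFitResult,
    band: CurveBand,
    path,
    title: str = "",
) -> None:
    """One comparison panel: bias points over duration with the fitted curve."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(records["duration"], records["bias"], s=12, color="black", alpha=0.5)
    ax.plot(band.x, band.fitted, color="tab:blue", lw=2,
            label=f"y = {fit.coef:.4f} x^{fit.exp:.4f} - 1")
    ax.fill_between(band.x, band.lower95, band.upper95, color="tab:blue", alpha=0.2)
    ax.axhline(0.0, color="red", lw=1.5)
    ax.set_xlabel("duration (min)")
    ax.set_ylabel("bias")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
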