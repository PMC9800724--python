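"""Optional matplotlib views of the selection report (SVG/PNG)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_density_bars(densities: pd.DataFrame, path: str | Path, value: str = "normalized_density"):
    """Bar chart of per-region densities (e.g. normalized complex densities)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    label_col = "complex" if "complex" in densities.columns else densities.columns[0]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(densities[label_col], densities[value], color="#4878a8")
    ax.set_ylabel("mutations / sample / kb")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dssh_regression(regression: dict, per_gene: pd.DataFrame, path: str | Path):
    """Scatter of gene density vs gene-mean DssH with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(per_gene["mean_dss"], per_gene["density"], s=18, color="#a84848")
    xs = np.linspace(per_gene["mean_dss"].min(), per_gene["mean_dss"].max(), 10)
    ax.plot(xs, regression["slope"] * xs + regression["intercept"], "k--", lw=1)
    ax.set_xlabel("gene-mean DssH (genome-length units)")
    ax.set_ylabel("C$_H$>T$_H$ density (/sample/kb)")
    ax.set_title(f"r = {regression['r']:.3f}, p = {regression['p']:.3g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
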