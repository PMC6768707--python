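"""Optional figures for simulation summaries (matplotlib, lazily imported)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_test_summary(df: pd.DataFrame, path: str | Path | None = None):
    """Plot relative bias (with ±1 relative-SE whiskers) for one test's cells.

    Cells are arranged along the x axis in table order; panels are implied
    by the parameter columns that vary. Returns the matplotlib figure; saves
    to ``path`` when given. Purely presentational — no analysis happens here.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    varying = [
        c for c in ("n_key", "n_key_sampled", "scenario_key", "scenario_nonkey",
                    "false_positive_rate")
        if c in df.columns and df[c].nunique() > 1
    ]
    labels = [
        "\n".join(f"{c.replace('_', ' ')}={row[c]}" for c in varying) or str(i)
        for i, (_, row) in enumerate(df.iterrows())
    ]
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(df)), 4))
    x = range(len(df))
    ax.errorbar(x, df["relative_bias_pct"], yerr=df["relative_se_pct"],
                fmt="o", capsize=3)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("relative bias (%), whiskers = ±1 relative SE")
    test = df["test"].iloc[0] if "test" in df.columns else ""
    ax.set_title(f"Test {test}: venue-based scale-up estimator")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
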