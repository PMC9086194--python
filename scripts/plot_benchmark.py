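"""Plot a long-format benchmark table: one panel per metric, one line per selector.

    python scripts/plot_benchmark.py results.csv --out figures/
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

METRICS = ("fdr", "sensitivity", "stability", "f1")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table", type=Path, help="long-format CSV from the benchmark")
    ap.add_argument("--out", type=Path, default=Path("figures"))
    args = ap.parse_args()

    tab = pd.read_csv(args.table)
    args.out.mkdir(parents=True, exist_ok=True)

    means = (
        tab[tab.metric.isin(METRICS)]
        .groupby(["scenario", "selector", "metric"])["value"]
        .mean()
        .reset_index()
    )
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, metric in zip(axes.ravel(), METRICS):
        sub = means[means.metric == metric]
        for sel, grp in sub.groupby("selector"):
            ax.plot(grp.scenario, grp.value, marker="o", label=sel)
        ax.set_title(metric.upper() if metric == "fdr" else metric.capitalize())
        ax.set_ylim(0, 1)
        ax.tick_params(axis="x", rotation=45)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    out = args.out / "selection_metrics.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")

    acc = tab[tab.metric.isin(["accuracy", "auc"]) & (tab.classifier != "")]
    if len(acc):
        means = (
            acc.groupby(["classifier", "selector", "metric"])["value"]
            .mean().reset_index()
        )
        fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
        for ax, metric in zip(axes, ("accuracy", "auc")):
            sub = means[means.metric == metric]
            for sel, grp in sub.groupby("selector"):
                ax.plot(grp.classifier, grp.value, marker="o", label=sel)
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=45)
        axes[0].legend(fontsize=8)
        fig.tight_layout()
        out = args.out / "prediction_performance.png"
        fig.savefig(out, dpi=150)
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
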