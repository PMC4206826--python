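"""Figure rendering from pipeline output tables.

Four summary figures mirroring the standard presentation of this kind of
experiment: a population-average dF/F trace with SEM band and stimulus
marker, a cell x time dF/F color map, the per-paradigm dF/F(2hr - before)
bar chart, and the pattern-similarity time course per paradigm.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

REQUIRED_TABLES = ("popavg_trace", "per_cell_metrics", "dff_change", "similarity")


def make_report(outdir, fmt: str = "png") -> list:
    """Render figures from the CSV tables in ``outdir``; returns file paths."""
    outdir = Path(outdir)
    missing = [n for n in REQUIRED_TABLES if not (outdir / f"{n}.csv").exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline tables in {outdir}: {missing}")
    tables = {n: pd.read_csv(outdir / f"{n}.csv") for n in REQUIRED_TABLES}
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    paths = []

    # 1. population-average trace with SEM band
    tr = tables["popavg_trace"]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(tr["time_s"], tr["mean_dff"], color="tab:green")
    ax.fill_between(tr["time_s"], tr["mean_dff"] - tr["sem_dff"],
                    tr["mean_dff"] + tr["sem_dff"], alpha=0.3, color="tab:green")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("dF/F")
    ax.set_title("Population average (SEM band)")
    paths.append(_save(fig, figdir / f"population_average.{fmt}"))

    # 2. cell x time-point color map of per-cell peak dF/F
    cells = tables["per_cell_metrics"]
    if cells.empty:
        raise ValueError("per_cell_metrics is empty; nothing to map")
    par0 = cells["paradigm"].iloc[0]
    sub = cells[(cells["paradigm"] == par0) & (cells["animal"] == cells["animal"].min())]
    grid = sub.pivot_table(index="cell_id", columns="time_point", values="peak_dff",
                           sort=False)
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45)
    ax.set_xlabel("time point")
    ax.set_ylabel("cell")
    ax.set_title(f"Per-cell peak dF/F ({par0}, one animal)")
    fig.colorbar(im, ax=ax, label="peak dF/F")
    paths.append(_save(fig, figdir / f"cell_map.{fmt}"))

    # 3. dF/F(2hr - before) by paradigm
    delta = tables["dff_change"]
    g = delta.groupby("paradigm")["dff_2hr_minus_before"]
    mean, sem = g.mean(), g.std(ddof=1) / np.sqrt(g.count())
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(mean.index, mean.to_numpy(), yerr=sem.to_numpy(), capsize=4,
           color="tab:blue")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("dF/F (2hr - before)")
    paths.append(_save(fig, figdir / f"dff_change.{fmt}"))

    # 4. similarity time course per paradigm
    simdf = tables["similarity"]
    fig, ax = plt.subplots(figsize=(5, 3))
    order = list(dict.fromkeys(simdf["time_point"]))
    for par, sub in simdf.groupby("paradigm"):
        g = sub.groupby("time_point")["mean_cosine"]
        m = g.mean().reindex(order)
        s = (g.std(ddof=1) / np.sqrt(g.count())).reindex(order)
        ax.errorbar(order, m.to_numpy(), yerr=s.to_numpy(), label=par,
                    marker="o", capsize=3)
    ax.set_ylabel("pattern similarity (mean cosine)")
    ax.set_xlabel("time point")
    ax.legend(fontsize=8)
    paths.append(_save(fig, figdir / f"similarity.{fmt}"))
    return paths


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
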