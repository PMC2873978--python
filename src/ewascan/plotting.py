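"""Manhattan-style scan plots and class-level summary tables.

Reporting is a pure function of the persisted scan results: the same tidy
results table always regenerates the same figure and summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

#: plot symbols per cohort, cycled in cohort order
COHORT_MARKERS = ("D", "s", "o", "^", "v", "P", "X", "*")


def manhattan_plot(results: pd.DataFrame, alpha: float = 0.02,
                   validated: set[str] | frozenset[str] = frozenset(),
                   path: str | None = None, ax=None):
    """Environment-wide association plot.

    y is -log10(p); x groups factors by environmental class and orders them
    within class by ascending odds ratio (the analogue of chromosome, then
    position). One symbol per cohort; the horizontal threshold line sits at
    the exact -log10(alpha); validated factors are drawn emphasized. Zero
    p-values are plotted at a capped ceiling and annotated.
    """
    df = results.loc[np.isfinite(results["p_value"].to_numpy(dtype=float))
                     ].copy()
    if df.empty:
        raise ValueError("no finite p-values to plot")
    order = (df.groupby(["env_class", "symbol"], sort=True)["or_point"]
             .median().reset_index()
             .sort_values(["env_class", "or_point", "symbol"]))
    xpos = {sym: i for i, sym in enumerate(order["symbol"])}
    df["x"] = df["symbol"].map(xpos)

    finite_p = df.loc[df["p_value"] > 0, "p_value"]
    cap = -np.log10(finite_p.min()) + 1.0 if len(finite_p) else 10.0
    zero_p = df["p_value"] == 0
    df["neglogp"] = np.where(zero_p, cap,
                             -np.log10(df["p_value"].where(~zero_p)))

    if ax is None:
        fig, ax = plt.subplots(figsize=(max(8.0, len(xpos) * 0.06), 4.5))
    else:
        fig = ax.figure

    classes = order["env_class"].unique()
    cmap = plt.get_cmap("tab20")
    class_color = {c: cmap(i % 20) for i, c in enumerate(classes)}
    cohorts = list(dict.fromkeys(df["cohort_id"]))
    for ci, cid in enumerate(cohorts):
        sub = df[df["cohort_id"] == cid]
        emph = sub["symbol"].isin(validated)
        for mask, size, lw in ((~emph, 18, 0.0), (emph, 60, 1.2)):
            s = sub[mask]
            if s.empty:
                continue
            ax.scatter(s["x"], s["neglogp"],
                       c=[class_color[e] for e in s["env_class"]],
                       marker=COHORT_MARKERS[ci % len(COHORT_MARKERS)],
                       s=size, edgecolors="black" if lw else "none",
                       linewidths=lw, label=cid if mask is not emph else None)
    if zero_p.any():
        ax.annotate(f"p = 0 capped at {cap:.1f}", xy=(0.99, 0.99),
                    xycoords="axes fraction", ha="right", va="top",
                    fontsize=8)
    ax.axhline(-np.log10(alpha), color="red", lw=1.0)
    # class separators and labels
    bounds = order.groupby("env_class", sort=False).size().cumsum()
    start = 0
    for c, end in bounds.items():
        ax.text((start + end - 1) / 2.0, -0.08, str(c), rotation=90,
                ha="center", va="top", fontsize=7,
                transform=ax.get_xaxis_transform())
        start = end
    ax.set_xticks([])
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_xlabel("")
    handles, labels = ax.get_legend_handles_labels()
    seen: dict[str, object] = {}
    for h, l in zip(handles, labels):
        seen.setdefault(l, h)
    ax.legend(seen.values(), seen.keys(), fontsize=7, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def class_summary(results: pd.DataFrame, alpha: float = 0.02) -> pd.DataFrame:
    """Percent (and count) of significant factors per class per cohort.

    Classes not measured in a cohort are marked distinctly (NaN percent,
    ``measured = 0``) rather than reported as 0% significant.
    """
    rows = []
    classes = sorted(results["env_class"].unique())
    cohorts = list(dict.fromkeys(results["cohort_id"]))
    for c in classes:
        for cid in cohorts:
            sub = results[(results["env_class"] == c)
                          & (results["cohort_id"] == cid)]
            measured = int(sub["symbol"].nunique())
            if measured == 0:
                rows.append({"env_class": c, "cohort_id": cid, "measured": 0,
                             "significant": 0, "pct_significant": np.nan})
                continue
            p = sub["p_value"].to_numpy(dtype=float)
            sig = int(((p <= alpha) & np.isfinite(p)).sum())
            rows.append({"env_class": c, "cohort_id": cid,
                         "measured": measured, "significant": sig,
                         "pct_significant": 100.0 * sig / measured})
    return pd.DataFrame(rows)
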