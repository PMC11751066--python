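"""Sliding-window profiles of Jindex and RDE along a rank ordering.

For one TF's targets (joined with their list RDE values and weights),
genes are sorted by RDE or by a weight-modulated set rank and traversed
with a sliding window of width w = ceil(0.02 n).  Each window keeps the
raw Jindex and RDE values of its members plus two weighted means:
Saverage (weighted mean of the gene-set scores, i.e. Jindex) and
Laverage (weighted mean of the gene-list scores, i.e. RDE).  For a
repressor, windows at the top of the weighted-rank ordering show high
Jindex mass but low RDE mass — its strongest predicted targets are the
most downregulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ORDER_KEYS = ("rde", "weighted_rank")

REQUIRED_COLUMNS = ("gene_id", "jindex", "rde", "weight")


@dataclass
class WindowProfile:
    order_by: str
    window: int
    step: int
    genes: pd.DataFrame              # ordered; gene_id, jindex, rde, weight, ...
    bounds: list[tuple[int, int]]    # [start, end) index ranges into `genes`
    saverage: np.ndarray             # weighted mean Jindex per window
    laverage: np.ndarray             # weighted mean RDE per window

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_windows(self) -> int:
        return len(self.bounds)

    def window_values(self, k: int, column: str) -> np.ndarray:
        lo, hi = self.bounds[k]
        return self.genes[column].to_numpy()[lo:hi]


def default_window(n: int) -> int:
    """Window width w = ceil(0.02 n), at least 1."""
    return max(1, math.ceil(0.02 * n))


def sliding_profile(
    joined: pd.DataFrame,
    order_by: str = "weighted_rank",
    step: int = 1,
    window: int | None = None,
) -> WindowProfile:
    """Order genes and compute all sliding windows with weighted means.

    ``joined`` needs columns gene_id, jindex, rde, weight; for the
    weighted_rank ordering also s_rank (derived from descending jindex
    if absent).  Windows are [k*step, k*step + w) through the last full
    window, plus one terminal partial window when step > 1 leaves a
    tail uncovered.
    """
    if joined is None or len(joined) == 0:
        raise ValueError("empty profile input")
    missing = [c for c in REQUIRED_COLUMNS if c not in joined.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if order_by not in ORDER_KEYS:
        raise ValueError(f"order_by must be one of {ORDER_KEYS}")
    if step < 1:
        raise ValueError("step must be >= 1")
    genes = joined.copy()
    n = len(genes)
    if order_by == "rde":
        genes = genes.sort_values(["rde", "gene_id"], ascending=[False, True])
    else:
        if "s_rank" not in genes.columns:
            genes = genes.sort_values(["jindex", "gene_id"], ascending=[False, True])
            genes["s_rank"] = np.arange(1, n + 1)
        # weight-modulated set rank: top (low) set ranks score highest
        genes["weighted_rank"] = genes["weight"] * (n + 1 - genes["s_rank"])
        genes = genes.sort_values(["weighted_rank", "gene_id"], ascending=[False, True])
    genes = genes.reset_index(drop=True)

    w = default_window(n) if window is None else int(window)
    if w < 1:
        raise ValueError("window must be >= 1")
    w = min(w, n)
    starts = list(range(0, n - w + 1, step))
    bounds = [(s, s + w) for s in starts]
    if bounds[-1][1] < n:  # terminal partial window covers the tail
        bounds.append((min(starts[-1] + step, bounds[-1][1]), n))

    wt = genes["weight"].to_numpy(dtype=float)
    jx = genes["jindex"].to_numpy(dtype=float)
    rde = genes["rde"].to_numpy(dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(wt)])
    cwj = np.concatenate([[0.0], np.cumsum(wt * jx)])
    cwr = np.concatenate([[0.0], np.cumsum(wt * rde)])
    sav, lav = [], []
    for lo, hi in bounds:
        wsum = cw[hi] - cw[lo]
        sav.append((cwj[hi] - cwj[lo]) / wsum)
        lav.append((cwr[hi] - cwr[lo]) / wsum)
    return WindowProfile(
        order_by=order_by, window=w, step=step, genes=genes, bounds=bounds,
        saverage=np.asarray(sav), laverage=np.asarray(lav),
    )


def profile_summary(profile: WindowProfile) -> pd.DataFrame:
    """Per-window quartiles and means of Jindex and RDE plus the
    weighted Saverage/Laverage, ready for plotting or TSV export."""
    if profile.n_windows == 0:
        raise ValueError("empty profile")
    rows = []
    for k, (lo, hi) in enumerate(profile.bounds):
        jx = profile.window_values(k, "jindex")
        rde = profile.window_values(k, "rde")
        rows.append({
            "window": k, "start": lo, "end": hi, "n_genes": hi - lo,
            "jindex_q1": np.percentile(jx, 25), "jindex_median": np.median(jx),
            "jindex_q3": np.percentile(jx, 75), "jindex_mean": jx.mean(),
            "rde_q1": np.percentile(rde, 25), "rde_median": np.median(rde),
            "rde_q3": np.percentile(rde, 75), "rde_mean": rde.mean(),
            "saverage": profile.saverage[k], "laverage": profile.laverage[k],
        })
    return pd.DataFrame(rows)


def build_profile_input(gene_set, gene_list, paired, weights) -> pd.DataFrame:
    """Join one TF's paired ranks with scores, RDE and weights.

    Rows are in set-rank order (i = 1..n), so row i carries S_i = i,
    the list rank R_i, the gene's Jindex-derived set score, its RDE and
    its weight v_i.
    """
    rde_by_gene = dict(zip(gene_list.frame["gene_id"], gene_list.frame["rde"]))
    score_by_gene = dict(zip(gene_set.table["gene_id"], gene_set.table["set_score"]))
    n = paired.n
    return pd.DataFrame({
        "gene_id": list(paired.gene_ids),
        "jindex": [score_by_gene[g] for g in paired.gene_ids],
        "rde": [rde_by_gene[g] for g in paired.gene_ids],
        "weight": np.asarray(weights, dtype=float),
        "s_rank": np.arange(1, n + 1),
        "r_rank": paired.r,
    })


def plot_profiles(
    profile_rde: WindowProfile,
    profile_wr: WindowProfile,
    path,
    title: str = "",
) -> None:
    """Two stacked panels: window medians/quartile bands of Jindex and
    RDE along the RDE ordering (top) and weighted-rank ordering
    (bottom), with Saverage/Laverage overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 7), sharex=False)
    for ax, profile, label in (
        (axes[0], profile_rde, "genes ordered by RDE"),
        (axes[1], profile_wr, "genes ordered by weighted rank"),
    ):
        summary = profile_summary(profile)
        x = summary["window"]
        ax.fill_between(x, summary["jindex_q1"], summary["jindex_q3"],
                        color="lightblue", alpha=0.6, label="Jindex IQR")
        ax.plot(x, summary["jindex_median"], color="steelblue", lw=1)
        ax2 = ax.twinx()
        ax2.fill_between(x, summary["rde_q1"], summary["rde_q3"],
                         color="khaki", alpha=0.6, label="RDE IQR")
        ax2.plot(x, summary["rde_median"], color="goldenrod", lw=1)
        ax.plot(x, summary["saverage"], color="navy", lw=1.5, ls="--", label="Saverage")
        ax2.plot(x, summary["laverage"], color="darkorange", lw=1.5, ls="--",
                 label="Laverage")
        ax.set_xlabel(f"window ({label})")
        ax.set_ylabel("Jindex")
        ax2.set_ylabel("RDE")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
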