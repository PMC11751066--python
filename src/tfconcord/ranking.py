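"""RDE ranking of differential-expression tables.

Each gene's log2 fold change and FDR are collapsed into a single signed
magnitude, the raw score of differential expression:

    RDE = -sgn(log2FC) * 2^|log2FC| * log10(FDR)

Since log10(FDR) <= 0, upregulated genes (log2FC > 0) get positive RDE
and downregulated genes negative RDE; confident calls (small FDR) are
amplified.  The full transcriptome — no significance filter — is then
sorted by descending RDE into the ranked gene list with list ranks
L_i = 1..n (1 = most upregulated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fallback clamp when a table reports FDR = 0 and has no positive FDR
MIN_FDR = 1e-300


class DERecord(NamedTuple):
    gene_id: str
    log2fc: float
    fdr: float


def compute_rde(log2fc, fdr):
    """RDE = -sgn(log2FC) * 2^|log2FC| * log10(FDR); vectorised.

    Requires 0 < fdr <= 1 (clamp zeros at table level first).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if (fdr <= 0).any():
        raise ValueError("fdr must be > 0 (clamp reported zeros first)")
    if (fdr > 1).any():
        raise ValueError("fdr must be <= 1")
    out = -np.sign(log2fc) * np.exp2(np.abs(log2fc)) * np.log10(fdr)
    if out.ndim == 0:
        return float(out)
    return out


def clamp_fdr(fdr: pd.Series) -> pd.Series:
    """Replace FDR == 0 (as reported by upstream tools) by the smallest
    positive FDR in the table, or 1e-300 if there is none."""
    fdr = fdr.astype(float)
    if (fdr < 0).any() or (fdr > 1).any():
        raise ValueError("fdr values must lie in [0, 1]")
    zeros = fdr == 0
    if zeros.any():
        positive = fdr[fdr > 0]
        floor = float(positive.min()) if len(positive) else MIN_FDR
        logger.warning("clamped %d zero FDR values to %.3g", int(zeros.sum()), floor)
        fdr = fdr.mask(zeros, floor)
    return fdr


@dataclass
class RankedGeneList:
    """All genes sorted by descending RDE with list ranks L_i = 1..n."""

    frame: pd.DataFrame  # gene_id, log2fc, fdr, rde, l_rank (sorted by l_rank)
    _rank_of: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._rank_of = dict(zip(self.frame["gene_id"], self.frame["l_rank"]))

    @property
    def n(self) -> int:
        return len(self.frame)

    def rank_of(self, gene_id: str) -> int:
        return self._rank_of[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank_of


def build_gene_list(table: Iterable[DERecord] | pd.DataFrame) -> RankedGeneList:
    """Rank all genes of a DE table by descending RDE.

    Ties in RDE are broken by gene_id (lexicographic) so the ranking is
    deterministic.  Duplicated gene ids and empty tables are errors.
    """
    if isinstance(table, pd.DataFrame):
        frame = table[["gene_id", "log2fc", "fdr"]].copy()
    else:
        frame = pd.DataFrame(list(table), columns=DERecord._fields)
    if frame.empty:
        raise ValueError("empty DE table")
    dups = frame["gene_id"][frame["gene_id"].duplicated()].unique()
    if len(dups):
        raise ValueError(f"duplicate gene ids: {sorted(map(str, dups))}")
    frame["rde"] = compute_rde(frame["log2fc"].to_numpy(), frame["fdr"].to_numpy())
    frame = frame.sort_values(
        ["rde", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    frame["l_rank"] = np.arange(1, len(frame) + 1)
    return RankedGeneList(frame=frame)
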