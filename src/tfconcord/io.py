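"""File formats and run configuration.

Conventions: GFF gene models are 1-based inclusive; offsets within
promoters are 0-based; the BED-like hits table uses 0-based half-open
[start, end) coordinates within the promoter.  All tables are TSV with
a header row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM, GeneModel, PromoterRecord, TFGeneSet
from .ranking import RankedGeneList, clamp_fdr

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_promoters(path) -> list[PromoterRecord]:
    return [PromoterRecord(gene_id=gid, sequence=seq)
            for gid, seq in read_fasta(path).items()]


def write_fasta(records, path) -> None:
    """Write promoters (PromoterRecord) or an id->sequence mapping."""
    if isinstance(records, Mapping):
        seq_records = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    else:
        seq_records = [SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
                       for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ------------------------------------------------------------ JASPAR PFM

_ROW_RE = re.compile(r"^\s*([ACGT])?\s*\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def read_pfm_file(path) -> list[tuple[str, np.ndarray]]:
    """Parse JASPAR-style PFM text: '>ID name' then four A/C/G/T rows,
    numbers optionally bracketed.  Returns [(id, (length, 4) counts)].
    """
    entries: list[tuple[str, np.ndarray]] = []
    seen: set[str] = set()
    current_id = None
    rows: list[list[float]] = []
    row_lines: list[int] = []

    def flush(line_no):
        nonlocal current_id, rows
        if current_id is None:
            return
        if len(rows) != 4:
            raise ValueError(
                f"{path}: motif {current_id!r} has {len(rows)} rows "
                f"(need 4: A,C,G,T) near line {line_no}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(
                f"{path}: motif {current_id!r} row width mismatch at line {row_lines[-1]}")
        counts = np.array(rows, dtype=float).T  # (length, 4)
        if (counts < 0).any():
            raise ValueError(f"{path}: motif {current_id!r} has negative counts")
        entries.append((current_id, counts))
        current_id, rows = None, []
        row_lines.clear()

    with open(path) as handle:
        line_no = 0
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ValueError(f"{path}: empty motif id at line {line_no}")
                if current_id in seen:
                    raise ValueError(f"{path}: duplicate motif id {current_id!r} "
                                     f"at line {line_no}")
                seen.add(current_id)
                continue
            if current_id is None:
                raise ValueError(f"{path}: data before first header at line {line_no}")
            match = _ROW_RE.match(line)
            if not match or not match.group(2).strip():
                raise ValueError(f"{path}: malformed row for motif {current_id!r} "
                                 f"at line {line_no}")
            letter = match.group(1)
            expected = "ACGT"[len(rows)] if len(rows) < 4 else None
            if letter is not None and letter != expected:
                raise ValueError(f"{path}: unexpected base row {letter!r} "
                                 f"(expected {expected!r}) at line {line_no}")
            try:
                values = [float(x) for x in match.group(2).split()]
            except ValueError:
                raise ValueError(f"{path}: malformed row for motif {current_id!r} "
                                 f"at line {line_no}") from None
            rows.append(values)
            row_lines.append(line_no)
        flush(line_no)
    if not entries:
        logger.warning("%s: no motifs found", path)
    return entries


def write_pfm_file(pwms: Sequence[PWM], path) -> None:
    """Write motifs as JASPAR-style count matrices.

    Uses the stored source counts when available, otherwise scales the
    probabilities to integer pseudo-counts (x1000).
    """
    with open(path, "w") as handle:
        for pwm in pwms:
            counts = pwm.counts
            if counts is None:
                counts = np.rint(pwm.probs * 1000).astype(int)
            counts = np.asarray(counts)
            handle.write(f">{pwm.tf_id}\n")
            for b, base in enumerate("ACGT"):
                row = " ".join(f"{v:g}" for v in counts[:, b])
                handle.write(f"{base} [ {row} ]\n")


# --------------------------------------------------------------- DE table

#: accepted header spellings per canonical column
DE_ALIASES = {
    "gene_id": ("gene_id", "gene", "Gene", "GeneID", "ID", "gene_name"),
    "log2fc": ("log2fc", "log2FC", "logFC", "log2FoldChange"),
    "fdr": ("fdr", "FDR", "adj.P.Val", "padj", "qvalue", "q_value"),
}


def read_de_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a DE table (TSV with header) into gene_id/log2fc/fdr columns.

    ``column_map`` maps source header -> canonical name and takes
    precedence over the built-in aliases (generic and limma-style
    headers are recognised automatically).  Zero FDRs are clamped to
    the smallest positive FDR in the table.  No significance filter is
    applied: the ranked list uses all genes.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    rename = {}
    for canonical, aliases in DE_ALIASES.items():
        found = [c for c in raw.columns if c in aliases]
        if canonical not in raw.columns and not found:
            raise ValueError(f"{path}: no column for {canonical!r} "
                             f"(accepted: {aliases}; or pass column_map)")
        if canonical not in raw.columns:
            rename[found[0]] = canonical
    frame = raw.rename(columns=rename)[["gene_id", "log2fc", "fdr"]].copy()
    for col in ("log2fc", "fdr"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric {col!r} value "
                             f"{frame[col][bad.idxmax()]!r} at row {row}")
        frame[col] = numeric
    frame["fdr"] = clamp_fdr(frame["fdr"])
    return frame


# ------------------------------------------------------------ TSV writers

def write_hits(hits: pd.DataFrame, pwm_lengths: Mapping[str, int], path) -> None:
    """BED-like hits: promoter_gene, start, end, tf_id, jindex, strand
    (0-based half-open within the promoter)."""
    out = pd.DataFrame({
        "promoter_gene": hits["gene_id"],
        "start": hits["offset"].astype(int),
        "end": hits["offset"].astype(int)
        + hits["tf_id"].map(pwm_lengths).astype(int),
        "tf_id": hits["tf_id"],
        "jindex": hits["jindex"],
        "strand": hits["strand"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame({
        "tf_id": raw["tf_id"], "gene_id": raw["promoter_gene"],
        "offset": raw["start"], "strand": raw["strand"], "jindex": raw["jindex"],
    })


def write_gene_sets(gene_sets: Sequence[TFGeneSet], path) -> None:
    frames = []
    for gs in gene_sets:
        frame = gs.table.copy()
        frame.insert(0, "tf_id", gs.tf_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> list[TFGeneSet]:
    raw = pd.read_csv(path, sep="\t")
    return [
        TFGeneSet(tf_id=str(tf), table=sub[["gene_id", "set_score", "s_rank"]]
                  .sort_values("s_rank").reset_index(drop=True))
        for tf, sub in raw.groupby("tf_id", sort=True)
    ]


def write_ranked_list(gene_list: RankedGeneList, path) -> None:
    gene_list.frame.to_csv(path, sep="\t", index=False)


def read_ranked_list(path) -> RankedGeneList:
    frame = pd.read_csv(path, sep="\t").sort_values("l_rank").reset_index(drop=True)
    return RankedGeneList(frame=frame)


def write_results(results_frame: pd.DataFrame, path) -> None:
    results_frame.to_csv(path, sep="\t", index=False)


def write_metadata(metadata: dict, path) -> None:
    with open(path, "w") as handle:
        json.dump(metadata, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ----------------------------------------------------------------- GFF3

def read_gff_genes(path) -> list[GeneModel]:
    """Gene features from GFF3 (ID attribute as gene_id)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id=gene_id, contig=feat.seqid,
                               start=feat.start, end=feat.end, strand=feat.strand))
    return genes


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the study conventions
    (550-bp promoters, Jindex threshold 1.0)."""

    pfm_path: str | None = None
    de_path: str | None = None
    promoter_fasta: str | None = None
    genome_fasta: str | None = None
    gff_path: str | None = None
    outdir: str = "results"
    promoter_length: int = 550
    jindex_threshold: float = 1.0
    both_strands: bool = True
    pseudocount: float = 0.25
    aggregation: str = "max"
    weighting: str = "mixed_density"
    n_perm: int = 0
    alpha: float = 0.05
    min_overlap: int = 3
    seed: int = 0
    column_map: dict = field(default_factory=dict)
    n_profile: int = 1  # top hits to profile

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
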