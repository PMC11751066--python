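"""End-to-end orchestration: scan -> gene sets -> ranked list -> screen
-> window profiles, from files (run_pipeline) or fully in memory on
synthetic data (run_synthetic_screen)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .concordance import (ConcordanceResult, compute_weights, pair_ranks,
                          results_to_frame, screen_tfs)
from .motifs import (PWM, PromoterRecord, TFGeneSet, build_gene_sets,
                     extract_promoters, pfm_to_pwm, scan_all)
from .ranking import RankedGeneList, build_gene_list
from .simulate import (SyntheticTruth, generate_de_table, generate_promoters,
                       generate_pwms)
from .windows import build_profile_input, profile_summary, sliding_profile

logger = logging.getLogger(__name__)


@dataclass
class ScreenBundle:
    """Everything one screen computed, for inspection or testing."""

    pwms: list[PWM]
    promoters: list[PromoterRecord]
    hits: pd.DataFrame
    gene_sets: list[TFGeneSet]
    gene_list: RankedGeneList
    results: list[ConcordanceResult]
    truth: SyntheticTruth | None = None
    de_table: pd.DataFrame | None = None

    @property
    def results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)


def _profile_top_hits(bundle: ScreenBundle, n_profile: int, min_overlap: int,
                      weighting: str, outdir: Path | None = None):
    """Sliding-window profiles (both orderings) for the top hits."""
    profiles = {}
    sets_by_id = {gs.tf_id: gs for gs in bundle.gene_sets}
    for res in bundle.results[:n_profile]:
        gene_set = sets_by_id[res.tf_id]
        paired = pair_ranks(gene_set, bundle.gene_list, min_overlap=min_overlap)
        weights = compute_weights(paired, mode=weighting)
        joined = build_profile_input(gene_set, bundle.gene_list, paired, weights)
        by_rde = sliding_profile(joined, order_by="rde")
        by_wr = sliding_profile(joined, order_by="weighted_rank")
        profiles[res.tf_id] = (by_rde, by_wr)
        if outdir is not None:
            profile_summary(by_rde).to_csv(
                outdir / f"profile_{res.tf_id}_by_rde.tsv", sep="\t", index=False)
            profile_summary(by_wr).to_csv(
                outdir / f"profile_{res.tf_id}_by_weighted_rank.tsv",
                sep="\t", index=False)
    return profiles


def run_pipeline(config: tio.RunConfig) -> ScreenBundle:
    """File-based pipeline; writes all artifacts plus run metadata."""
    for label, path in (("pfms", config.pfm_path), ("de table", config.de_path)):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{label}: file not found ({path})")
    if config.promoter_fasta:
        if not Path(config.promoter_fasta).exists():
            raise FileNotFoundError(
                f"promoters: file not found ({config.promoter_fasta})")
        promoters = tio.read_promoters(config.promoter_fasta)
        digests = {"promoters": tio.file_digest(config.promoter_fasta)}
    elif config.genome_fasta and config.gff_path:
        for label, path in (("genome", config.genome_fasta), ("gff", config.gff_path)):
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: file not found ({path})")
        genome = tio.read_fasta(config.genome_fasta)
        genes = tio.read_gff_genes(config.gff_path)
        promoters = extract_promoters(genome, genes, upstream_bp=config.promoter_length)
        digests = {"genome": tio.file_digest(config.genome_fasta),
                   "gff": tio.file_digest(config.gff_path)}
    else:
        raise FileNotFoundError(
            "promoters: provide promoter_fasta or genome_fasta + gff_path")
    digests["pfms"] = tio.file_digest(config.pfm_path)
    digests["de"] = tio.file_digest(config.de_path)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage scan: %d promoters", len(promoters))
    pfms = tio.read_pfm_file(config.pfm_path)
    pwms = [pfm_to_pwm(counts, pseudocount=config.pseudocount, tf_id=tf_id)
            for tf_id, counts in pfms]
    hits = scan_all(pwms, promoters, threshold=config.jindex_threshold,
                    both_strands=config.both_strands)
    gene_sets = build_gene_sets(hits, aggregation=config.aggregation)

    logger.info("stage rank: reading %s", config.de_path)
    de = tio.read_de_table(config.de_path, column_map=config.column_map or None)
    gene_list = build_gene_list(de)

    logger.info("stage screen: %d gene sets, %d genes", len(gene_sets), gene_list.n)
    results = screen_tfs(gene_sets, gene_list, weighting=config.weighting,
                         n_perm=config.n_perm, alpha=config.alpha,
                         seed=config.seed, min_overlap=config.min_overlap)
    bundle = ScreenBundle(pwms=pwms, promoters=promoters, hits=hits,
                          gene_sets=gene_sets, gene_list=gene_list, results=results)

    pwm_lengths = {p.tf_id: p.length for p in pwms}
    tio.write_hits(hits, pwm_lengths, outdir / "hits.tsv")
    if gene_sets:
        tio.write_gene_sets(gene_sets, outdir / "gene_sets.tsv")
    tio.write_ranked_list(gene_list, outdir / "ranked_list.tsv")
    tio.write_results(bundle.results_frame, outdir / "results.tsv")
    _profile_top_hits(bundle, config.n_profile, config.min_overlap,
                      config.weighting, outdir)
    tio.write_metadata({
        "config": config.to_dict(),
        "seed": config.seed,
        "input_digests": digests,
        "n_promoters": len(promoters),
        "n_hits": int(len(hits)),
        "n_gene_sets": len(gene_sets),
        "n_tested": len(results),
    }, outdir / "metadata.json")
    return bundle


# ----------------------------------------------------------- synthetic

def run_synthetic_screen(
    seed: int,
    n_genes: int = 2000,
    n_decoys: int = 24,
    promoter_length: int = 550,
    motif_length: int = 10,
    concentration: float = 0.5,
    planted_fraction: float = 0.15,
    strength_range: tuple[float, float] = (0.5, 1.0),
    effect_size: float = 1.0,
    direction: str = "repressor",
    noise_sd: float = 1.0,
    threshold: float = 1.0,
    weighting: str = "mixed_density",
    n_perm: int = 0,
    alpha: float = 0.05,
) -> ScreenBundle:
    """Generate a synthetic study and screen it, fully in memory.

    The first generated motif is the focal (planted, DE-coupled) TF;
    the rest are decoys planted independently of the DE signal.
    """
    s_pwm, s_prom, s_de = np.random.SeedSequence(seed).spawn(3)
    pwms = generate_pwms(k=n_decoys + 1, length=motif_length,
                         concentration=concentration, seed=s_pwm)
    focal, decoys = pwms[0], pwms[1:]
    promoters, planted = generate_promoters(
        n_genes=n_genes, length=promoter_length, focal=focal,
        planted_fraction=planted_fraction, strength_range=strength_range,
        decoys=decoys, seed=s_prom)
    truth = SyntheticTruth(focal_tf=focal.tf_id, effect_size=effect_size,
                           direction=direction,
                           decoy_tfs=[p.tf_id for p in decoys],
                           seed=seed, planted=planted)
    hits = scan_all(pwms, promoters, threshold=threshold)
    focal_hits = hits[hits["tf_id"] == focal.tf_id]
    gene_jindex = focal_hits.groupby("gene_id")["jindex"].max().to_dict()
    de = generate_de_table(truth, gene_jindex, [p.gene_id for p in promoters],
                           noise_sd=noise_sd, seed=s_de)
    gene_list = build_gene_list(de)
    gene_sets = build_gene_sets(hits)
    results = screen_tfs(gene_sets, gene_list, weighting=weighting,
                         n_perm=n_perm, alpha=alpha, seed=seed)
    return ScreenBundle(pwms=pwms, promoters=promoters, hits=hits,
                        gene_sets=gene_sets, gene_list=gene_list,
                        results=results, truth=truth, de_table=de)
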