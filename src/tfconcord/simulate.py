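"""Self-contained synthetic data: motifs, promoters with planted sites,
and differential-expression tables with a known regulator effect.

The generator emulates the three inputs the pipeline consumes so every
stage is testable without downloads:

* random PFMs drawn position-wise from a Dirichlet (low concentration
  -> informative, near-consensus motifs);
* fixed-length promoters with i.i.d. background composition, into
  which motif occurrences are planted at random offsets with a
  per-gene "strength" (probability of emitting the consensus base per
  position);
* a DE table in which the focal TF's targets carry a latent shift
  proportional to their (standardised) promoter Jindex — negative for
  a repressor, positive for an activator — on top of Gaussian noise,
  mapped monotonically to (log2FC, FDR) so the RDE ordering reflects
  the latent ordering.

Decoy motifs are planted too (in independent random gene subsets, with
no coupling to the DE signal) so decoy TFs produce realistic, testable
gene sets that remain null by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import BASES, PWM, UNIFORM_BACKGROUND, PromoterRecord, pfm_to_pwm

#: counts scale used when materialising Dirichlet probabilities as a PFM
PFM_SCALE = 1000

DIRECTIONS = ("activator", "repressor")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study, for exact replay."""

    focal_tf: str
    effect_size: float
    direction: str
    decoy_tfs: list[str]
    seed: int
    planted: pd.DataFrame = field(default_factory=pd.DataFrame)
    # planted columns: gene_id, strength, offset (focal motif only)

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def direction_sign(self) -> int:
        return 1 if self.direction == "activator" else -1


def generate_pwms(
    k: int,
    length: int = 10,
    concentration: float = 0.5,
    seed=0,
    prefix: str = "TF",
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> list[PWM]:
    """k random motifs with Dirichlet(concentration) position columns.

    Probabilities are materialised as integer counts (scale 1000) and
    run through the standard PFM->PWM conversion, so generated motifs
    round-trip exactly through JASPAR-style files.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if length < 4:
        raise ValueError("length must be >= 4")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    if background is None:
        background = UNIFORM_BACKGROUND
    pwms = []
    width = len(str(k))
    for i in range(k):
        probs = rng.dirichlet(np.full(4, concentration), size=length)
        counts = np.rint(probs * PFM_SCALE).astype(int)
        counts[counts.sum(axis=1) == 0, :] = 1  # guard a fully-rounded-away row
        pwms.append(pfm_to_pwm(
            counts, pseudocount=pseudocount, background=background,
            tf_id=f"{prefix}{i + 1:0{width}d}",
        ))
    return pwms


def _sample_site(pwm: PWM, strength: float, rng) -> np.ndarray:
    """Planted occurrence: consensus base with prob `strength` per
    position, otherwise uniform over the three other bases."""
    consensus = pwm.probs.argmax(axis=1)
    codes = consensus.copy()
    miss = rng.random(pwm.length) >= strength
    if miss.any():
        offsets = rng.integers(1, 4, size=int(miss.sum()))
        codes[miss] = (consensus[miss] + offsets) % 4
    return codes


def generate_promoters(
    n_genes: int,
    length: int = 550,
    focal: PWM | None = None,
    planted_fraction: float = 0.15,
    strength_range: tuple[float, float] = (0.5, 1.0),
    decoys: tuple = (),
    seed=0,
    background: np.ndarray | None = None,
    plant_decoys: bool = True,
) -> tuple[list[PromoterRecord], pd.DataFrame]:
    """Promoters with planted motif occurrences plus the truth table.

    Background bases are i.i.d. from ``background`` (default uniform).
    A ``planted_fraction`` of genes receive one focal-motif occurrence
    at a uniform random offset, with per-gene strength drawn uniformly
    from ``strength_range``.  Decoy motifs are planted the same way in
    independent gene subsets (decoys first, so a focal site is never
    overwritten).  The truth table records the focal plants only.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    motifs = ([focal] if focal is not None else []) + list(decoys)
    for pwm in motifs:
        if pwm.length > length:
            raise ValueError(f"motif {pwm.tf_id} longer than promoter")
    rng = np.random.default_rng(seed)
    if background is None:
        background = UNIFORM_BACKGROUND
    codes = rng.choice(4, size=(n_genes, length), p=background).astype(np.uint8)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    n_plant = int(round(planted_fraction * n_genes))

    def plant(pwm: PWM, record: bool):
        idx = rng.choice(n_genes, size=n_plant, replace=False)
        strengths = rng.uniform(*strength_range, size=n_plant)
        offsets = rng.integers(0, length - pwm.length + 1, size=n_plant)
        for g, s, o in zip(idx, strengths, offsets):
            codes[g, o:o + pwm.length] = _sample_site(pwm, s, rng)
        if record:
            return pd.DataFrame({
                "gene_id": [gene_ids[g] for g in idx],
                "strength": strengths,
                "offset": offsets,
            })
        return None

    truth = pd.DataFrame(columns=["gene_id", "strength", "offset"])
    if plant_decoys:
        for pwm in decoys:
            plant(pwm, record=False)
    if focal is not None and n_plant:
        truth = plant(focal, record=True).sort_values("gene_id").reset_index(drop=True)

    lut = np.frombuffer((BASES + "N").encode(), dtype=np.uint8)
    promoters = [
        PromoterRecord(gene_id=gid, sequence=lut[row].tobytes().decode("ascii"))
        for gid, row in zip(gene_ids, codes)
    ]
    return promoters, truth


def generate_de_table(
    truth: SyntheticTruth,
    gene_jindex: dict,
    gene_ids,
    noise_sd: float = 1.0,
    seed=0,
) -> pd.DataFrame:
    """DE table whose RDE ordering encodes the planted regulator effect.

    Latent score: z_g = sign(direction) * effect_size * standardised
    Jindex_g + N(0, noise_sd) for focal targets (genes present in
    ``gene_jindex``), pure N(0, noise_sd) otherwise.  Monotone map to
    the observable columns: log2fc = z_g and fdr = two-sided normal
    tail of z_g / noise_sd, clamped to (1e-12, 1], so RDE ordering
    reflects z ordering.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, noise_sd, size=len(gene_ids))
    targets = [i for i, g in enumerate(gene_ids) if g in gene_jindex]
    if targets and truth.effect_size > 0:
        jx = np.array([gene_jindex[gene_ids[i]] for i in targets], dtype=float)
        sd = jx.std()
        std_jx = (jx - jx.mean()) / sd if sd > 0 else np.zeros_like(jx)
        z[targets] += truth.direction_sign * truth.effect_size * std_jx
    fdr = np.clip(2.0 * stats.norm.sf(np.abs(z) / noise_sd), 1e-12, 1.0)
    return pd.DataFrame({"gene_id": gene_ids, "log2fc": z, "fdr": fdr})
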