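"""Synthetic screens with known ground truth.

The generator emulates the structure of a pooled phage-selection screen:
a random annotated genome, an RBS-panel guide library, log-normal
baseline guide abundances (oligo-pool and cloning skew), relative
enrichment of guides protecting against fit genes under selection (each
guide's true effect drawn around its gene's effect, capturing
guide-to-guide variability), negative-binomial sequencing noise at a
fixed read depth, and an MOI-0 (unselected baseline) vs MOI-10
(selected) sample layout with biological replicates.  Everything is
deterministic under a seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import revcomp
from .counting import CountMatrix, ExtractionParams
from .genome_io import GeneFeature, GenomeRecord

logger = logging.getLogger(__name__)

_STOPS = ("TAA", "TGA", "TAG")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror a transcriptome-wide phage screen: 200 genes with 7
    guides each, 15 truly fit genes (7.5%), per-guide protective effects
    of +4 log2 with 1 log2 of guide-to-guide spread, log-normal baseline
    abundances (sigma 1), negative-binomial counts (size 10) at 1e6 reads
    per sample and 3 biological replicates per condition.
    """

    n_genes: int = 200
    genome_length: int = 120_000
    fraction_fit_genes: float = 0.075
    guide_effect_mean: float = 4.0
    guide_effect_sd: float = 1.0
    abundance_sd: float = 1.0
    nb_dispersion: float | None = 10.0  # NB size parameter; None = Poisson
    reads_per_sample: int = 1_000_000
    n_replicates: int = 3
    moi_labels: tuple[str, str] = ("MOI0", "MOI10")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_fit_genes <= 1.0):
            raise ValueError("fraction_fit_genes must be in [0, 1]")
        for name in ("n_genes", "genome_length", "reads_per_sample", "n_replicates"):
            if getattr(self, name) <= 0 and not (name == "n_genes" and self.n_genes == 0):
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (or None for Poisson)")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually planted, for recovery scoring."""

    gene_fit: pd.Series          # bool per gene_id
    guide_enrichment: pd.Series  # true log2 enrichment per guide_id


def simulate_genome(
    n_genes: int,
    genome_length: int,
    seed: int = 0,
    min_intergenic: int = 60,
    gene_len_range: tuple[int, int] = (150, 600),
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Random linear genome with non-overlapping ATG-started CDSs.

    Genes land on both strands with at least ``min_intergenic`` nt between
    them (so every RBS window has upstream context).  Deterministic under
    ``seed``; raises when the genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=genome_length)
    features: list[GeneFeature] = []
    if n_genes:
        if genome_length < n_genes * 300:
            raise ValueError(
                f"genome_length {genome_length} too small to pack {n_genes} genes "
                "(need >= 300 nt per gene)"
            )
        lengths = []
        for _ in range(n_genes):
            L = int(rng.integers(gene_len_range[0] // 3, gene_len_range[1] // 3 + 1)) * 3
            lengths.append(L)
        needed = sum(lengths) + (n_genes + 1) * min_intergenic
        if needed > genome_length:
            raise ValueError(
                f"cannot pack {n_genes} genes ({needed} nt incl. spacing) into "
                f"{genome_length} nt"
            )
        slack = genome_length - needed
        gaps = rng.multinomial(slack, np.ones(n_genes + 1) / (n_genes + 1))
        pos = 0
        for i, L in enumerate(lengths):
            pos += min_intergenic + int(gaps[i])
            strand = "+" if rng.random() < 0.5 else "-"
            body = "".join(rng.choice(bases, size=L - 6))
            stop = _STOPS[int(rng.integers(3))]
            cds = "ATG" + body + stop
            insert = cds if strand == "+" else revcomp(cds)
            seq[pos:pos + L] = list(insert)
            features.append(GeneFeature(
                f"gene_{i + 1:03d}", pos, pos + L, strand,
                product=f"simulated protein {i + 1}",
            ))
            pos += L
    genome = GenomeRecord(f"sim_genome_{seed}", "".join(seq), "linear")
    return genome, features


def make_ground_truth(library: pd.DataFrame, config: SimConfig,
                      rng: np.random.Generator | None = None) -> GroundTruth:
    """Pick fit genes and draw per-guide true log2 enrichments.

    Fit genes share the configured mean effect; each of their guides
    draws its own effect Normal(mean, sd) in log2 units (log-normal
    guide-to-guide variability on the linear scale).  Guides of non-fit
    genes have enrichment exactly 0.
    """
    rng = rng or np.random.default_rng(config.seed)
    gene_ids = pd.Index(pd.unique(library["gene_id"]))
    n_fit = int(round(config.fraction_fit_genes * len(gene_ids)))
    fit_genes = set(rng.choice(gene_ids.to_numpy(), size=n_fit, replace=False)) if n_fit else set()
    gene_fit = pd.Series([g in fit_genes for g in gene_ids], index=gene_ids,
                         name="fit")
    enrich = np.zeros(len(library))
    is_fit_guide = library["gene_id"].isin(fit_genes).to_numpy()
    enrich[is_fit_guide] = rng.normal(config.guide_effect_mean,
                                      config.guide_effect_sd,
                                      size=int(is_fit_guide.sum()))
    guide_enrichment = pd.Series(enrich, index=pd.Index(library["guide_id"]),
                                 name="true_log2_enrichment")
    return GroundTruth(gene_fit, guide_enrichment)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float | None) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if dispersion is None or not math.isfinite(dispersion):
        return rng.poisson(mu)
    k = float(dispersion)
    p = k / (k + mu)
    return rng.negative_binomial(k, p)


def simulate_screen(
    library: pd.DataFrame,
    truth: GroundTruth | None,
    config: SimConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Baseline and selected count columns for every replicate.

    Baseline relative abundance of each guide is log-normal(0,
    ``abundance_sd``); under selection the expected abundance is scaled
    by ``2 ** true_enrichment`` and renormalized (survivor sampling, not
    mechanistic infection kinetics).  Counts per sample are negative
    binomial around the expected share of ``reads_per_sample``.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = make_ground_truth(library, config, rng)
    guide_ids = pd.Index(library["guide_id"], name="guide_id")
    n = len(guide_ids)
    abundance = rng.lognormal(0.0, config.abundance_sd, size=n)
    enrich = truth.guide_enrichment.reindex(guide_ids).to_numpy()
    selected = abundance * np.power(2.0, enrich)
    base_label, sel_label = config.moi_labels
    cols = {}
    meta_rows = []
    for cond, weights in ((base_label, abundance), (sel_label, selected)):
        share = weights / weights.sum()
        for r in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{r}"
            mu = share * config.reads_per_sample
            cols[sample] = _draw_counts(rng, mu, config.nb_dispersion)
            meta_rows.append((sample, cond, r, cond == base_label))
    counts = pd.DataFrame(cols, index=guide_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition",
                                            "replicate", "baseline"])
    meta = meta.set_index("sample_id")
    return CountMatrix(counts, meta), truth


def write_screen_fastq(
    counts: pd.Series,
    library: pd.DataFrame,
    path,
    params: ExtractionParams | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    paired: bool = False,
    path2=None,
    flank5: str = "CACCG",
    flank3: str = "CCGAA",
) -> None:
    """Write reads realizing a count column (amplicon = anchors + spacer).

    Each read is ``flank5 + upstream_anchor + spacer + downstream_anchor +
    flank3`` with independent per-base substitution errors at
    ``error_rate`` and Phred qualities consistent with that rate.  At
    ``error_rate=0`` counting the output recovers the generating counts
    exactly.  ``paired=True`` splits each amplicon into an overlapping
    mate pair (mate 2 reverse-complemented) written to ``path2``.
    """
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    params = params or ExtractionParams()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    q = 40 if error_rate == 0 else min(40, int(round(-10 * math.log10(error_rate))))
    spacers = dict(zip(library["guide_id"], library["spacer"]))
    reads: list[tuple[str, str]] = []
    for guide_id, n_reads in counts.items():
        if n_reads <= 0:
            continue
        amplicon = (flank5 + params.upstream_anchor + spacers[guide_id]
                    + params.downstream_anchor + flank3)
        arr = np.frombuffer(amplicon.encode("ascii"), dtype=np.uint8)
        for i in range(int(n_reads)):
            read = arr.copy()
            if error_rate > 0:
                hit = rng.random(len(read)) < error_rate
                if hit.any():
                    subs = rng.choice(bases, size=int(hit.sum()))
                    read[hit] = np.frombuffer("".join(subs).encode("ascii"),
                                              dtype=np.uint8)
            reads.append((f"{guide_id}:{i}", read.tobytes().decode("ascii")))
    order = rng.permutation(len(reads))
    qual_char = chr(q + 33)
    if not paired:
        with open(path, "w") as fh:
            for j in order:
                name, seq = reads[j]
                fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
        return
    if path2 is None:
        raise ValueError("paired output needs path2")
    read_len = max(45, len(reads[0][1]) * 2 // 3) if reads else 45
    with open(path, "w") as fh1, open(path2, "w") as fh2:
        for j in order:
            name, seq = reads[j]
            r1 = seq[:read_len]
            r2 = revcomp(seq[-read_len:])
            fh1.write(f"@{name}\n{r1}\n+\n{qual_char * len(r1)}\n")
            fh2.write(f"@{name}\n{r2}\n+\n{qual_char * len(r2)}\n")
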