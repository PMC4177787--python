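"""Synthetic prokaryote cohorts with GC-driven composition.

The generator produces genome fixtures — FASTA replicons, PTT gene
tables and a phylum metadata table — whose codon usage varies linearly
with genomic GC content, the structure the downstream analysis is built
to detect.  The model is deliberately minimal:

* **Independent positions.**  Each codon position draws its base
  independently with P(G) = P(C) = gc/2 and P(A) = P(T) = (1 - gc)/2,
  so every base frequency is an exactly linear function of GC (A and T
  decline with slope -1/2, G and C rise with slope +1/2).
* **Stop-codon removal.**  Genes must not contain internal stops, so
  each stop codon's probability (genetic code 11: TAA, TAG, TGA) is
  redistributed within its first-two-base codon family — TAA and TAG
  to TAT/TAC, TGA to TGT/TGC/TGG, proportionally to their base-model
  probabilities.  This keeps the position-1 and position-2 base
  marginals exact (A at position 1 stays (1-gc)/2, analytic slope
  -0.5 against GC) and perturbs the expected coding GC by less than
  0.004 across the 0.15-0.75 range.
* **Per-genome noise.**  Each genome's codon distribution is perturbed
  on the log scale (Gaussian, scale ``noise_sd``) and renormalised,
  giving genomes scatter around the GC-driven line.
* **Phylum labels.**  ``gc_correlated`` assigns phyla as contiguous
  blocks of the GC-sorted cohort (lineage and GC confounded);
  ``gc_uncorrelated`` assigns them round-robin so every phylum spans
  the full GC range — under this labelling only GC drives usage, so
  GC-bin sections must show smaller distance variances than phylum
  sections.

Genes are laid head-to-tail on a single replicon separated by short
GC-balanced random spacers, roughly half on the minus strand (stored
reverse-complemented in the replicon).  All gene lengths are multiples
of 3.  All randomness flows from one integer seed; identical specs
reproduce fixtures byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneAnnotation,
    GenomeRecord,
    reverse_complement,
    write_fasta,
    write_ptt,
)
from .usage_profiles import (
    CODON_GC_COUNT,
    CODONS,
    SENSE_MASK,
    STOP_CODONS,
    UsageProfile,
    _AA_MATRIX,
    _BASE_MATRIX,
)

__all__ = [
    "CohortSpec",
    "codon_distribution_for_gc",
    "perturb_distribution",
    "generate_genome",
    "write_genome",
    "generate_cohort",
    "simulate_profiles",
    "phylum_labels",
]

_CODON_ARRAY = np.array(CODONS)
_SPACER_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults describe the standard study cohort: 100 genomes on an even
    GC grid spanning 0.15-0.75 (the prokaryotic range), 500 genes of
    300 codons each, phyla uncorrelated with GC, mild per-genome noise.
    """

    n_genomes: int = 100
    gc_lo: float = 0.15
    gc_hi: float = 0.75
    gc_values: Sequence[float] | None = None
    genes_per_genome: int = 500
    gene_length_codons: int | tuple[int, int] = 300
    phylum_model: str = "gc_uncorrelated"
    n_phyla: int = 10
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gc_values is None:
            if self.n_genomes < 2:
                raise ValueError("n_genomes must be >= 2")
            if not (0 < self.gc_lo < self.gc_hi < 1):
                raise ValueError("need 0 < gc_lo < gc_hi < 1")
        else:
            self.gc_values = [float(g) for g in self.gc_values]
            self.n_genomes = len(self.gc_values)
            if self.n_genomes < 2:
                raise ValueError("need at least 2 gc values")
            if any(not 0 < g < 1 for g in self.gc_values):
                raise ValueError("gc values must lie in (0, 1)")
        min_len = (
            self.gene_length_codons
            if isinstance(self.gene_length_codons, int)
            else min(self.gene_length_codons)
        )
        if min_len < 2:
            raise ValueError("gene_length_codons must be >= 2")
        if self.genes_per_genome < 1:
            raise ValueError("genes_per_genome must be >= 1")
        if self.phylum_model not in {"gc_correlated", "gc_uncorrelated"}:
            raise ValueError(f"unknown phylum_model {self.phylum_model!r}")
        if self.n_phyla > self.n_genomes:
            raise ValueError("n_phyla cannot exceed n_genomes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resolved_gc(self) -> np.ndarray:
        if self.gc_values is not None:
            return np.asarray(self.gc_values, dtype=float)
        return np.linspace(self.gc_lo, self.gc_hi, self.n_genomes)

    def genome_ids(self) -> list[str]:
        width = len(str(self.n_genomes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genomes)]


# Stop families: each stop's probability moves to the sense codons
# sharing its first two bases, preserving position-1/2 marginals.
_STOP_FAMILIES: dict[int, list[int]] = {}
for _stop in sorted(STOP_CODONS):
    _members = [
        i for i, c in enumerate(CODONS)
        if c[:2] == _stop[:2] and c not in STOP_CODONS
    ]
    _STOP_FAMILIES[CODONS.index(_stop)] = _members


def codon_distribution_for_gc(
    target_gc: float, reassign_stops: bool = True
) -> np.ndarray:
    """64 codon probabilities for a target GC under the independent-position model.

    With ``reassign_stops`` (default) stop codons get probability zero,
    their mass redistributed within their first-two-base families; the
    vector always sums to 1.  Boundary GC values (0 or 1) degenerate to
    a two-letter alphabet and are rejected.
    """
    if not 0.0 < target_gc < 1.0:
        raise ValueError(f"target_gc must be strictly inside (0, 1), got {target_gc}")
    # Per-position base probabilities in codon-table order T, C, A, G.
    pb = np.array([
        (1 - target_gc) / 2, target_gc / 2, (1 - target_gc) / 2, target_gc / 2
    ])
    p = np.einsum("i,j,k->ijk", pb, pb, pb).ravel()
    if reassign_stops:
        raw = p.copy()
        for stop_idx, family in _STOP_FAMILIES.items():
            weights = raw[family] / raw[family].sum()
            p[family] += raw[stop_idx] * weights
            p[stop_idx] = 0.0
    return p / p.sum()


def perturb_distribution(
    p: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-scale Gaussian perturbation of a codon distribution.

    Nonzero entries get independent N(0, noise_sd) shifts on the log
    scale and are renormalised; zero entries (stops) stay zero.
    """
    if noise_sd == 0:
        return p.copy()
    q = np.zeros_like(p)
    nz = p > 0
    logq = np.log(p[nz]) + rng.normal(0.0, noise_sd, size=int(nz.sum()))
    logq -= logq.max()  # overflow guard
    w = np.exp(logq)
    q[nz] = w / w.sum()
    return q


def _gene_lengths(spec_len, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec_len, int):
        return np.full(n_genes, spec_len, dtype=int)
    lo, hi = spec_len
    return rng.integers(lo, hi + 1, size=n_genes)


def generate_genome(
    genome_id: str,
    target_gc: float,
    genes_per_genome: int = 500,
    gene_length_codons: int | tuple[int, int] = 300,
    noise_sd: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> GenomeRecord:
    """Sample one annotated genome.

    Genes are drawn codon-wise from the genome's perturbed codon
    distribution and placed head-to-tail on one replicon with random
    10-50 bp GC-balanced spacers; each gene lands on the minus strand
    with probability 1/2 (reverse-complemented in the replicon,
    annotated with strand ``-``).  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = perturb_distribution(
        codon_distribution_for_gc(target_gc), noise_sd, rng
    )
    lengths = _gene_lengths(gene_length_codons, genes_per_genome, rng)
    codon_idx = rng.choice(64, size=int(lengths.sum()), p=p)
    strands = np.where(rng.random(genes_per_genome) < 0.5, "-", "+")

    replicon_id = f"{genome_id}_chr"
    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 1  # next free 1-based position
    offset = 0
    for i in range(genes_per_genome):
        spacer_len = int(rng.integers(10, 51))
        spacer = rng.choice(_SPACER_BASES, size=spacer_len).tobytes().decode()
        parts.append(spacer)
        pos += spacer_len
        gene = "".join(_CODON_ARRAY[codon_idx[offset : offset + lengths[i]]])
        offset += lengths[i]
        start, end = pos, pos + len(gene) - 1
        parts.append(gene if strands[i] == "+" else reverse_complement(gene))
        pos = end + 1
        annotations.append(
            GeneAnnotation(
                replicon_id, start, end, str(strands[i]),
                f"{genome_id}_g{i + 1:04d}",
            )
        )
    tail_len = int(rng.integers(10, 51))
    parts.append(rng.choice(_SPACER_BASES, size=tail_len).tobytes().decode())
    return GenomeRecord(genome_id, [(replicon_id, "".join(parts))], annotations)


def write_genome(record: GenomeRecord, directory: str | Path) -> tuple[Path, Path]:
    """Write one genome as ``<id>.fna`` + ``<id>.ptt``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fna = directory / f"{record.genome_id}.fna"
    ptt = directory / f"{record.genome_id}.ptt"
    write_fasta(record.replicons, fna)
    replicon_id, seq = record.replicons[0]
    write_ptt(record.annotations, ptt, replicon_id, len(seq))
    return fna, ptt


def phylum_labels(
    genome_ids_gc_sorted: Sequence[str], model: str, n_phyla: int
) -> dict[str, str]:
    """Assign phylum names over a GC-sorted genome list.

    ``gc_correlated``: contiguous GC blocks (lineage tracks GC);
    ``gc_uncorrelated``: round-robin, each phylum spans the GC range.
    """
    n = len(genome_ids_gc_sorted)
    if n_phyla > n:
        raise ValueError("n_phyla cannot exceed the number of genomes")
    names = [f"Phylum{k + 1:02d}" for k in range(n_phyla)]
    labels: dict[str, str] = {}
    if model == "gc_uncorrelated":
        for i, gid in enumerate(genome_ids_gc_sorted):
            labels[gid] = names[i % n_phyla]
    elif model == "gc_correlated":
        for k, block in enumerate(np.array_split(np.arange(n), n_phyla)):
            for i in block:
                labels[genome_ids_gc_sorted[i]] = names[k]
    else:
        raise ValueError(f"unknown phylum model {model!r}")
    return labels


def _spawn_seeds(spec: CohortSpec) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(spec.seed).spawn(spec.n_genomes)


def _metadata(spec: CohortSpec) -> pd.DataFrame:
    gcs = spec.resolved_gc()
    ids = spec.genome_ids()
    order = np.lexsort((ids, gcs))  # GC ascending, id tie-break
    labels = phylum_labels(
        [ids[i] for i in order], spec.phylum_model, spec.n_phyla
    )
    return pd.DataFrame({
        "genome_id": ids,
        "gc_target": gcs,
        "phylum": [labels[g] for g in ids],
    })


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full fixture cohort: per-genome FASTA + PTT and metadata.tsv.

    Returns the metadata table (genome_id, gc_target, phylum), which is
    also written to ``<out_dir>/metadata.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metadata = _metadata(spec)
    for (gid, gc), seed in zip(
        zip(metadata["genome_id"], metadata["gc_target"]), _spawn_seeds(spec)
    ):
        record = generate_genome(
            gid, float(gc),
            genes_per_genome=spec.genes_per_genome,
            gene_length_codons=spec.gene_length_codons,
            noise_sd=spec.noise_sd,
            seed=seed,
        )
        write_genome(record, out_dir)
    metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return metadata


def simulate_profiles(
    spec: CohortSpec,
) -> tuple[list[UsageProfile], pd.DataFrame]:
    """Sample genome usage profiles directly, without building sequences.

    Statistically equivalent to generating sequence fixtures and running
    the profiling pipeline, minus the intergenic spacers: per-gene codon
    counts are multinomial draws from the genome's perturbed codon
    distribution, and the genome GC is the realised coding GC.  Useful
    for Monte-Carlo work where writing FASTA files would dominate the
    cost.  Returns (profiles, metadata).
    """
    metadata = _metadata(spec)
    profiles: list[UsageProfile] = []
    for (gid, gc), seed in zip(
        zip(metadata["genome_id"], metadata["gc_target"]), _spawn_seeds(spec)
    ):
        rng = np.random.default_rng(seed)
        p = perturb_distribution(
            codon_distribution_for_gc(float(gc)), spec.noise_sd, rng
        )
        lengths = _gene_lengths(
            spec.gene_length_codons, spec.genes_per_genome, rng
        )
        if np.ptp(lengths) == 0:
            counts = rng.multinomial(int(lengths[0]), p, size=spec.genes_per_genome)
        else:
            counts = np.vstack([rng.multinomial(int(n), p) for n in lengths])
        per_gene_n = counts.sum(axis=1, keepdims=True)
        codon_freqs = counts / per_gene_n
        base_freqs = codon_freqs @ _BASE_MATRIX.T
        sense = counts[:, SENSE_MASK].sum(axis=1, keepdims=True)
        aa_freqs = (counts @ _AA_MATRIX.T) / sense
        total = counts.sum(axis=0)
        realised_gc = float(total @ CODON_GC_COUNT) / (3.0 * total.sum())
        profiles.append(
            UsageProfile(
                genome_id=gid,
                gc=realised_gc,
                n_genes=spec.genes_per_genome,
                base_vec=base_freqs.mean(axis=0),
                codon_vec=codon_freqs.mean(axis=0),
                aa_vec=aa_freqs.mean(axis=0),
            )
        )
    return profiles, metadata
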