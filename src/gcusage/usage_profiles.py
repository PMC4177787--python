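"""Per-gene and genome-level composition vectors.

Three frequency vectors summarise each coding sequence:

* ``base_vec`` (12) — usage of A, T, C, G at codon positions 1, 2, 3.
  Each position block of four sums to 1.
* ``codon_vec`` (64) — frequencies of all 64 codons (stops included),
  in the classic codon-table order (TTT, TTC, … GGG).
* ``aa_vec`` (20) — frequencies of the 20 standard amino acids among
  *sense* codons (stops excluded from numerator and denominator),
  ordered alphabetically by three-letter code.

Translation uses the bacterial/archaeal genetic code (NCBI table 11);
initiator codons are translated literally (no forced Met for GTG/TTG
starts) and TGA/TAG are always stops (no selenocysteine/pyrrolysine
recoding).

The genome-level profile is the **unweighted arithmetic mean** of the
per-gene vectors — every gene counts equally regardless of its length.
This differs from pooling codon counts over the concatenated genes
whenever gene lengths differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .genome_io import CodingSequence, GenomeRecord, extract_cds, genomic_gc

logger = logging.getLogger(__name__)

__all__ = [
    "BASES",
    "CODONS",
    "STOP_CODONS",
    "AA3",
    "AA1",
    "BASE_FEATURES",
    "FEATURE_NAMES",
    "GeneUsage",
    "UsageProfile",
    "codon_counts",
    "gene_base_position_freqs",
    "gene_codon_freqs",
    "gene_amino_acid_freqs",
    "gene_usage",
    "genome_profile",
    "profile_genome",
    "validate_simplex",
    "validate_base_vec",
    "profiles_to_long",
    "write_profiles",
]

# Codon-table base order; defines the lexicographic codon indexing.
BASES = "TCAG"
CODONS: list[str] = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# Base order within each position block of the 12-dim vector.
BASE_ORDER = "ATCG"
BASE_FEATURES: list[str] = [f"{b}{p}" for p in (1, 2, 3) for b in BASE_ORDER]

# 20 standard residues, alphabetical by three-letter code.
AA3: list[str] = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]
AA1 = "ARNDCQEGHILKMFPSTWYV"

FEATURE_NAMES = {
    "gc": ["gc"],
    "base": BASE_FEATURES,
    "codon": CODONS,
    "amino_acid": AA3,
}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

# 12 x 64 marginalisation matrix: row 4*(p-1)+b picks codons with base
# BASE_ORDER[b] at position p.
_BASE_MATRIX = np.zeros((12, 64))
for _ci, _codon in enumerate(CODONS):
    for _p in range(3):
        _BASE_MATRIX[4 * _p + BASE_ORDER.index(_codon[_p]), _ci] = 1.0

# 20 x 64 translation matrix (stop columns all zero) and stop mask.
_AA_MATRIX = np.zeros((20, 64))
STOP_MASK = np.zeros(64, dtype=bool)
for _ci, _codon in enumerate(CODONS):
    if _codon in STOP_CODONS:
        STOP_MASK[_ci] = True
    else:
        _AA_MATRIX[AA1.index(_TABLE11.forward_table[_codon]), _ci] = 1.0

SENSE_MASK = ~STOP_MASK

# Number of G/C bases in each codon (for expected-GC computations).
CODON_GC_COUNT = np.array([c.count("G") + c.count("C") for c in CODONS], float)

_CODON_LUT = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(BASES):
    _CODON_LUT[ord(_b)] = _i


def _sequence_of(cds: CodingSequence | str) -> str:
    return cds.sequence if isinstance(cds, CodingSequence) else cds


def codon_counts(cds: CodingSequence | str) -> np.ndarray:
    """Integer counts of the 64 codons in a CDS.

    Requires a non-empty ACGT-only sequence whose length is a multiple
    of 3.
    """
    seq = _sequence_of(cds)
    if not seq:
        raise ValueError("empty coding sequence")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    arr = _CODON_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("CDS contains characters other than A, C, G, T")
    idx = arr[0::3] * 16 + arr[1::3] * 4 + arr[2::3]
    return np.bincount(idx, minlength=64)


def gene_base_position_freqs(cds: CodingSequence | str) -> np.ndarray:
    """12 base frequencies: A,T,C,G at codon positions 1, 2, 3.

    Entry ``4*(p-1)+b`` is the fraction of codons carrying base ``b``
    at position ``p``; each position block sums to 1.  All codons,
    including stops, are counted.
    """
    counts = codon_counts(cds)
    return (_BASE_MATRIX @ counts) / counts.sum()


def gene_codon_freqs(cds: CodingSequence | str) -> np.ndarray:
    """64 codon frequencies (stop codons carried; vector sums to 1)."""
    counts = codon_counts(cds)
    return counts / counts.sum()


def gene_amino_acid_freqs(cds: CodingSequence | str) -> np.ndarray:
    """20 amino-acid frequencies among sense codons (genetic code 11).

    Stop codons are excluded from numerator and denominator; a gene
    consisting solely of stop codons raises ``ValueError``.
    """
    counts = codon_counts(cds)
    n_sense = counts[SENSE_MASK].sum()
    if n_sense == 0:
        raise ValueError("gene has no sense codons (all stops)")
    return (_AA_MATRIX @ counts) / n_sense


@dataclass(frozen=True)
class GeneUsage:
    """The three composition vectors of one gene."""

    gene_id: str
    base_vec: np.ndarray
    codon_vec: np.ndarray
    aa_vec: np.ndarray


@dataclass
class UsageProfile:
    """Genome-level composition: GC content plus mean usage vectors.

    ``n_genes`` is ``None`` for profiles ingested from precomputed
    tables, where the gene count is unknown.
    """

    genome_id: str
    gc: float
    n_genes: int | None
    base_vec: np.ndarray
    codon_vec: np.ndarray
    aa_vec: np.ndarray

    def __post_init__(self) -> None:
        self.base_vec = np.asarray(self.base_vec, dtype=float)
        self.codon_vec = np.asarray(self.codon_vec, dtype=float)
        self.aa_vec = np.asarray(self.aa_vec, dtype=float)
        if self.base_vec.shape != (12,):
            raise ValueError("base_vec must have 12 entries")
        if self.codon_vec.shape != (64,):
            raise ValueError("codon_vec must have 64 entries")
        if self.aa_vec.shape != (20,):
            raise ValueError("aa_vec must have 20 entries")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc {self.gc} outside [0, 1]")
        if self.n_genes is not None and self.n_genes < 1:
            raise ValueError("n_genes must be >= 1 when known")


def gene_usage(cds: CodingSequence | str, gene_id: str | None = None) -> GeneUsage:
    """All three usage vectors of one gene, computed from one codon count."""
    counts = codon_counts(cds)
    n = counts.sum()
    n_sense = counts[SENSE_MASK].sum()
    if n_sense == 0:
        raise ValueError("gene has no sense codons (all stops)")
    if gene_id is None:
        gene_id = cds.gene_id if isinstance(cds, CodingSequence) else ""
    return GeneUsage(
        gene_id=gene_id,
        base_vec=(_BASE_MATRIX @ counts) / n,
        codon_vec=counts / n,
        aa_vec=(_AA_MATRIX @ counts) / n_sense,
    )


def genome_profile(
    genome_id: str, gc: float, genes: Sequence[GeneUsage]
) -> UsageProfile:
    """Unweighted per-gene mean of usage vectors.

    Every gene contributes equally to the mean irrespective of its
    length; this is *not* the pooled-codon-count frequency unless all
    genes have the same length.
    """
    if len(genes) == 0:
        raise ValueError(f"genome {genome_id!r}: no genes to average")
    return UsageProfile(
        genome_id=genome_id,
        gc=gc,
        n_genes=len(genes),
        base_vec=np.mean([g.base_vec for g in genes], axis=0),
        codon_vec=np.mean([g.codon_vec for g in genes], axis=0),
        aa_vec=np.mean([g.aa_vec for g in genes], axis=0),
    )


def profile_genome(genome: GenomeRecord) -> UsageProfile:
    """End-to-end profile of one genome record.

    Extracts coding sequences (dropping genes whose length is not a
    multiple of 3), additionally drops genes containing non-ACGT
    characters or only stop codons from the usage statistics (their
    replicons still contribute to genomic GC), and averages the
    remaining genes.
    """
    gc = genomic_gc(genome)
    usages: list[GeneUsage] = []
    n_ambiguous = 0
    for cds in extract_cds(genome):
        try:
            usages.append(gene_usage(cds))
        except ValueError:
            n_ambiguous += 1
    if n_ambiguous:
        logger.info(
            "genome %s: %d genes dropped from usage (ambiguous bases or all-stop)",
            genome.genome_id, n_ambiguous,
        )
    if not usages:
        raise ValueError(f"genome {genome.genome_id!r}: no usable genes")
    return genome_profile(genome.genome_id, gc, usages)


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------

def validate_simplex(vec: np.ndarray, atol: float = 1e-9, context: str = "") -> None:
    """Check a frequency vector: entries in [0,1], sum 1 within ``atol``."""
    vec = np.asarray(vec, dtype=float)
    prefix = f"{context}: " if context else ""
    if (vec < -atol).any() or (vec > 1 + atol).any():
        raise ValueError(f"{prefix}frequency outside [0, 1]")
    total = vec.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"{prefix}frequencies sum to {total}, expected 1")


def validate_base_vec(vec: np.ndarray, atol: float = 1e-9, context: str = "") -> None:
    """Check a 12-dim base vector: each position block of 4 sums to 1."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (12,):
        raise ValueError(f"{context}: base vector must have 12 entries")
    for p in range(3):
        validate_simplex(
            vec[4 * p : 4 * p + 4], atol=atol,
            context=f"{context} position {p + 1}".strip(),
        )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def profiles_to_long(profiles: Iterable[UsageProfile]):
    """Long-format table: one row per (genome, usage kind, feature)."""
    import pandas as pd

    rows = []
    for p in profiles:
        rows.append((p.genome_id, "gc", "gc", p.gc))
        for kind, vec in (
            ("base", p.base_vec), ("codon", p.codon_vec), ("amino_acid", p.aa_vec)
        ):
            for name, value in zip(FEATURE_NAMES[kind], vec):
                rows.append((p.genome_id, kind, name, value))
    return pd.DataFrame(rows, columns=["genome_id", "usage_kind", "feature", "value"])


def write_profiles(profiles: Sequence[UsageProfile], directory) -> None:
    """Write per-layout genome tables (gc/base/codon/amino_acid .tsv).

    Round-trip compatible with :func:`gcusage.genome_io.load_profile_dir`.
    """
    from pathlib import Path

    from .genome_io import write_profile_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_profile_table(
        {p.genome_id: p.gc for p in profiles}, "gc", directory / "gc.tsv"
    )
    write_profile_table(
        {p.genome_id: p.base_vec for p in profiles}, "base", directory / "base.tsv"
    )
    write_profile_table(
        {p.genome_id: p.codon_vec for p in profiles}, "codon", directory / "codon.tsv"
    )
    write_profile_table(
        {p.genome_id: p.aa_vec for p in profiles},
        "amino_acid", directory / "amino_acid.tsv",
    )
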