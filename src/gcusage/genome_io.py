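"""Genome sequence and annotation input/output.

Readers for genome FASTA files (NCBI ``.fna`` convention) and NCBI PTT
protein-table annotations, strand-correct extraction of protein-coding
sequences, genomic GC content, and ingestion of precomputed genome-level
usage-frequency tables (one genome per row, one frequency per column, in
either delimited-text or spreadsheet form).

Coordinates follow the PTT convention end-to-end: 1-based, inclusive on
both ends.  A :class:`GenomeRecord` holds every replicon of one organism
(chromosome plus plasmids) so that GC content and usage statistics are
genome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "UndefinedGCError",
    "GeneAnnotation",
    "GenomeRecord",
    "CodingSequence",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_ptt",
    "write_ptt",
    "extract_cds",
    "genomic_gc",
    "genomic_at",
    "gc_base_counts",
    "read_profile_table",
    "write_profile_table",
    "load_profile_dir",
    "read_genome_dir",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. frequency outside [0,1])."""


class UndefinedGCError(ValueError):
    """GC content requested for a sequence with no unambiguous bases."""


# Complement map covering the IUPAC nucleotide ambiguity alphabet.
_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)

_VALID_BASES = frozenset("ACGTURYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC letters allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One CDS location: 1-based inclusive ``start..end`` on ``strand``."""

    replicon_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    gene_id: str


@dataclass
class GenomeRecord:
    """All replicons of one genome plus its gene annotations.

    Sequences are normalised to uppercase on construction and replicon
    identifiers must be unique within the genome.
    """

    genome_id: str
    replicons: list[tuple[str, str]]
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.replicons = [(rid, seq.upper()) for rid, seq in self.replicons]
        ids = [rid for rid, _ in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"duplicate replicon ids in genome {self.genome_id!r}"
            )
        for rid, seq in self.replicons:
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValidationError(
                    f"replicon {rid!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @property
    def replicon_map(self) -> dict[str, str]:
        return dict(self.replicons)


@dataclass(frozen=True)
class CodingSequence:
    """A coding-strand CDS (5'→3' of the protein)."""

    gene_id: str
    sequence: str


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(replicon_id, SEQUENCE), ...]``.

    The replicon id is the header token before the first whitespace;
    sequences are uppercased.  Raises :class:`FormatError` (naming the
    offending line) for an empty file or a malformed first header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {stripped[:30]!r}"
                )
            if not stripped[1:].split():
                raise FormatError(f"{path}: line {lineno}: empty FASTA header")
            break
        else:
            raise FormatError(f"{path}: line 1: empty FASTA file")

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise FormatError(f"{path}: line 1: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``[(id, sequence), ...]`` as FASTA (wrapped at 70 columns)."""
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seqrecords, Path(path), "fasta")


# ---------------------------------------------------------------------------
# PTT annotation tables
# ---------------------------------------------------------------------------

def read_ptt(path: str | Path, replicon_id: str) -> list[GeneAnnotation]:
    """Parse an NCBI PTT protein table for one replicon.

    Up to three leading header/label lines are tolerated (title, protein
    count, column-name row).  Data rows are tab-separated with the first
    column ``start..end`` (1-based inclusive) and the second the strand.
    Rows with ``end < start`` are skipped with a logged warning;
    non-integer coordinates raise :class:`FormatError`.

    The gene identifier is taken from the Synonym column (6th) when
    present, else the PID column (4th), else synthesised from the row
    number.
    """
    path = Path(path)
    annotations: list[GeneAnnotation] = []
    n_skipped = 0
    header_budget = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            is_data_like = "\t" in line and ".." in fields[0]
            if not is_data_like:
                if header_budget > 0:
                    header_budget -= 1
                    continue
                raise FormatError(
                    f"{path}: line {lineno}: expected 'start..end<TAB>strand' row"
                )
            header_budget = 0
            lo, _, hi = fields[0].strip().partition("..")
            try:
                start, end = int(lo), int(hi)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates {fields[0]!r}"
                ) from None
            strand = fields[1].strip() if len(fields) > 1 else "+"
            if strand not in {"+", "-"}:
                raise FormatError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            if end < start:
                n_skipped += 1
                logger.warning(
                    "%s: line %d: end < start (%d..%d), row skipped",
                    path, lineno, start, end,
                )
                continue
            gene_id = ""
            if len(fields) > 5 and fields[5].strip() not in {"", "-"}:
                gene_id = fields[5].strip()
            elif len(fields) > 3 and fields[3].strip() not in {"", "-"}:
                gene_id = fields[3].strip()
            else:
                gene_id = f"{replicon_id}_row{lineno}"
            annotations.append(
                GeneAnnotation(replicon_id, start, end, strand, gene_id)
            )
    if n_skipped:
        logger.warning("%s: %d rows skipped (end < start)", path, n_skipped)
    return annotations


_PTT_COLUMNS = "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct"


def write_ptt(
    annotations: list[GeneAnnotation],
    path: str | Path,
    replicon_id: str,
    replicon_length: int,
    title: str | None = None,
) -> None:
    """Write annotations in the NCBI PTT dialect read by :func:`read_ptt`."""
    lines = [
        title or f"{replicon_id} - 1..{replicon_length}",
        f"{len(annotations)} proteins",
        _PTT_COLUMNS,
    ]
    for i, ann in enumerate(annotations, start=1):
        aa_len = max((ann.end - ann.start + 1) // 3 - 1, 0)
        lines.append(
            f"{ann.start}..{ann.end}\t{ann.strand}\t{aa_len}\t{i}\t-\t"
            f"{ann.gene_id}\t-\t-\thypothetical protein"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

def extract_cds(genome: GenomeRecord) -> list[CodingSequence]:
    """Extract strand-correct coding sequences from a genome.

    Plus-strand genes are the ``[start, end]`` substring; minus-strand
    genes are its reverse complement.  Genes whose length is not a
    multiple of 3 are excluded (and counted in the log), as are genes
    running off the end of their replicon or spanning the origin
    (``start > end`` in PTT terms).  Output order follows annotation
    order.
    """
    seqs = genome.replicon_map
    out: list[CodingSequence] = []
    n_not_triplet = n_out_of_range = n_origin = n_missing = 0
    for ann in genome.annotations:
        seq = seqs.get(ann.replicon_id)
        if seq is None:
            n_missing += 1
            logger.warning(
                "genome %s: gene %s references unknown replicon %s",
                genome.genome_id, ann.gene_id, ann.replicon_id,
            )
            continue
        if ann.start > ann.end:
            n_origin += 1
            continue
        if ann.start < 1 or ann.end > len(seq):
            n_out_of_range += 1
            logger.warning(
                "genome %s: gene %s (%d..%d) outside replicon of length %d",
                genome.genome_id, ann.gene_id, ann.start, ann.end, len(seq),
            )
            continue
        sub = seq[ann.start - 1 : ann.end]
        if len(sub) % 3 != 0:
            n_not_triplet += 1
            continue
        if ann.strand == "-":
            sub = reverse_complement(sub)
        out.append(CodingSequence(ann.gene_id, sub))
    if n_not_triplet or n_out_of_range or n_origin or n_missing:
        logger.info(
            "genome %s: excluded genes — %d length not multiple of 3, "
            "%d out of range, %d origin-spanning, %d missing replicon",
            genome.genome_id, n_not_triplet, n_out_of_range, n_origin, n_missing,
        )
    return out


# ---------------------------------------------------------------------------
# Genomic GC content
# ---------------------------------------------------------------------------

def gc_base_counts(genome: GenomeRecord | str) -> tuple[int, int]:
    """``(G+C count, A+C+G+T count)`` over all replicons, ambiguity excluded."""
    if isinstance(genome, GenomeRecord):
        seqs = [seq for _, seq in genome.replicons]
    else:
        seqs = [genome.upper()]
    gc = total = 0
    for seq in seqs:
        g = seq.count("G") + seq.count("C")
        gc += g
        total += g + seq.count("A") + seq.count("T")
    return gc, total


def genomic_gc(genome: GenomeRecord | str) -> float:
    """Fraction of G+C among unambiguous bases of the whole genome.

    Ambiguity letters (N etc.) are excluded from both numerator and
    denominator; a genome with no unambiguous base raises
    :class:`UndefinedGCError`.
    """
    gc, total = gc_base_counts(genome)
    if total == 0:
        raise UndefinedGCError("no unambiguous (A/C/G/T) bases in genome")
    return gc / total


def genomic_at(genome: GenomeRecord | str) -> float:
    """Fraction of A+T among unambiguous bases (complement of GC)."""
    gc, total = gc_base_counts(genome)
    if total == 0:
        raise UndefinedGCError("no unambiguous (A/C/G/T) bases in genome")
    return (total - gc) / total


# ---------------------------------------------------------------------------
# Precomputed genome-level usage tables
# ---------------------------------------------------------------------------

LAYOUT_DIMS = {"gc": 1, "base": 12, "codon": 64, "amino_acid": 20}


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xls", ".xlsx"}:
        return pd.read_excel(path)
    return pd.read_csv(path, sep=None, engine="python")


def read_profile_table(
    path: str | Path, layout: str, atol: float = 1e-3
) -> dict[str, float | np.ndarray]:
    """Read a genome-level frequency table into ``{genome_id: vector}``.

    ``layout`` selects the expected width: ``gc`` (1 value), ``base``
    (12: A,T,C,G at codon positions 1–3), ``codon`` (64, codon-table
    order TTT..GGG), ``amino_acid`` (20, alphabetical by three-letter
    code).  The first column is the genome id.  Normalisation invariants
    are checked to ``atol`` (loose by default to tolerate rounding in
    published tables); frequencies outside [0, 1] raise
    :class:`ValidationError`, layout/width mismatches and duplicate ids
    raise :class:`FormatError`.

    For ``layout='gc'`` values are floats; otherwise 1-D numpy arrays.
    """
    if layout not in LAYOUT_DIMS:
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    df = _read_table(path)
    dim = LAYOUT_DIMS[layout]
    if df.shape[1] != dim + 1:
        raise FormatError(
            f"{path}: layout {layout!r} expects {dim + 1} columns "
            f"(genome_id + {dim}), found {df.shape[1]}"
        )
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise FormatError(f"{path}: duplicate genome ids {dups}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError(f"{path}: non-numeric or missing frequencies")
    if (values < 0).any() or (values > 1).any():
        raise ValidationError(f"{path}: frequency outside [0, 1]")

    from . import usage_profiles  # deferred: usage_profiles imports this module

    out: dict[str, float | np.ndarray] = {}
    for gid, row in zip(ids, values):
        if layout == "gc":
            out[gid] = float(row[0])
            continue
        if layout == "base":
            usage_profiles.validate_base_vec(row, atol=atol, context=gid)
        else:
            usage_profiles.validate_simplex(row, atol=atol, context=gid)
        out[gid] = row
    return out


def write_profile_table(
    records: dict[str, float | np.ndarray], layout: str, path: str | Path
) -> None:
    """Write ``{genome_id: vector}`` in the layout read by :func:`read_profile_table`.

    Delimited text (``.tsv``/``.csv``) or spreadsheet (``.xlsx``) is
    chosen from the file suffix.
    """
    from . import usage_profiles

    if layout not in LAYOUT_DIMS:
        raise ValueError(f"unknown layout {layout!r}")
    columns = usage_profiles.FEATURE_NAMES[layout]
    rows = []
    for gid, vec in records.items():
        vals = [vec] if layout == "gc" else list(np.asarray(vec, dtype=float))
        rows.append([gid, *vals])
    df = pd.DataFrame(rows, columns=["genome_id", *columns])
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    elif path.suffix.lower() == ".csv":
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def load_profile_dir(directory: str | Path, atol: float = 1e-3) -> list:
    """Assemble :class:`~gcusage.usage_profiles.UsageProfile` objects from a
    directory of per-layout tables.

    Expects files named ``gc``, ``base``, ``codon``, ``amino_acid`` with
    suffix ``.tsv``, ``.csv``, ``.xlsx`` or ``.xls``.  Only genomes
    present in all four tables are returned (missing ids are logged).
    """
    from .usage_profiles import UsageProfile

    directory = Path(directory)
    tables: dict[str, dict[str, float | np.ndarray]] = {}
    for layout in LAYOUT_DIMS:
        for suffix in (".tsv", ".csv", ".xlsx", ".xls"):
            candidate = directory / f"{layout}{suffix}"
            if candidate.exists():
                tables[layout] = read_profile_table(candidate, layout, atol=atol)
                break
        else:
            raise FileNotFoundError(
                f"no {layout} table (gc/base/codon/amino_acid .tsv/.csv/.xlsx) "
                f"in {directory}"
            )
    common = set(tables["gc"])
    for layout in ("base", "codon", "amino_acid"):
        common &= set(tables[layout])
    dropped = set().union(*(set(t) for t in tables.values())) - common
    if dropped:
        logger.warning(
            "%d genomes missing from at least one table, dropped: %s",
            len(dropped), sorted(dropped)[:5],
        )
    profiles = [
        UsageProfile(
            genome_id=gid,
            gc=float(tables["gc"][gid]),
            n_genes=None,
            base_vec=np.asarray(tables["base"][gid], dtype=float),
            codon_vec=np.asarray(tables["codon"][gid], dtype=float),
            aa_vec=np.asarray(tables["amino_acid"][gid], dtype=float),
        )
        for gid in sorted(common)
    ]
    return profiles


def read_genome_dir(directory: str | Path) -> list[GenomeRecord]:
    """Read every ``<genome>.fna`` (+ matching ``<genome>.ptt``) in a directory.

    Each FASTA file is one genome; all its records are that genome's
    replicons.  A single ``<genome>.ptt`` is applied to the first
    replicon (the layout emitted by the cohort simulator); genomes
    without a PTT get no annotations.
    """
    directory = Path(directory)
    genomes: list[GenomeRecord] = []
    for fna in sorted(directory.glob("*.fna")):
        replicons = read_fasta(fna)
        ptt = fna.with_suffix(".ptt")
        annotations: list[GeneAnnotation] = []
        if ptt.exists():
            annotations = read_ptt(ptt, replicon_id=replicons[0][0])
        else:
            logger.warning("no PTT annotation for %s", fna.name)
        genomes.append(GenomeRecord(fna.stem, replicons, annotations))
    if not genomes:
        raise FileNotFoundError(f"no .fna genome files in {directory}")
    return genomes
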