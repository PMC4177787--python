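"""Euclidean distances between genome usage vectors.

The distance between two genomes for a usage kind is the Euclidean norm
of the difference of their genome-mean vectors.  All-vs-all tables are
stored condensed (upper triangle, :mod:`scipy.spatial.distance`
``pdist`` ordering) over the genome list sorted by ascending GC content
(ties broken lexicographically by genome id), the ordering used for the
GC-sorted heat maps.

For probability vectors the distances are bounded: codon and amino-acid
distances by sqrt(2) (two disjoint simplex vertices) and the base
distance by sqrt(6) (three independent position simplices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .usage_profiles import UsageProfile

__all__ = [
    "USAGE_KINDS",
    "DistanceTable",
    "usage_distance",
    "gc_difference",
    "sort_by_gc",
    "pairwise_distances",
    "pair_table",
    "condensed_gc_diffs",
]

USAGE_KINDS = ("base", "codon", "amino_acid")

_VEC_ATTR = {"base": "base_vec", "codon": "codon_vec", "amino_acid": "aa_vec"}


def _vector(profile: UsageProfile, usage_kind: str) -> np.ndarray:
    try:
        return getattr(profile, _VEC_ATTR[usage_kind])
    except KeyError:
        raise ValueError(
            f"unknown usage kind {usage_kind!r}; expected one of {USAGE_KINDS}"
        ) from None


@dataclass
class DistanceTable:
    """Condensed all-vs-all distances over a GC-sorted genome list.

    ``distances[k]`` is the distance between genomes ``i < j`` in pdist
    order; length is M(M-1)/2.
    """

    genome_ids: list[str]
    usage_kind: str
    distances: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.genome_ids)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (m * (m - 1) // 2,):
            raise ValueError(
                f"condensed length {self.distances.size} does not match "
                f"{m} genomes (expected {m * (m - 1) // 2})"
            )
        if (self.distances < 0).any():
            raise ValueError("negative distance")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def square(self) -> pd.DataFrame:
        """Symmetric square matrix with genome ids as index/columns."""
        return pd.DataFrame(
            squareform(self.distances),
            index=self.genome_ids, columns=self.genome_ids,
        )


def usage_distance(
    p_i: UsageProfile, p_j: UsageProfile, usage_kind: str
) -> float:
    """Euclidean distance between two genomes' mean usage vectors."""
    vi, vj = _vector(p_i, usage_kind), _vector(p_j, usage_kind)
    if vi.shape != vj.shape:
        raise ValueError(f"dimension mismatch: {vi.shape} vs {vj.shape}")
    return float(np.linalg.norm(vi - vj))


def gc_difference(p_i, p_j) -> float:
    """Absolute difference of genomic GC contents.

    Accepts :class:`UsageProfile` objects or bare GC fractions.
    """
    gi = p_i.gc if isinstance(p_i, UsageProfile) else float(p_i)
    gj = p_j.gc if isinstance(p_j, UsageProfile) else float(p_j)
    return abs(gi - gj)


def sort_by_gc(profiles: Sequence[UsageProfile]) -> list[UsageProfile]:
    """GC-ascending order, ties broken by genome id (the heat-map order)."""
    return sorted(profiles, key=lambda p: (p.gc, p.genome_id))


def pairwise_distances(
    profiles: Sequence[UsageProfile], usage_kind: str
) -> DistanceTable:
    """All-vs-all Euclidean distances for one usage kind.

    Profiles are sorted by GC (ascending, id tie-break) first, so the
    result is invariant under permutation of the input.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for pairwise distances")
    ordered = sort_by_gc(profiles)
    matrix = np.vstack([_vector(p, usage_kind) for p in ordered])
    return DistanceTable(
        genome_ids=[p.genome_id for p in ordered],
        usage_kind=usage_kind,
        distances=pdist(matrix, metric="euclidean"),
    )


def condensed_gc_diffs(profiles: Sequence[UsageProfile]) -> np.ndarray:
    """Condensed |GC_i - GC_j| in the same pair order as the distance tables."""
    ordered = sort_by_gc(profiles)
    gcs = np.array([[p.gc] for p in ordered])
    return pdist(gcs, metric="euclidean")


def pair_table(profiles: Sequence[UsageProfile]) -> pd.DataFrame:
    """Long-format pair export: ids, GC difference and the three distances."""
    ordered = sort_by_gc(profiles)
    ids = [p.genome_id for p in ordered]
    m = len(ids)
    ii, jj = np.triu_indices(m, k=1)
    frame = pd.DataFrame({
        "genome_i": [ids[i] for i in ii],
        "genome_j": [ids[j] for j in jj],
        "gc_diff": condensed_gc_diffs(ordered),
    })
    for kind in USAGE_KINDS:
        frame[f"{kind}_dist"] = pairwise_distances(ordered, kind).distances
    return frame
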