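"""Simple least-squares fits with SSE and R².

Two families of fits drive the analysis:

* usage distance vs. GC-content difference, over all M(M-1)/2 genome
  pairs (pairs sharing a genome are statistically dependent; following
  the original analysis no clustering correction is applied, so the
  fits are descriptive, not inferential — no p-values are reported);
* a single feature's genome-mean frequency (e.g. A at codon position 1,
  codon AAA, or Lys) vs. genomic GC content, one point per genome.

R² is computed as 1 - SSE/SST, which for ordinary least squares with an
intercept lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance_metrics import (
    USAGE_KINDS,
    condensed_gc_diffs,
    pairwise_distances,
)
from .usage_profiles import (
    AA1,
    AA3,
    BASE_FEATURES,
    CODONS,
    UsageProfile,
)

__all__ = [
    "DegenerateFitError",
    "RegressionFit",
    "BinSummary",
    "fit_simple_linear",
    "distance_vs_gcdiff_fit",
    "feature_vs_gc_fit",
    "resolve_feature",
    "binned_point_summary",
    "fits_to_table",
]


class DegenerateFitError(ValueError):
    """The regression problem has no unique OLS solution (constant x)."""


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line y = intercept + slope * x."""

    slope: float
    intercept: float
    sse: float
    r_square: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_simple_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Fit y = intercept + slope*x by ordinary least squares.

    Requires at least 3 points and non-constant x.  SSE is the sum of
    squared residuals; R² = 1 - SSE/SST, clipped into [0, 1] against
    floating-point round-off.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant; slope is undefined")
    result = stats.linregress(x, y)
    residuals = y - (result.intercept + result.slope * x)
    sse = float(residuals @ residuals)
    sst = float(((y - y.mean()) ** 2).sum())
    r_square = 0.0 if sst == 0 else 1.0 - sse / sst
    return RegressionFit(
        slope=float(result.slope),
        intercept=float(result.intercept),
        sse=sse,
        r_square=float(min(max(r_square, 0.0), 1.0)),
        n_points=int(x.size),
    )


def distance_vs_gcdiff_fit(
    profiles: Sequence[UsageProfile], usage_kind: str
) -> RegressionFit:
    """OLS of usage distance on GC difference over all unordered pairs."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 genomes")
    x = condensed_gc_diffs(profiles)
    y = pairwise_distances(profiles, usage_kind).distances
    return fit_simple_linear(x, y)


def resolve_feature(feature: str) -> tuple[str, int]:
    """Map a feature id to ``(usage_kind, vector_index)``.

    Accepts base ids ``A1``..``G3``, the 64 codons, and amino acids by
    three-letter (``Lys``) or one-letter (``K``) code.
    """
    if feature in BASE_FEATURES:
        return "base", BASE_FEATURES.index(feature)
    upper = feature.upper()
    if upper in CODONS:
        return "codon", CODONS.index(upper)
    title = feature.capitalize()
    if title in AA3:
        return "amino_acid", AA3.index(title)
    if len(feature) == 1 and upper in AA1:
        return "amino_acid", AA1.index(upper)
    raise ValueError(f"unknown feature id {feature!r}")


def feature_vs_gc_fit(
    profiles: Sequence[UsageProfile], feature: str
) -> RegressionFit:
    """OLS of one genome-mean frequency on genomic GC, one point per genome."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 genomes")
    kind, index = resolve_feature(feature)
    attr = {"base": "base_vec", "codon": "codon_vec", "amino_acid": "aa_vec"}[kind]
    x = np.array([p.gc for p in profiles])
    y = np.array([getattr(p, attr)[index] for p in profiles])
    return fit_simple_linear(x, y)


class BinSummary(NamedTuple):
    """Pairs falling in one half-open GC-difference bin [lo, hi)."""

    count: int
    min_distance: float | None
    max_distance: float | None


def binned_point_summary(
    pairs: pd.DataFrame, bin_lo: float, bin_hi: float, usage_kind: str
) -> BinSummary:
    """Count pairs with gc_diff in [bin_lo, bin_hi) and their distance range.

    ``pairs`` is the long-format table from
    :func:`gcusage.distance_metrics.pair_table` (columns ``gc_diff`` and
    ``<kind>_dist``).  An empty bin reports count 0 with an undefined
    (None) range.
    """
    if not bin_lo < bin_hi:
        raise ValueError(f"bin_lo {bin_lo} must be < bin_hi {bin_hi}")
    if usage_kind not in USAGE_KINDS:
        raise ValueError(f"unknown usage kind {usage_kind!r}")
    mask = (pairs["gc_diff"] >= bin_lo) & (pairs["gc_diff"] < bin_hi)
    selected = pairs.loc[mask, f"{usage_kind}_dist"]
    if selected.empty:
        return BinSummary(0, None, None)
    return BinSummary(int(mask.sum()), float(selected.min()), float(selected.max()))


def fits_to_table(fits: dict[str, RegressionFit]) -> pd.DataFrame:
    """Tabulate fits with the conventional column heads.

    Columns: label, Slope, Intercept, SSE, R-square.
    """
    return pd.DataFrame(
        [
            (label, f.slope, f.intercept, f.sse, f.r_square)
            for label, f in fits.items()
        ],
        columns=["label", "Slope", "Intercept", "SSE", "R-square"],
    )
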