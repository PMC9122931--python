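"""Stage 4 — read alignments to IQR coverage, normalized abundances,
presence calls, and per-sample diversity indices.

Interquartile-range (IQR) coverage is the mean per-position read depth
restricted to positions whose depth lies inside the inclusive Q1–Q3 band;
it damps the influence of conserved (over-recruiting) and hypervariable
(under-recruiting) regions.  With the nearest-rank percentile convention
used here (1-based index ceil(q·n), band inclusive), a population has
positive IQR coverage exactly when more than 25% of its positions are
covered, for lengths divisible by four.  Normalizing each sample's IQR
coverage by smallest-library/library read count gives the relative
abundance proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqops import AlignmentHit

__all__ = [
    "CoverageProfile",
    "filter_hits",
    "coverage_profile",
    "iqr_coverage",
    "normalize_matrix",
    "presence",
    "diversity_indices",
]


@dataclass
class CoverageProfile:
    """Per-position read depth of one reference in one sample."""

    reference_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise ValueError("depth must be a non-empty 1-D vector")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def breadth(self) -> float:
        return float(np.count_nonzero(self.depth)) / len(self.depth)


def filter_hits(
    hits: Sequence[AlignmentHit],
    min_identity: float,
    min_aln_bp: int | None = None,
    min_read_fraction: float | None = None,
) -> list[AlignmentHit]:
    """Keep hits meeting the identity floor AND the applicable length
    criterion (absolute aligned bp, or fraction of the read).

    The two length criteria are alternative conventions and may not be
    combined.  ``min_read_fraction`` requires hits that know their read
    length.
    """
    if min_aln_bp is not None and min_read_fraction is not None:
        raise ValueError("set min_aln_bp or min_read_fraction, not both")
    kept = []
    for h in hits:
        if h.percent_identity < min_identity:
            continue
        if min_aln_bp is not None and h.aln_length < min_aln_bp:
            continue
        if min_read_fraction is not None:
            frac = h.read_fraction
            if frac is None:
                raise ValueError(
                    f"hit {h.query_id}->{h.subject_id} lacks a query length; "
                    "cannot apply a read-fraction filter"
                )
            if frac < min_read_fraction:
                continue
        kept.append(h)
    return kept


def coverage_profile(
    reference_id: str,
    reference_length: int,
    filtered_hits: Sequence[AlignmentHit],
    sample_id: str = "",
) -> CoverageProfile:
    """Depth vector where depth[p] counts hits whose reference interval
    covers p; hits contribute over their full aligned interval."""
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    for h in filtered_hits:
        s0, s1 = h.subject_interval
        if s0 < 0 or s1 > reference_length:
            raise ValueError(
                f"hit interval ({s0}, {s1}) outside reference of length {reference_length}"
            )
        delta[s0] += 1
        delta[s1] -= 1
    depth = np.cumsum(delta[:-1])
    return CoverageProfile(reference_id, sample_id, depth)


def iqr_coverage(profile: CoverageProfile | np.ndarray) -> float:
    """Mean depth over positions whose depth lies inside the inclusive
    interquartile band.

    Nearest-rank convention: with depths sorted ascending, Q1 and Q3 are
    the values at 1-based indices ceil(0.25 n) and ceil(0.75 n); the mean
    is over all depth values d with Q1 <= d <= Q3.
    """
    depth = profile.depth if isinstance(profile, CoverageProfile) else np.asarray(profile)
    if depth.ndim != 1 or len(depth) == 0:
        raise ValueError("depth must be a non-empty 1-D vector")
    srt = np.sort(depth)
    n = len(srt)
    q1 = srt[math.ceil(0.25 * n) - 1]
    q3 = srt[math.ceil(0.75 * n) - 1]
    band = srt[(srt >= q1) & (srt <= q3)]
    return float(band.mean())


def normalize_matrix(
    raw_iqr: pd.DataFrame, library_sizes: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Scale each sample column by smallest-library / library read count.

    ``raw_iqr`` is populations x samples; the normalization factor of the
    smallest library is exactly 1, zeros stay zero, and within-sample rank
    order is preserved.
    """
    sizes = pd.Series(library_sizes, dtype=float)
    missing = set(raw_iqr.columns) - set(sizes.index)
    if missing:
        raise ValueError(f"library sizes missing for samples: {sorted(missing)}")
    sizes = sizes[raw_iqr.columns]
    if (sizes <= 0).any():
        bad = sizes[sizes <= 0].index.tolist()
        raise ValueError(f"non-positive library size for samples: {bad}")
    return raw_iqr * (sizes.min() / sizes)


def presence(matrix_entry: float) -> bool:
    """A population is present in a sample iff its IQR coverage is non-zero."""
    return matrix_entry > 0


def diversity_indices(sample_column: Sequence[float]) -> tuple[float, int, float | None]:
    """(Shannon H, richness, evenness) of one sample's abundance column.

    H = -sum p_i ln p_i over present populations; evenness = H / ln(richness),
    reported as None when richness <= 1.
    """
    col = np.asarray(sample_column, dtype=float)
    if (col < 0).any():
        raise ValueError("negative abundance")
    present = col[col > 0]
    richness = int(len(present))
    if richness == 0:
        return 0.0, 0, None
    p = present / present.sum()
    shannon = float(-(p * np.log(p)).sum())
    evenness = None if richness <= 1 else shannon / math.log(richness)
    return shannon, richness, evenness
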