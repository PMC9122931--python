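"""Stage 5 — export flags, source-dataset categories, and depth of origin.

A population is exported from the photic zone when it shows non-zero IQR
coverage in any shallow (5–500 m) dataset; its source category is the
exact subset of shallow datasets with coverage.  Depth of origin is the
depth bin — surface (5–75 m), DCM (100–125 m), transitional (150–250 m) or
mesopelagic (500 m) — with the highest normalized IQR coverage in the
water-column virioplankton series; populations never detected above 500 m
are classified bathypelagic.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

__all__ = [
    "DEPTH_BINS",
    "BATHYPELAGIC",
    "DEPTH_BIN_RANGES_M",
    "flag_exported",
    "assign_depth_of_origin",
    "presence_by_origin_summary",
]

logger = logging.getLogger(__name__)

# shallow bins ordered surface -> deep; bathypelagic = not detected <= 500 m
DEPTH_BINS = ("surface", "DCM", "transitional", "mesopelagic")
BATHYPELAGIC = "bathypelagic"
DEPTH_BIN_RANGES_M = {
    "surface": (5, 75),
    "DCM": (100, 125),
    "transitional": (150, 250),
    "mesopelagic": (500, 500),
}


def flag_exported(
    shallow_dataset_coverages: Mapping[str, float],
) -> tuple[bool, frozenset[str]]:
    """(exported, source category) from per-shallow-dataset normalized IQR
    coverage; exported iff any dataset shows coverage > 0."""
    positive = frozenset(
        ds for ds, cov in shallow_dataset_coverages.items() if cov > 0
    )
    return bool(positive), positive


def assign_depth_of_origin(
    per_bin_normalized_coverage: Mapping[str, float],
    population_id: str = "",
) -> str:
    """Depth bin with the highest normalized IQR coverage; all-zero means
    bathypelagic; ties resolve to the shallowest tied bin (logged)."""
    unknown = set(per_bin_normalized_coverage) - set(DEPTH_BINS)
    if unknown:
        raise ValueError(f"unknown depth bins: {sorted(unknown)}")
    coverages = {b: per_bin_normalized_coverage.get(b, 0.0) for b in DEPTH_BINS}
    if any(v < 0 for v in coverages.values()):
        raise ValueError("negative coverage")
    top = max(coverages.values())
    if top <= 0:
        return BATHYPELAGIC
    tied = [b for b in DEPTH_BINS if coverages[b] == top]
    if len(tied) > 1:
        logger.info(
            "depth-of-origin tie for %s between %s; assigning shallowest",
            population_id or "population",
            tied,
        )
    return tied[0]


def presence_by_origin_summary(
    origins: Mapping[str, str],
    trap_presence: pd.DataFrame,
) -> pd.DataFrame:
    """Counts of present populations per origin bin per trap sample.

    ``origins`` maps population id -> depth bin label; ``trap_presence`` is
    a boolean populations x samples frame.  Rows are ordered surface ->
    bathypelagic; every bin appears even when empty.
    """
    bins = list(DEPTH_BINS) + [BATHYPELAGIC]
    bad = set(origins.values()) - set(bins)
    if bad:
        raise ValueError(f"unknown origin labels: {sorted(bad)}")
    table = pd.DataFrame(0, index=bins, columns=trap_presence.columns, dtype=int)
    for pop, origin in origins.items():
        if pop in trap_presence.index:
            table.loc[origin] += trap_presence.loc[pop].astype(int).values
    table.index.name = "depth_of_origin"
    return table
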