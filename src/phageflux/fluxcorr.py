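"""Stage 6 — summer export pulses, co-abundance modules, and module
correlation with log-transformed particulate carbon flux.

Samples at >= 150% of the long-term reference mean carbon flux are summer
export pulse (SEP) samples.  Populations are grouped into co-abundance
modules from a weighted correlation network: adjacency
``a_ij = |pearson(x_i, x_j)|^power`` (unsigned, soft threshold), the
topological overlap dissimilarity ``d_ij = 1 - TOM_ij`` with

    TOM_ij = (sum_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage hierarchical clustering on ``d``, and a static tree cut
(the cut height plus a minimum module size standing in for the dynamic
hybrid method).  Each module's eigenprofile (first principal component of
its members' z-scored profiles) is tested by Pearson correlation against
ln flux; members of positively correlated modules with p below alpha are
flagged flux-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .io import FluxRecord

__all__ = [
    "ModuleAssignment",
    "flag_export_pulse",
    "detect_modules",
    "correlate_modules_with_flux",
]


@dataclass
class ModuleAssignment:
    """Module labels (0 = unassigned) plus per-module flux statistics."""

    labels: pd.Series  # population id -> module label (int)
    eigenprofiles: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    module_r: dict[int, float] = field(default_factory=dict)
    module_p: dict[int, float] = field(default_factory=dict)
    flux_correlated: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def flag_export_pulse(
    flux_series: Sequence[FluxRecord], reference_mean: float
) -> list[FluxRecord]:
    """Set ``is_sep`` on each record: flux >= 1.5 x the long-term reference
    mean.  The reference mean is external context and must be supplied; it
    is never computed from the series itself."""
    if reference_mean is None or not reference_mean > 0:
        raise ValueError("reference_mean must be a positive number")
    out = []
    for rec in flux_series:
        out.append(
            FluxRecord(
                sample_id=rec.sample_id,
                interval_start=rec.interval_start,
                interval_end=rec.interval_end,
                carbon_flux=rec.carbon_flux,
                is_sep=rec.carbon_flux >= 1.5 * reference_mean,
            )
        )
    return out


def _tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def detect_modules(
    matrix: pd.DataFrame,
    power: float = 6.0,
    cut_height: float = 0.988,
    min_module_size: int = 10,
) -> ModuleAssignment:
    """Label co-abundance modules in a populations x samples matrix.

    Zero-variance populations get label 0 and take no part in the network.
    Clusters from the static cut that are smaller than ``min_module_size``
    are relabelled 0; surviving modules are numbered 1, 2, ... by
    decreasing size.  Deterministic and invariant to row order.
    """
    if matrix.shape[1] < 8:
        raise ValueError("module detection needs at least 8 samples")
    # canonical row order for determinism under input shuffling
    matrix = matrix.loc[sorted(matrix.index)]
    values = matrix.to_numpy(dtype=float)
    variances = values.var(axis=1)
    active = variances > 0
    labels = pd.Series(0, index=matrix.index, dtype=int)
    if active.sum() < 2:
        return ModuleAssignment(labels=labels)
    x = values[active]
    corr = np.corrcoef(x)
    adjacency = np.abs(np.clip(corr, -1.0, 1.0)) ** power
    d = _tom_dissimilarity(adjacency)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    active_ids = matrix.index[active]
    sizes: dict[int, int] = {}
    for c in flat:
        sizes[c] = sizes.get(c, 0) + 1
    surviving = [c for c, n in sizes.items() if n >= min_module_size]
    # order modules by size descending, ties by first member id
    first_member = {
        c: min(pid for pid, cc in zip(active_ids, flat) if cc == c) for c in surviving
    }
    surviving.sort(key=lambda c: (-sizes[c], first_member[c]))
    relabel = {c: i + 1 for i, c in enumerate(surviving)}
    for pid, c in zip(active_ids, flat):
        labels[pid] = relabel.get(c, 0)
    return ModuleAssignment(labels=labels)


def _eigenprofile(z_profiles: np.ndarray) -> np.ndarray:
    """First principal component across samples of member z-scored
    profiles (members x samples), sign-oriented to the mean profile and
    scaled to unit variance."""
    centered = z_profiles - z_profiles.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    mean_profile = z_profiles.mean(axis=0)
    if np.corrcoef(pc1, mean_profile)[0, 1] < 0:
        pc1 = -pc1
    sd = pc1.std()
    if sd > 0:
        pc1 = (pc1 - pc1.mean()) / sd
    return pc1


def correlate_modules_with_flux(
    modules: ModuleAssignment,
    matrix: pd.DataFrame,
    flux_series: Sequence[FluxRecord] | Mapping[str, float],
    alpha: float = 0.05,
    profile: str = "eigen",
) -> ModuleAssignment:
    """Fill per-module Pearson r and p against ln flux and flag members.

    ``profile='eigen'`` correlates the module eigenprofile (default);
    ``profile='sum'`` correlates the summed member abundances instead.
    Members of modules with p < alpha and r > 0 are flagged
    flux-correlated; negative-r modules are reported but never flagged.
    """
    if profile not in ("eigen", "sum"):
        raise ValueError(f"bad profile {profile!r}")
    if isinstance(flux_series, Mapping):
        flux = pd.Series(flux_series, dtype=float)
    else:
        flux = pd.Series(
            {rec.sample_id: rec.carbon_flux for rec in flux_series}, dtype=float
        )
    if set(flux.index) != set(matrix.columns) or len(flux) != matrix.shape[1]:
        raise ValueError("flux samples and matrix samples are not aligned 1:1")
    flux = flux[matrix.columns]
    if (flux <= 0).any():
        raise ValueError("carbon flux must be positive for the log transform")
    log_flux = np.log(flux.to_numpy())
    if np.ptp(log_flux) == 0:
        raise ValueError("constant flux series: correlation undefined")

    eigenprofiles: dict[int, np.ndarray] = {}
    module_r: dict[int, float] = {}
    module_p: dict[int, float] = {}
    flagged = pd.Series(False, index=matrix.index)
    for module in modules.module_ids:
        members = modules.members(module)
        sub = matrix.loc[members].to_numpy(dtype=float)
        if profile == "eigen":
            sd = sub.std(axis=1, keepdims=True)
            zscored = (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
            prof = _eigenprofile(zscored)
        else:
            prof = sub.sum(axis=0)
        r, p = stats.pearsonr(prof, log_flux)
        eigenprofiles[module] = prof
        module_r[module] = float(r)
        module_p[module] = float(p)
        if p < alpha and r > 0:
            flagged[members] = True
    return ModuleAssignment(
        labels=modules.labels,
        eigenprofiles=pd.DataFrame(eigenprofiles, index=matrix.columns),
        module_r=module_r,
        module_p=module_p,
        flux_correlated=flagged,
    )
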