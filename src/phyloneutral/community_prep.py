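"""Count-table conditioning: rarefaction, prevalence filtering, CLR transform
and species accumulation curves."""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import FeatureTable, SampleMetadata

__all__ = [
    "PrepConfig",
    "rarefy",
    "prevalence_filter",
    "clr_transform",
    "accumulation_curve",
]


@dataclasses.dataclass
class PrepConfig:
    rarefaction_depth: int = 5300
    min_reads: int = 2  # strict: a sample counts only if reads > min_reads
    min_sample_fraction: float = 0.05  # strict: kept only if fraction > this
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if not 0 <= self.min_sample_fraction <= 1:
            raise ValueError("min_sample_fraction must be in [0,1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below the depth are dropped with a warning; a
    sample already at exactly the depth is returned unchanged.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if table.is_transformed:
        raise ValueError("rarefy requires raw counts")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, ok in zip(table.sample_ids, keep) if not ok]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} samples below depth {depth}: {dropped}",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    cols = []
    for j in np.flatnonzero(keep):
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    out = np.column_stack(cols)
    return FeatureTable(
        list(table.taxon_ids),
        [s for s, ok in zip(table.sample_ids, keep) if ok],
        out,
    )


def prevalence_filter(
    table: FeatureTable, min_reads: int = 2, min_sample_fraction: float = 0.05
) -> FeatureTable:
    """Retain taxa with more than ``min_reads`` reads in over
    ``min_sample_fraction`` of the samples (both comparisons strict)."""
    if table.is_transformed:
        raise ValueError("prevalence_filter requires raw counts")
    frac = (table.counts > min_reads).sum(axis=1) / table.n_samples
    keep = frac > min_sample_fraction
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    kept_ids = [t for t, ok in zip(table.taxon_ids, keep) if ok]
    return FeatureTable(kept_ids, list(table.sample_ids), table.counts[keep, :])


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> FeatureTable:
    """Centered log-ratio transform per sample after adding a pseudocount."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if table.is_transformed:
        raise ValueError("table is already transformed")
    logs = np.log(table.counts.astype(float) + pseudocount)
    x = logs - logs.mean(axis=0, keepdims=True)
    return FeatureTable(
        list(table.taxon_ids), list(table.sample_ids), x, is_transformed=True
    )


@dataclasses.dataclass
class AccumulationCurve:
    group: str
    k: np.ndarray  # 1..n_group
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_perm: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "n_samples": self.k,
             "mean_richness": self.mean_richness, "sd_richness": self.sd_richness}
        )


def _cumulative_richness(presence: np.ndarray, order: Sequence[int]) -> np.ndarray:
    seen = np.zeros(presence.shape[0], dtype=bool)
    out = np.empty(len(order), dtype=float)
    for pos, j in enumerate(order):
        seen |= presence[:, j]
        out[pos] = seen.sum()
    return out


def accumulation_curve(
    table: FeatureTable,
    metadata: SampleMetadata,
    group: str,
    n_perm: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> AccumulationCurve:
    """Mean +/- sd cumulative richness over random orderings of a group's samples.

    With ``exhaustive=True`` every ordering is enumerated instead of sampled
    (only sensible for tiny groups).
    """
    members = [j for j, s in enumerate(table.sample_ids) if metadata.groups.get(s) == group]
    if not members:
        raise ValueError(f"unknown or empty group {group!r}")
    presence = table.counts > 0
    n = len(members)
    if exhaustive:
        orders = [list(perm) for perm in itertools.permutations(members)]
    else:
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(members)) for _ in range(n_perm)]
    curves = np.array([_cumulative_richness(presence, o) for o in orders])
    return AccumulationCurve(
        group=group,
        k=np.arange(1, n + 1),
        mean_richness=curves.mean(axis=0),
        sd_richness=curves.std(axis=0, ddof=0),
        n_perm=len(orders),
    )
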