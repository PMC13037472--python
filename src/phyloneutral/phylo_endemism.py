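"""Phylogenetic endemism and diversification analysis.

Given a tree whose tips split into focal (study) and reference (database)
sequences: cophenetic distances, a subsampled clustering test, sequence
identity novelty binning, nearest-reference distances, neighbor counts, a
resampled null curve for expected neighbors versus distance, and the
per-tip diversification index (observed minus expected neighbors). Negative
indices read as sparse phylogenetic neighborhoods, the purifying-selection
signature the downstream comparison tests for.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .diversity_stats import DistanceMatrix, PermutationTestResult, rank_sum_test
from .io_core import Phylogeny
from .neutral_model import (
    CATEGORY_NOT_SELECTED,
    CATEGORY_SELECTED,
    SelectionClassification,
)

__all__ = [
    "NullNeighborCurve",
    "ADIRecord",
    "NoveltyBin",
    "NOVELTY_THRESHOLDS",
    "cophenetic_distances",
    "clustering_test",
    "pairwise_identity",
    "classify_novelty",
    "nearest_nonfocal",
    "neighbor_count",
    "fit_null_neighbors",
    "fit_power_law",
    "null_self_calibration",
    "adi",
    "adi_records",
    "compare_adi_by_selection",
]

# 16S identity cutoffs delimiting novelty ranks (species / genus / family)
NOVELTY_THRESHOLDS = {"species": 0.987, "genus": 0.945, "family": 0.865}

BIN_KNOWN = "known_species"
BIN_SPECIES = "novel_species"
BIN_GENUS = "novel_genus"
BIN_FAMILY = "novel_family_or_higher"


# ---------------------------------------------------------------------------
# cophenetic distances


def cophenetic_distances(phylogeny: Phylogeny) -> DistanceMatrix:
    """Pairwise path-length distances between tips.

    Computed by a single post-order sweep: two tips in different child
    subtrees of a node are at distance depth(a) + depth(b) - 2*depth(node).
    """
    tree = phylogeny.tree
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    if n < 2:
        raise ValueError("need at least 2 tips")
    idx = {name: i for i, name in enumerate(tips)}
    depth: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    tip_depth = np.empty(n)
    D = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = idx[node.name]
            tip_depth[i] = depth[id(node)]
            below[id(node)] = np.array([i])
            continue
        kids = [below.pop(id(c)) for c in node.children]
        nd = depth[id(node)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                A, B = kids[a], kids[b]
                d = tip_depth[A][:, None] + tip_depth[B][None, :] - 2.0 * nd
                D[np.ix_(A, B)] = d
                D[np.ix_(B, A)] = d.T
        below[id(node)] = np.concatenate(kids)
    D = np.maximum(D, 0.0)  # guard tiny negative round-off
    return DistanceMatrix(tips, D, "cophenetic")


# ---------------------------------------------------------------------------
# clustering test


def clustering_test(
    phylogeny: Phylogeny,
    focal: Iterable[str] | None = None,
    k: int = 50,
    n_iter: int = 1000,
    seed: int = 0,
    dm: DistanceMatrix | None = None,
) -> PermutationTestResult:
    """Are focal tips more tightly clustered than random tips?

    Each iteration subsamples k tips from the focal set and k from all tips
    and records both mean pairwise cophenetic distances; the one-sided p is
    the paired fraction of iterations where the null mean is at most the
    focal mean (smaller = more clustered).
    """
    if k < 2:
        raise ValueError("subsample size k must be >= 2")
    focal = sorted(focal if focal is not None else phylogeny.focal)
    if dm is None:
        dm = cophenetic_distances(phylogeny)
    all_ids = list(dm.ids)
    if len(focal) < k or len(all_ids) < k:
        raise ValueError(f"need at least k={k} focal tips and k total tips")
    rng = np.random.default_rng(seed)
    focal_idx = np.array([dm.index(t) for t in focal])
    all_idx = np.arange(len(all_ids))
    iu = np.triu_indices(k, k=1)

    def mean_pairwise(pool: np.ndarray) -> float:
        pick = rng.choice(pool, size=k, replace=False)
        sub = dm.data[np.ix_(pick, pick)]
        return float(sub[iu].mean())

    focal_means = np.array([mean_pairwise(focal_idx) for _ in range(n_iter)])
    null_means = np.array([mean_pairwise(all_idx) for _ in range(n_iter)])
    observed = float(focal_means.mean())
    hits = int(np.sum(null_means <= focal_means))
    p = (1 + hits) / (1 + n_iter)
    return PermutationTestResult(observed, n_iter, p, seed, "clustering_subsample")


# ---------------------------------------------------------------------------
# identity binning


def pairwise_identity(a: str, b: str, gap_as_mismatch: bool = True) -> float:
    """Fraction of matching columns between two aligned sequences.

    Gap-gap columns and terminal gap overhangs are excluded; N matches
    nothing; internal gap-base columns count as mismatches by default.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()

    def core(seq: str) -> tuple[int, int]:
        stripped = seq.strip("-")
        start = len(seq) - len(seq.lstrip("-"))
        return start, start + len(stripped)

    a0, a1 = core(a)
    b0, b1 = core(b)
    lo, hi = max(a0, b0), min(a1, b1)
    matches = comparable = 0
    for i in range(lo, hi):
        ca, cb = a[i], b[i]
        if ca == "-" and cb == "-":
            continue
        if ca == "-" or cb == "-":
            if gap_as_mismatch:
                comparable += 1
            continue
        comparable += 1
        if ca == cb and ca != "N":
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return matches / comparable


@dataclasses.dataclass
class NoveltyBin:
    focal_id: str
    identity: float
    bin: str


def classify_novelty(identity: float, focal_id: str = "") -> NoveltyBin:
    """Bin a best-hit identity by the species/genus/family cutoffs; values
    exactly on a boundary fall in the less-novel bin."""
    if not 0 <= identity <= 1:
        raise ValueError(f"identity must be in [0,1], got {identity}")
    if identity >= NOVELTY_THRESHOLDS["species"]:
        bin_ = BIN_KNOWN
    elif identity >= NOVELTY_THRESHOLDS["genus"]:
        bin_ = BIN_SPECIES
    elif identity >= NOVELTY_THRESHOLDS["family"]:
        bin_ = BIN_GENUS
    else:
        bin_ = BIN_FAMILY
    return NoveltyBin(focal_id=focal_id, identity=identity, bin=bin_)


def novelty_bins(
    sequences: Mapping[str, str], focal: Iterable[str]
) -> list[NoveltyBin]:
    """Best identity of each focal sequence against all non-focal sequences,
    binned by the novelty cutoffs."""
    focal = set(focal)
    refs = {k: v for k, v in sequences.items() if k not in focal}
    if not refs:
        raise ValueError("no reference sequences")
    out = []
    for fid in sorted(focal):
        best = max(pairwise_identity(sequences[fid], r) for r in refs.values())
        out.append(classify_novelty(best, focal_id=fid))
    return out


# ---------------------------------------------------------------------------
# neighbor statistics


def nearest_nonfocal(dm: DistanceMatrix, focal: Iterable[str]) -> dict[str, float]:
    """Each focal tip's distance to its nearest non-focal (reference) tip."""
    focal = set(focal)
    ref_idx = np.array([i for i, t in enumerate(dm.ids) if t not in focal])
    if len(ref_idx) == 0:
        raise ValueError("empty reference set")
    out = {}
    for t in sorted(focal):
        i = dm.index(t)
        out[t] = float(dm.data[i, ref_idx].min())
    return out


def neighbor_count(
    dm: DistanceMatrix, focal: Iterable[str], d_ref: Mapping[str, float]
) -> dict[str, int]:
    """Number of other focal tips strictly closer than d_ref (ties excluded)."""
    focal_sorted = sorted(set(focal))
    focal_idx = np.array([dm.index(t) for t in focal_sorted])
    out = {}
    for t in focal_sorted:
        i = dm.index(t)
        dists = dm.data[i, focal_idx]
        out[t] = int(np.sum(dists < d_ref[t]) - (0.0 < d_ref[t]))  # exclude self (d=0)
    return out


@dataclasses.dataclass
class NullNeighborCurve:
    """Resampled (radius, neighbor count) points with a fitted monotone curve.

    Two families are fitted: the two-parameter power law n_exp(r) = a * r**b
    (a, b >= 0) and a monotone isotonic (pool-adjacent-violators) step
    function. ``family`` selects which one ``predict`` uses; the default is
    isotonic because neighbor counts saturate at n-1 for large radii, a shape
    the power law cannot capture without becoming badly miscalibrated at
    small radii. When the sampled radii are degenerate the curve falls back
    to the constant mean count.
    """

    a: float
    b: float
    radii: np.ndarray
    counts: np.ndarray
    n_iter: int
    seed: int
    residual_rms: float
    family: str = "isotonic"  # "isotonic" | "power"
    iso_x: np.ndarray | None = None
    iso_y: np.ndarray | None = None
    fallback_constant: float | None = None

    def predict(self, r) -> np.ndarray | float:
        r_arr = np.asarray(r, dtype=float)
        if self.fallback_constant is not None:
            out = np.full_like(r_arr, self.fallback_constant, dtype=float)
        elif self.family == "isotonic":
            out = np.interp(r_arr, self.iso_x, self.iso_y)
        else:
            out = self.a * np.power(r_arr, self.b)
        if np.isscalar(r) or r_arr.ndim == 0:
            return float(out)
        return out

    def summary(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "family": self.family,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "residual_rms": self.residual_rms,
            "fallback_constant": self.fallback_constant,
        }


def _fit_isotonic(radii: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Monotone non-decreasing least-squares step fit (PAVA); returns the
    breakpoints used for interpolation at prediction time."""
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(y_min=0.0, increasing=True, out_of_bounds="clip")
    iso.fit(radii, counts)
    return np.asarray(iso.X_thresholds_, dtype=float), np.asarray(iso.y_thresholds_, dtype=float)


def fit_power_law(radii: np.ndarray, counts: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of counts = a * radii**b with a, b >= 0."""
    pos = (radii > 0) & (counts > 0)
    if pos.sum() >= 2 and np.ptp(np.log(radii[pos])) > 0:
        slope, intercept = np.polyfit(np.log(radii[pos]), np.log(counts[pos]), 1)
        p0 = (float(np.exp(intercept)), max(slope, 0.0))
    else:
        p0 = (max(counts.mean(), 1e-6), 1.0)
    popt, _ = optimize.curve_fit(
        lambda r, a, b: a * np.power(r, b),
        radii,
        counts,
        p0=p0,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    a, b = float(popt[0]), float(popt[1])
    resid = counts - a * np.power(radii, b)
    return a, b, float(np.sqrt(np.mean(resid**2)))


def fit_null_neighbors(
    dm: DistanceMatrix,
    n_iter: int = 1000,
    seed: int = 0,
    tip_pool: Sequence[str] | None = None,
    family: str = "isotonic",
) -> NullNeighborCurve:
    """Resampled null for the expected number of neighbors within a radius.

    Each iteration draws one tip uniformly from the pool (all tips by
    default) and one radius uniformly from the empirical distribution of all
    pairwise distances, recording how many other tips sit strictly within
    that radius of the drawn tip. Both a power law and an isotonic step
    function are least-squares fitted to the sampled points; ``family``
    picks which one predictions use.
    """
    if family not in ("isotonic", "power"):
        raise ValueError(f"unknown curve family {family!r}")
    if len(dm) < 10:
        raise ValueError("need at least 10 tips for the null")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    pool_idx = (
        np.arange(len(dm))
        if tip_pool is None
        else np.array([dm.index(t) for t in tip_pool])
    )
    pairwise = dm.condensed()
    tips = rng.choice(pool_idx, size=n_iter, replace=True)
    radii = rng.choice(pairwise, size=n_iter, replace=True)
    counts = (dm.data[tips] < radii[:, None]).sum(axis=1) - (radii > 0).astype(int)
    counts = counts.astype(float)
    if np.ptp(radii) < 1e-12:
        mean_count = float(counts.mean())
        warnings.warn(
            "degenerate pairwise distances; null curve is the constant mean",
            stacklevel=2,
        )
        return NullNeighborCurve(
            a=0.0, b=0.0, radii=radii, counts=counts, n_iter=n_iter, seed=seed,
            residual_rms=float(counts.std()), family=family,
            fallback_constant=mean_count,
        )
    iso_x, iso_y = _fit_isotonic(radii, counts)
    try:
        a, b, _ = fit_power_law(radii, counts)
    except RuntimeError:
        warnings.warn("power-law fit failed; only the isotonic curve is usable", stacklevel=2)
        a = b = float("nan")
        if family == "power":
            family = "isotonic"
    curve = NullNeighborCurve(
        a=a, b=b, radii=radii, counts=counts, n_iter=n_iter, seed=seed,
        residual_rms=0.0, family=family, iso_x=iso_x, iso_y=iso_y,
    )
    curve.residual_rms = float(np.sqrt(np.mean((counts - curve.predict(radii)) ** 2)))
    return curve


def null_self_calibration(
    dm: DistanceMatrix, curve: NullNeighborCurve, n_draws: int = 4000, seed: int = 0
) -> float:
    """Mean diversification index of randomly drawn reference tips.

    Draws fresh (tip, radius) pairs by the same rule the null curve was
    built from and returns the mean of observed-minus-expected neighbor
    counts; approximately 0 when the curve is well calibrated.
    """
    rng = np.random.default_rng(seed)
    pairwise = dm.condensed()
    tips = rng.integers(0, len(dm.ids), size=n_draws)
    radii = rng.choice(pairwise, size=n_draws, replace=True)
    counts = (dm.data[tips] < radii[:, None]).sum(axis=1) - (radii > 0).astype(int)
    return float(np.mean(counts - curve.predict(radii)))


# ---------------------------------------------------------------------------
# diversification index


@dataclasses.dataclass
class ADIRecord:
    focal_id: str
    d_ref: float
    n_obs: int
    n_exp: float
    adi: float


def adi(n_obs: int, d_ref: float, curve: NullNeighborCurve) -> float:
    """Diversification index: observed minus expected neighbors at d_ref."""
    return float(n_obs - curve.predict(d_ref))


def adi_records(
    dm: DistanceMatrix, focal: Iterable[str], curve: NullNeighborCurve
) -> list[ADIRecord]:
    """Full per-focal-tip record set: d_ref, n_obs, n_exp and the index."""
    focal = sorted(set(focal))
    d_ref = nearest_nonfocal(dm, focal)
    n_obs = neighbor_count(dm, focal, d_ref)
    out = []
    for t in focal:
        n_exp = float(curve.predict(d_ref[t]))
        out.append(
            ADIRecord(
                focal_id=t,
                d_ref=d_ref[t],
                n_obs=n_obs[t],
                n_exp=n_exp,
                adi=n_obs[t] - n_exp,
            )
        )
    return out


def compare_adi_by_selection(
    records: Sequence[ADIRecord],
    classification: SelectionClassification,
    group_a: str = CATEGORY_SELECTED,
    group_b: str = CATEGORY_NOT_SELECTED,
) -> dict:
    """Two-sided rank-sum comparison of diversification indices between two
    selection categories, with per-group summaries."""
    category = dict(zip(classification.taxon_ids, classification.category))
    values = {group_a: [], group_b: []}
    for rec in records:
        cat = category.get(rec.focal_id)
        if cat in values:
            values[cat].append(rec.adi)
    for name, vals in values.items():
        if len(vals) < 2:
            raise ValueError(f"category {name!r} has fewer than 2 ADI records")
    stat, p = rank_sum_test(values[group_a], values[group_b])
    summaries = {
        name: {
            "n": len(vals),
            "mean_adi": float(np.mean(vals)),
            "median_adi": float(np.median(vals)),
        }
        for name, vals in values.items()
    }
    return {"statistic": stat, "p_value": p, "groups": summaries}
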