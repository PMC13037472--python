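"""Diversity metrics and permutation statistics: Bray-Curtis, Aitchison,
unweighted/weighted UniFrac, Faith's PD, PCoA, ANOSIM, dispersion homogeneity,
and rank tests.

Distance metrics and permutation tests are implemented directly (not
delegated) so their definitions match the stated contracts exactly; the rank
tests wrap the standard scipy routines behind the same interface.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_prep import clr_transform
from .io_core import FeatureTable, Phylogeny, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "bray_curtis",
    "aitchison",
    "unifrac",
    "faith_pd",
    "pcoa",
    "anosim",
    "dispersion_test",
    "rank_sum_test",
    "kruskal_wallis",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal and named rows."""

    ids: list[str]
    data: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if data.shape != (n, n):
            raise ValueError(f"matrix shape {data.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(data) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(data < 0):
            raise ValueError("negative distances")
        data = (data + data.T) / 2.0
        np.fill_diagonal(data, 0.0)
        self.data = data

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, id_: str) -> int:
        return self.ids.index(id_)

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in keep]
        return DistanceMatrix(list(keep), self.data[np.ix_(idx, idx)], self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclasses.dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # non-increasing, clamped at 0
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float


@dataclasses.dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int
    method: str = ""


# ---------------------------------------------------------------------------
# distances


def _sample_matrix(table: FeatureTable) -> np.ndarray:
    return table.counts.T.astype(float)  # samples x taxa


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """d(u,v) = sum|u-v| / (sum u + sum v), equivalently 1 - 2*sum(min)/..."""
    if table.is_transformed:
        raise ValueError("bray_curtis requires raw counts")
    S = _sample_matrix(table)
    sums = S.sum(axis=1)
    if np.any(sums == 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    num = np.abs(S[:, None, :] - S[None, :, :]).sum(axis=2)
    D = num / (sums[:, None] + sums[None, :])
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(table.sample_ids), D, "braycurtis")


def aitchison(table: FeatureTable, pseudocount: float = 1.0) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    clr = clr_transform(table, pseudocount)
    X = clr.counts.T  # samples x taxa
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(table.sample_ids), D, "aitchison")


def _branch_table(phylogeny: Phylogeny, tip_order: Sequence[str]):
    """Per-branch lengths and the tip-index sets below each branch."""
    idx = {t: i for i, t in enumerate(tip_order)}
    lengths = []
    masks = []
    below: dict[int, np.ndarray] = {}
    for node in phylogeny.tree.postorder(include_self=True):
        if node.is_tip():
            # tree tips absent from the table carry no abundance
            mask = np.zeros(len(tip_order), dtype=bool)
            if node.name in idx:
                mask[idx[node.name]] = True
        else:
            mask = np.zeros(len(tip_order), dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            masks.append(mask)
    return np.array(lengths), np.array(masks)


def unifrac(
    table: FeatureTable, phylogeny: Phylogeny, weighted: bool = False, raw: bool = False
) -> DistanceMatrix:
    """Phylogenetic dissimilarity between samples.

    Unweighted: unique branch length over total branch length across the two
    samples' tip sets. Weighted: branch-length-weighted abundance-flow
    difference, normalized to [0,1] unless ``raw=True``.
    """
    if table.is_transformed:
        raise ValueError("unifrac requires raw counts")
    tip_set = set(phylogeny.tip_names)
    present = table.counts.sum(axis=1) > 0
    missing = [t for t, ok in zip(table.taxon_ids, present) if ok and t not in tip_set]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    used = [t for t, ok in zip(table.taxon_ids, present) if ok]
    sub = table.select_taxa(used)
    lengths, masks = _branch_table(phylogeny, used)  # branches x taxa
    S = sub.counts.T.astype(float)  # samples x taxa
    totals = S.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    n = table.n_samples
    D = np.zeros((n, n))
    if weighted:
        rel = S / totals[:, None]
        A = rel @ masks.T  # samples x branches: abundance below each branch
        for i in range(n):
            for j in range(i + 1, n):
                num = float(np.sum(lengths * np.abs(A[i] - A[j])))
                if raw:
                    D[i, j] = D[j, i] = num
                else:
                    den = float(np.sum(lengths * (A[i] + A[j])))
                    D[i, j] = D[j, i] = num / den if den > 0 else 0.0
    else:
        P = (S > 0) @ masks.T > 0  # samples x branches: any tip below present
        for i in range(n):
            for j in range(i + 1, n):
                either = P[i] | P[j]
                only_one = P[i] ^ P[j]
                den = float(np.sum(lengths[either]))
                D[i, j] = D[j, i] = float(np.sum(lengths[only_one])) / den if den > 0 else 0.0
    name = ("weighted" if weighted else "unweighted") + "_unifrac" + ("_raw" if raw else "")
    return DistanceMatrix(list(table.sample_ids), D, name)


def faith_pd(taxa: Iterable[str], phylogeny: Phylogeny) -> float:
    """Total branch length of the union of root-to-tip paths of observed taxa."""
    taxa = set(taxa)
    if not taxa:
        warnings.warn("empty taxon set: Faith's PD is 0", stacklevel=2)
        return 0.0
    tips = set(phylogeny.tip_names)
    missing = sorted(taxa - tips)
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    total = 0.0
    counted: set[int] = set()
    name_to_tip = {t.name: t for t in phylogeny.tree.tips()}
    for name in taxa:
        node = name_to_tip[name]
        while node.parent is not None and id(node) not in counted:
            counted.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


# ---------------------------------------------------------------------------
# ordination


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis with Gower double-centering.

    Negative eigenvalues are clamped to zero and their absolute mass reported.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 samples")
    D2 = dm.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    negative_mass = float(np.sum(np.abs(eigvals[eigvals < 0])))
    # zero out numerically-null eigenvalues so their arbitrary eigenvectors
    # cannot leak into the coordinates
    tol = np.abs(eigvals).max() * 1e-12 if eigvals.size else 0.0
    eigvals = np.where(np.abs(eigvals) < tol, 0.0, eigvals)
    clamped = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(clamped)[None, :]
    total = clamped.sum()
    proportions = clamped / total if total > 0 else np.zeros_like(clamped)
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=clamped,
        proportion_explained=proportions,
        negative_eigenvalue_mass=negative_mass,
    )


# ---------------------------------------------------------------------------
# permutation tests


def _group_vector(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, SampleMetadata):
        mapping: Mapping[str, str] = groups.groups
    else:
        mapping = dict(groups)
    missing = [s for s in dm.ids if s not in mapping]
    if missing:
        raise KeyError(f"samples absent from group mapping: {missing}")
    return np.array([mapping[s] for s in dm.ids])


def _check_groups(labels: np.ndarray) -> None:
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    small = [str(v) for v, c in zip(values, counts) if c < 2]
    if small:
        raise ValueError(f"groups with a single sample: {small}")


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Rank-based group-separation statistic R with label-permutation p-value."""
    labels = _group_vector(dm, groups)
    _check_groups(labels)
    ranks = stats.rankdata(dm.condensed())  # midranks for ties
    iu = np.triu_indices(len(dm), k=1)
    rng = np.random.default_rng(seed)
    within = labels[iu[0]] == labels[iu[1]]
    observed = _anosim_r(ranks, within)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationTestResult(observed, n_perm, p, seed, "anosim")


def _centroid_distances(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = np.empty(len(labels))
    for g in np.unique(labels):
        mask = labels == g
        centroid = coords[mask].mean(axis=0)
        out[mask] = np.sqrt(((coords[mask] - centroid) ** 2).sum(axis=1))
    return out


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(values) - k
    # identical group geometries leave only round-off in both sums; report 0
    # rather than a ratio of noise
    scale = len(values) * (grand**2 + 1e-12)
    if ss_between < 1e-12 * scale:
        return 0.0
    if ss_within <= 0:
        return np.inf
    return float((ss_between / df_b) / (ss_within / df_w))


def dispersion_test(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Homogeneity of group dispersions: one-way F on distances to group
    centroids in the positive-eigenvalue PCoA space; p by label permutation."""
    labels = _group_vector(dm, groups)
    _check_groups(labels)
    ord_res = pcoa(dm)
    keep = ord_res.eigenvalues > 1e-10
    coords = ord_res.coordinates[:, keep]
    rng = np.random.default_rng(seed)
    observed = _anova_f(_centroid_distances(coords, labels), labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anova_f(_centroid_distances(coords, perm), perm) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationTestResult(observed, n_perm, p, seed, "dispersion")


# ---------------------------------------------------------------------------
# rank tests


def rank_sum_test(x, y, mode: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney two-sample test.

    Exact enumeration when the pooled size is <= 20 with no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if mode != "two_sided":
        raise ValueError(f"unsupported mode {mode!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
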