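"""Synthetic communities, phylogenies and alignments with known ground truth.

The community generator is the exact finite-depth analogue of the occupancy
model fitted downstream: per-host relative abundances are Beta(mN*p, mN*(1-p))
draws and read counts are Binomial(depth, abundance), so parameter recovery is
well-posed. Selection is injected at the occupancy level by forcing presence
or absence in a stated extra fraction of hosts. The phylogeny generator builds
a birth-death backbone and grafts focal clades whose internal diversification
is controllably complete or pruned.

All generators are pure functions of (spec, seed); a single integer seed fans
out to per-component streams via ``numpy.random.default_rng([seed, stream])``.
"""
from __future__ import annotations

import dataclasses
import io
import random
import warnings
from typing import Literal, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim
from skbio import TreeNode

from .io_core import AlignedSequenceSet, FeatureTable, Phylogeny, SampleMetadata

__all__ = [
    "CommunitySimSpec",
    "PhyloSimSpec",
    "CladeRegime",
    "SelectedTaxon",
    "SyntheticTruth",
    "simulate_metacommunity",
    "simulate_phylogeny",
    "evolve_sequences",
    "simulate_benchmark",
]

# fixed stream ids for fanning one seed out to independent generators
_STREAM_COMMUNITY = 11
_STREAM_PHYLOGENY = 22
_STREAM_SEQUENCES = 33


@dataclasses.dataclass(frozen=True)
class SelectedTaxon:
    index: int
    direction: Literal["over", "under"]
    delta: float

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError(f"occupancy offset delta must be in (0,1), got {self.delta}")
        if self.direction not in ("over", "under"):
            raise ValueError(f"direction must be 'over' or 'under', got {self.direction!r}")


@dataclasses.dataclass
class CommunitySimSpec:
    n_taxa: int
    n_hosts: int
    depth: int
    mN_true: float
    abundance_lognorm: tuple[float, float] = (0.0, 1.5)  # (mu, sigma) before normalization
    abundances: np.ndarray | None = None  # explicit p_i override (normalized internally)
    selected_taxa: Sequence[SelectedTaxon] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_hosts < 1:
            raise ValueError("n_taxa and n_hosts must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.mN_true <= 0:
            raise ValueError(f"mN_true must be positive, got {self.mN_true}")
        for st in self.selected_taxa:
            if not 0 <= st.index < self.n_taxa:
                raise ValueError(f"selected taxon index {st.index} out of range")


@dataclasses.dataclass(frozen=True)
class CladeRegime:
    kind: Literal["complete", "pruned"]
    prune_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("complete", "pruned"):
            raise ValueError(f"unknown clade regime {self.kind!r}")
        if not 0 <= self.prune_fraction < 1:
            raise ValueError("prune_fraction must be in [0,1)")
        if self.kind == "complete" and self.prune_fraction != 0:
            raise ValueError("complete regime cannot have a prune fraction")


@dataclasses.dataclass
class PhyloSimSpec:
    n_reference_tips: int
    n_focal_clades: int
    tips_per_clade: int
    clade_regimes: Sequence[CladeRegime] = ()
    birth_rate: float = 1.0
    death_rate: float = 0.2
    graft_depth: float = 1.0  # stem branch length connecting clade root to backbone
    clade_height: float = 0.5  # clades rescaled to this root-to-tip height
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference_tips < 3:
            raise ValueError("need at least 3 reference tips")
        if self.n_focal_clades > 0 and self.tips_per_clade < 1:
            raise ValueError("tips_per_clade must be >= 1")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth rate must be > 0 and death rate >= 0")
        if not self.clade_regimes:
            self.clade_regimes = tuple(CladeRegime("complete") for _ in range(self.n_focal_clades))
        if len(self.clade_regimes) != self.n_focal_clades:
            raise ValueError("one regime required per focal clade")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data."""

    mN_true: float | None = None
    selection_labels: dict[str, str] = dataclasses.field(default_factory=dict)
    clade_regimes: dict[str, CladeRegime] = dataclasses.field(default_factory=dict)
    clade_membership: dict[str, str] = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# community generator


def simulate_metacommunity(
    spec: CommunitySimSpec,
) -> tuple[FeatureTable, SampleMetadata, SyntheticTruth]:
    """Draw a taxa-by-hosts count table from the neutral occupancy model,
    then inject the spec's occupancy-level selection shifts."""
    rng = np.random.default_rng([spec.seed, _STREAM_COMMUNITY])
    if spec.abundances is not None:
        p = np.asarray(spec.abundances, dtype=float)
        if len(p) != spec.n_taxa or np.any(p <= 0):
            raise ValueError("abundances must be positive and match n_taxa")
    else:
        mu, sigma = spec.abundance_lognorm
        p = rng.lognormal(mu, sigma, size=spec.n_taxa)
    p = p / p.sum()

    a = rng.beta(
        spec.mN_true * p[:, None],
        spec.mN_true * (1.0 - p[:, None]),
        size=(spec.n_taxa, spec.n_hosts),
    )
    counts = rng.binomial(spec.depth, a)
    # detection-exact at the limit d = 1/depth: a taxon is present iff its
    # local abundance exceeds d, so occupancy converges to the occupancy
    # curve's prediction exactly (binomial sampling alone smears detection
    # around the limit and breaks that convergence)
    d = 1.0 / spec.depth
    counts = np.where(a > d, np.maximum(counts, 1), 0)

    labels = {i: "neutral" for i in range(spec.n_taxa)}
    for st in spec.selected_taxa:
        labels[st.index] = st.direction
        n_force = int(round(st.delta * spec.n_hosts))
        row = counts[st.index]
        if st.direction == "over":
            candidates = np.flatnonzero(row == 0)
        else:
            candidates = np.flatnonzero(row > 0)
        if len(candidates) < n_force:
            warnings.warn(
                f"taxon {st.index}: occupancy shift of {n_force} hosts clipped to "
                f"{len(candidates)} available hosts",
                stacklevel=2,
            )
            n_force = len(candidates)
        chosen = rng.choice(candidates, size=n_force, replace=False) if n_force else []
        if st.direction == "over":
            # minimal presence: selection is an occupancy shift, so forced
            # presences must not also inflate the taxon's mean abundance
            row[chosen] = 1
        else:
            row[chosen] = 0

    taxon_ids = [f"T{i:04d}" for i in range(spec.n_taxa)]
    sample_ids = [f"H{j:04d}" for j in range(spec.n_hosts)]
    table = FeatureTable(taxon_ids, sample_ids, counts)
    # hosts are split into arbitrary "site" groups so grouped statistics can run
    group_of = lambda j: ["siteA", "siteB", "siteC"][j % 3]
    metadata = SampleMetadata(groups={s: group_of(j) for j, s in enumerate(sample_ids)})
    truth = SyntheticTruth(
        mN_true=spec.mN_true,
        selection_labels={taxon_ids[i]: lab for i, lab in labels.items()},
    )
    return table, metadata, truth


# ---------------------------------------------------------------------------
# phylogeny generator


def _birth_death_skbio(n_tips: int, birth: float, death: float, rng: np.random.Generator) -> TreeNode:
    """Simulate a birth-death tree with n extant tips and return it as a TreeNode."""
    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    dtree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=py_rng,
        repeat_until_success=True,
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def _root_to_tip(root: TreeNode, tip: TreeNode) -> float:
    d, node = 0.0, tip
    while node is not root:
        d += node.length or 0.0
        node = node.parent
    return d


def _scale_tree(tree: TreeNode, target_height: float) -> None:
    height = max(_root_to_tip(tree, t) for t in tree.tips())
    if height <= 0:
        return
    factor = target_height / height
    for node in tree.traverse(include_self=False):
        node.length = (node.length or 0.0) * factor


def simulate_phylogeny(spec: PhyloSimSpec) -> tuple[Phylogeny, SyntheticTruth]:
    """Build a reference backbone and graft focal clades onto random branches.

    Pruned-regime clades lose the stated fraction of their tips after
    simulation, emulating the removal of intermediate variants; complete
    clades keep every tip. All clades are rescaled to the same root-to-tip
    height so regimes are age-matched.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_PHYLOGENY])
    backbone = _birth_death_skbio(spec.n_reference_tips, spec.birth_rate, spec.death_rate, rng)
    for i, tip in enumerate(backbone.tips()):
        tip.name = f"R{i:04d}"

    truth = SyntheticTruth()
    focal: set[str] = set()
    for c in range(spec.n_focal_clades):
        regime = spec.clade_regimes[c]
        clade_name = f"C{c}"
        if spec.tips_per_clade == 1:
            clade = TreeNode(name=f"{clade_name}_T0000", length=spec.clade_height)
            clade_tips = [clade]
        else:
            clade = _birth_death_skbio(spec.tips_per_clade, spec.birth_rate, spec.death_rate, rng)
            _scale_tree(clade, spec.clade_height)
            clade_tips = list(clade.tips())
            for i, tip in enumerate(clade_tips):
                tip.name = f"{clade_name}_T{i:04d}"
        if regime.kind == "pruned" and len(clade_tips) > 1:
            n_keep = max(1, int(round(len(clade_tips) * (1 - regime.prune_fraction))))
            keep_idx = rng.choice(len(clade_tips), size=n_keep, replace=False)
            keep = {clade_tips[i].name for i in keep_idx}
            clade = clade.shear(keep)
            clade_tips = list(clade.tips())
        # graft next to a random backbone leaf: the joint sits a short, fixed
        # distance up that leaf's terminal edge, so every clade's distance to
        # its nearest reference tip is set by graft_depth + clade height, not
        # by where on the backbone it happened to land
        candidates = [n for n in backbone.tips() if (n.length or 0) > 0]
        target = candidates[int(rng.integers(0, len(candidates)))]
        stub = min(0.05, 0.5 * target.length)
        parent = target.parent
        joint = TreeNode(length=target.length - stub)
        parent.remove(target)
        parent.append(joint)
        target.length = stub
        joint.append(target)
        clade.length = spec.graft_depth
        joint.append(clade)

        for tip in clade_tips:
            focal.add(tip.name)
            truth.clade_membership[tip.name] = clade_name
        truth.clade_regimes[clade_name] = regime

    phylogeny = Phylogeny(tree=backbone, focal=frozenset(focal))
    return phylogeny, truth


# ---------------------------------------------------------------------------
# sequence evolution


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def evolve_sequences(phylogeny: Phylogeny, length: int, seed: int) -> AlignedSequenceSet:
    """Evolve gap-free sequences tip-ward from a random root sequence under
    the one-parameter substitution model (equal exchange rates, branch lengths
    in substitutions/site)."""
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_SEQUENCES])
    root = phylogeny.tree
    states: dict[int, np.ndarray] = {id(root): rng.integers(0, 4, size=length)}
    out: dict[str, str] = {}
    for node in root.preorder(include_self=False):
        parent_state = states[id(node.parent)]
        t = node.length or 0.0
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        state = parent_state.copy()
        mask = rng.random(length) < p_diff
        n_mut = int(mask.sum())
        if n_mut:
            state[mask] = (state[mask] + rng.integers(1, 4, size=n_mut)) % 4
        states[id(node)] = state
        if node.is_tip():
            out[node.name] = _BASES[state].tobytes().decode("ascii")
    return AlignedSequenceSet(sequences=out)


# ---------------------------------------------------------------------------
# linked end-to-end benchmark


def _abundance_for_occupancy(target: float, mN: float, d: float) -> float:
    """Metacommunity relative abundance whose predicted occurrence is ``target``."""
    from scipy import optimize as _opt

    from .neutral_model import predicted_occurrence

    return float(
        10 ** _opt.brentq(
            lambda lp: predicted_occurrence(10**lp, mN, d) - target, -9, -0.31
        )
    )


def simulate_benchmark(
    seed: int,
    n_reference_tips: int = 300,
    n_clades_per_regime: int = 3,
    tips_per_clade: int = 16,
    prune_fraction: float = 0.7,
    n_offtree_taxa: int = 60,
    n_hosts: int = 111,
    depth: int = 5300,
    mN_true: float = 130.0,
    delta: float = 0.35,
) -> tuple[FeatureTable, SampleMetadata, Phylogeny, SyntheticTruth]:
    """Generate a linked dataset where over-occurring taxa sit in pruned
    (under-diversified) clades and under-occurring taxa in complete clades.

    This is the ground-truth configuration for the end-to-end directional
    check: taxa under positive occupancy selection should come out with lower
    diversification indices than the negatively selected group.
    """
    regimes = [CladeRegime("pruned", prune_fraction)] * n_clades_per_regime + [
        CladeRegime("complete")
    ] * n_clades_per_regime
    pspec = PhyloSimSpec(
        n_reference_tips=n_reference_tips,
        n_focal_clades=len(regimes),
        tips_per_clade=tips_per_clade,
        clade_regimes=regimes,
        seed=seed,
    )
    phylogeny, ptruth = simulate_phylogeny(pspec)

    focal_tips = sorted(phylogeny.focal)
    over_tips = [t for t in focal_tips if ptruth.clade_regimes[ptruth.clade_membership[t]].kind == "pruned"]
    under_tips = [t for t in focal_tips if t not in set(over_tips)]

    n_taxa = len(focal_tips) + n_offtree_taxa
    selected = [
        SelectedTaxon(i, "over", delta) for i in range(len(over_tips))
    ] + [
        SelectedTaxon(len(over_tips) + i, "under", delta) for i in range(len(under_tips))
    ]
    # give tree-resident taxa mid-range metacommunity abundances so their
    # neutral occupancy leaves headroom for the injected shift in both
    # directions; off-tree taxa carry the bulk of the abundance distribution
    rng = np.random.default_rng([seed, 44])
    w_off = rng.lognormal(0.0, 1.5, size=n_offtree_taxa)
    target_p = _abundance_for_occupancy(0.5, mN_true, 1.0 / depth)
    jitter = rng.lognormal(0.0, 0.25, size=len(focal_tips))
    # solve w so that w / (sum_off + sum_focal_w) = target_p on average
    w_focal = jitter * target_p * w_off.sum() / max(1e-12, 1.0 - len(focal_tips) * target_p)
    p = np.concatenate([w_focal, w_off])
    cspec = CommunitySimSpec(
        n_taxa=n_taxa,
        n_hosts=n_hosts,
        depth=depth,
        mN_true=mN_true,
        abundances=p,
        selected_taxa=selected,
        seed=seed,
    )
    table, metadata, ctruth = simulate_metacommunity(cspec)

    # rename taxa so tree-resident taxa carry their tip labels
    new_ids = over_tips + under_tips + [f"OFF{i:04d}" for i in range(n_offtree_taxa)]
    table = FeatureTable(new_ids, table.sample_ids, table.counts)
    labels = {
        new_ids[i]: ctruth.selection_labels[f"T{i:04d}"] for i in range(n_taxa)
    }
    truth = SyntheticTruth(
        mN_true=mN_true,
        selection_labels=labels,
        clade_regimes=ptruth.clade_regimes,
        clade_membership=ptruth.clade_membership,
    )
    return table, metadata, phylogeny, truth
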