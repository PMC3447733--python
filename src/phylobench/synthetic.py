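"""Synthetic benchmark data with known ground truth.

Real evaluations of tree-building methods need a corpus of orthologous
groups and a curated taxonomy; this module stands in for both so the whole
pipeline — measures, paired comparisons, correlations — is exercisable
end-to-end from a seed.  The generative story mirrors the benchmark's core
premise: there is one species tree, every orthologous group (OG) covers a
random subset of the species, and a perfect method would return exactly the
induced subtree for each OG (so restrictions of any two true trees always
agree).  A simulated "method" with error rate ``lambda`` returns the true
induced tree perturbed by ``Poisson(lambda)`` random nearest-neighbor
interchanges (NNI), so both the Intra and the Taxon measure increase with
lambda — each NNI changes at most one split, bounding the RF damage per
tree by the number of moves.

The emitted taxonomy's induced trees equal the species-tree restrictions
(optionally with random polytomies), so the Taxon reference is the truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .measures import MethodRun, write_manifest
from .taxonomy import TaxonomyTable
from .trees import PhyloTree, TreeValidationError, write_newick

__all__ = [
    "MethodSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "random_binary_tree",
    "sample_og",
    "perturb_tree",
    "collapse_random_edges",
    "taxonomy_from_tree",
    "simulate_dataset",
    "write_dataset",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_binary_tree(
    n: int, seed=None, labels: Optional[Sequence[str]] = None
) -> PhyloTree:
    """Uniform random unrooted binary topology on ``n`` labeled leaves.

    Built by attaching each new leaf to a uniformly chosen edge of the
    current tree, which yields every one of the ``(2n-5)!!`` labeled
    topologies with equal probability.  No branch lengths.
    """
    if n < 3:
        raise ValueError("need at least 3 leaves")
    if labels is None:
        width = max(2, len(str(n)))
        labels = [f"s{i + 1:0{width}d}" for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("label count must equal n")
    rng = _rng(seed)
    # node ids: 0..n-1 leaves, internal from n upward
    center = n
    adj: Dict[int, Dict[int, None]] = {
        0: {center: None},
        1: {center: None},
        2: {center: None},
        center: {0: None, 1: None, 2: None},
    }
    next_internal = n + 1
    edges: List[Tuple[int, int]] = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n):
        u, v = edges[int(rng.integers(len(edges)))]
        mid = next_internal
        next_internal += 1
        del adj[u][v]
        del adj[v][u]
        adj[mid] = {u: None, v: None, leaf: None}
        adj[u][mid] = None
        adj[v][mid] = None
        adj[leaf] = {mid: None}
        edges.remove((u, v))
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    return PhyloTree(adj, {i: labels[i] for i in range(n)})


def sample_og(
    species_tree: PhyloTree, k: int, seed=None
) -> Tuple[frozenset, PhyloTree]:
    """A uniform ``k``-subset of species and its true induced tree."""
    n = species_tree.n_leaves
    if not 4 <= k <= n:
        raise ValueError(f"OG size must be in [4, {n}], got {k}")
    rng = _rng(seed)
    species = sorted(species_tree.leaves)
    subset = frozenset(rng.choice(species, size=k, replace=False).tolist())
    return subset, species_tree.restrict(subset)


def perturb_tree(tree: PhyloTree, n_moves: int, seed=None) -> PhyloTree:
    """Apply random NNI moves; RF distance to the input is at most n_moves."""
    if not tree.is_binary():
        raise TreeValidationError("NNI perturbation requires a binary tree")
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    rng = _rng(seed)
    adj = {u: dict(nbrs) for u, nbrs in tree._adj.items()}
    labels = dict(tree._labels)
    internal = set(adj) - set(labels)
    for _ in range(n_moves):
        internal_edges = [
            (u, v) for u in internal for v in adj[u] if v in internal and u < v
        ]
        if not internal_edges:
            break  # quartets still have one internal edge; n<4 cannot occur here
        u, v = internal_edges[int(rng.integers(len(internal_edges)))]
        a_opts = [w for w in adj[u] if w != v]
        b_opts = [w for w in adj[v] if w != u]
        a = a_opts[int(rng.integers(len(a_opts)))]
        b = b_opts[int(rng.integers(len(b_opts)))]
        la, lb = adj[u][a], adj[v][b]
        del adj[u][a], adj[a][u], adj[v][b], adj[b][v]
        adj[u][b] = adj[b][u] = lb
        adj[v][a] = adj[a][v] = la
    return PhyloTree(adj, labels)


def collapse_random_edges(tree: PhyloTree, rate: float, seed=None) -> PhyloTree:
    """Contract each internal edge independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed)
    old = tree._adj
    labels = dict(tree._labels)
    internal = set(old) - set(labels)
    # decide per original internal edge, then contract all chosen edges at
    # once (union-find), so each edge's decision is independent of the rest
    parent = {u: u for u in old}

    def find(u: int) -> int:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for u in sorted(internal):
        for v in sorted(old[u]):
            if v in internal and u < v and rng.random() < rate:
                parent[find(u)] = find(v)
    adj: Dict[int, Dict[int, Optional[float]]] = {}
    for u in old:
        adj.setdefault(find(u), {})
    for u in old:
        for v, l in old[u].items():
            ru, rv = find(u), find(v)
            if ru != rv:
                adj[ru][rv] = l
                adj[rv][ru] = l
    return PhyloTree(adj, labels)


def taxonomy_from_tree(
    species_tree: PhyloTree, polytomy_rate: float = 0.0, seed=None
) -> TaxonomyTable:
    """A taxonomy whose induced trees equal the species-tree restrictions.

    The unrooted species tree is rooted at an arbitrary internal node and
    every tree node becomes a taxonomy node.  With ``polytomy_rate`` > 0,
    internal nodes are randomly dissolved into their parent, creating
    multifurcating (less resolved, never contradictory) references.
    """
    rng = _rng(seed)
    adj = species_tree._adj
    labels = species_tree._labels
    internal = species_tree._internal_nodes()
    root = internal[0] if internal else next(iter(adj))
    parent: Dict[int, int] = {root: root}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    name = {
        u: (labels[u] if u in labels else f"clade{u:04d}") for u in parent
    }
    if polytomy_rate > 0:
        for u in order[1:]:
            if u in labels:
                continue
            if rng.random() < polytomy_rate:
                # dissolve u: its children re-attach to u's (possibly updated) parent
                target = parent[u]
                while name[target] is None:
                    target = parent[target]
                name[u] = None
                for v in parent:
                    if parent[v] == u:
                        parent[v] = target
    nodes = {
        name[u]: (name[parent[u]], "no rank", name[u])
        for u in parent
        if name[u] is not None
    }
    # re-point parents that were dissolved
    species_map = {labels[u]: name[u] for u in labels}
    return TaxonomyTable(nodes, species_map)


@dataclass(frozen=True)
class MethodSpec:
    """A simulated method: NNI error rate and optional polytomy emission."""

    method_id: str
    error_rate: float  # mean NNI moves per tree (Poisson)
    multifurcation_rate: float = 0.0

    def __post_init__(self):
        if self.error_rate < 0:
            raise ValueError("error_rate must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 30
    n_ogs: int = 100
    og_size_range: Tuple[int, int] = (4, 12)
    methods: Tuple[MethodSpec, ...] = (
        MethodSpec("perfect", 0.0),
        MethodSpec("noisy", 1.0),
    )
    polytomy_rate: float = 0.0
    class_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.og_size_range[0] < 4 or self.og_size_range[1] > self.n_species:
            raise ValueError("OG sizes must lie in [4, n_species]")
        object.__setattr__(
            self,
            "methods",
            tuple(
                m if isinstance(m, MethodSpec) else MethodSpec(**m)
                for m in self.methods
            ),
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        raw = json.loads(text)
        if "og_size_range" in raw:
            raw["og_size_range"] = tuple(raw["og_size_range"])
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    species_tree: PhyloTree
    taxonomy: TaxonomyTable
    true_trees: Dict[str, PhyloTree]  # og_id -> true induced tree
    runs: Dict[str, MethodRun]  # method_id -> run


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full benchmark dataset from a config (reproducible by seed)."""
    rng = np.random.default_rng(config.seed)
    species_tree = random_binary_tree(config.n_species, rng)
    taxonomy = taxonomy_from_tree(species_tree, config.polytomy_rate, rng)
    lo, hi = config.og_size_range
    width = max(3, len(str(config.n_ogs)))
    true_trees: Dict[str, PhyloTree] = {}
    for i in range(config.n_ogs):
        k = int(rng.integers(lo, hi + 1))
        _, true = sample_og(species_tree, k, rng)
        true_trees[f"og{i + 1:0{width}d}"] = true
    runs: Dict[str, MethodRun] = {}
    for spec in config.methods:
        trees: Dict[str, PhyloTree] = {}
        for og_id, true in true_trees.items():
            n_moves = int(rng.poisson(spec.error_rate))
            t = perturb_tree(true, n_moves, rng)
            if spec.multifurcation_rate > 0:
                t = collapse_random_edges(t, spec.multifurcation_rate, rng)
            trees[og_id] = t
        runs[spec.method_id] = MethodRun(spec.method_id, config.class_id, trees)
    return SyntheticDataset(config, species_tree, taxonomy, true_trees, runs)


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """Write the manifest + Newick layout the measures module reads.

    Layout: ``trees/<class>/<method>/<og>.nwk``, ``manifest.tsv``, the
    taxonomy as ``taxonomy.tsv`` (lineage TSV) and the config as JSON.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    rows = []
    for method_id, run in dataset.runs.items():
        mdir = outdir / "trees" / dataset.config.class_id / method_id
        mdir.mkdir(parents=True, exist_ok=True)
        for og_id, tree in run.trees.items():
            rel = Path("trees") / dataset.config.class_id / method_id / f"{og_id}.nwk"
            (outdir / rel).write_text(write_newick(tree) + "\n")
            rows.append((dataset.config.class_id, method_id, og_id, str(rel)))
    manifest = outdir / "manifest.tsv"
    write_manifest(rows, manifest)
    tax = dataset.taxonomy
    with open(outdir / "taxonomy.tsv", "w") as fh:
        for label, node in sorted(tax.species_map.items()):
            lineage = [tax.name_of(n) for n in tax.lineage(node)]
            fh.write(f"{label}\t{';'.join(lineage)}\n")
    (outdir / "config.json").write_text(dataset.config.to_json() + "\n")
    (outdir / "species_tree.nwk").write_text(
        write_newick(dataset.species_tree) + "\n"
    )
    return manifest
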