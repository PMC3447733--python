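"""Long-branch-attraction (LBA) quartet study.

The Intra measure is a *consistency* score, so a method that fails the same
way every time still looks consistent.  The classic construction where this
matters is the Felsenstein-zone quartet ``((A,C),(B,D))`` whose pendant
branches to C and D are ``f`` times longer than the other branches: maximum
parsimony is statistically inconsistent there and converges on grouping the
two long branches together (AD-BC style pairings), while distance methods
with a proper substitution correction recover the true topology.

This module simulates such quartets (site-independent DNA evolution under
JC69 or K2P), reconstructs each one with built-in quartet builders — Fitch
parsimony, the four-point condition on Jukes-Cantor-corrected distances,
and a chi-squared k-mer statistic — and scores the Taxon and Intra measures
on the quartet class.  With quartets there are only 3 possible topologies
and any error costs RF distance exactly 1, so the Taxon measure equals the
fraction of incorrectly reconstructed quartets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cleanup import SequenceGroup, SequenceRecord
from .trees import PhyloTree, TreeValidationError, parse_newick, rf_distance

__all__ = [
    "QuartetConfig",
    "SaturatedDistanceError",
    "felsenstein_quartet",
    "simulate_alignment",
    "jc_distance",
    "quartet_topologies",
    "parsimony_quartet",
    "distance_quartet",
    "kmer_quartet",
    "lba_study",
    "LbaStudyResult",
    "QUARTET_BUILDERS",
]

_BASES = "ACGT"
# Encoding for K2P: A=0, G=1 (purines), C=2, T=3 (pyrimidines); a transition
# flips the low bit, the two transversions flip the high bit.
_BASE_INDEX = {"A": 0, "G": 1, "C": 2, "T": 3}
_INDEX_BASE = np.array(["A", "G", "C", "T"])
_FITCH_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}


class SaturatedDistanceError(ValueError):
    """A pairwise distance is saturated (mismatch fraction >= 3/4)."""


@dataclass(frozen=True)
class QuartetConfig:
    """Study conditions for the Felsenstein-zone simulation.

    ``alpha`` (the short-branch length, substitutions/site) is drawn
    uniformly from ``alpha_range`` per replicate; ``f_grid`` lists the
    long/short ratios, each used for ``n_per_f`` replicates.  The internal
    branch also has length alpha, which is what keeps the geometry inside
    the zone.
    """

    f_grid: Tuple[float, ...] = (5.0, 7.5, 10.0, 12.5, 15.0)
    alpha_range: Tuple[float, float] = (0.05, 0.2)
    seq_length: int = 1000
    model: str = "JC69"
    n_per_f: int = 100
    seed: int = 0
    kappa: float = 2.0  # K2P transition/transversion rate ratio

    def __post_init__(self):
        if min(self.f_grid) < 1:
            raise ValueError("long/short ratios f must be >= 1")
        if self.alpha_range[0] <= 0 or self.alpha_range[1] < self.alpha_range[0]:
            raise ValueError("alpha_range must be a positive interval")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.model not in ("JC69", "K2P"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def n_replicates(self) -> int:
        return len(self.f_grid) * self.n_per_f


def felsenstein_quartet(alpha: float, f: float) -> PhyloTree:
    """The quartet ((A,C),(B,D)) with long branches to C and D.

    Pendant branches to A and B and the internal branch have length
    ``alpha``; the branches to C and D have length ``f * alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if f < 1:
        raise ValueError("f must be >= 1")
    long = f * alpha
    return parse_newick(
        f"((A:{alpha!r},C:{long!r}):{alpha!r},B:{alpha!r},D:{long!r});"
    )


def _substitution_sampler(model: str, kappa: float):
    """Returns evolve(parent_states, length, rng) for one branch."""
    if model == "JC69":

        def evolve(states: np.ndarray, d: float, rng) -> np.ndarray:
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            u = rng.random(states.size)
            out = states.copy()
            hit = u < p_change
            # uniform among the three other bases
            shift = rng.integers(1, 4, size=int(hit.sum()))
            out[hit] = (out[hit] + shift) % 4
            return out

        return evolve

    def evolve_k2p(states: np.ndarray, d: float, rng) -> np.ndarray:
        # d is the expected substitutions/site: d = (alpha + 2 beta) t with
        # alpha/beta = kappa.  Closed-form K2P transition probabilities.
        bt = d / (kappa + 2.0)
        at = kappa * bt
        e1 = np.exp(-4.0 * bt)
        e2 = np.exp(-2.0 * (at + bt))
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e1  # each of the two transversions
        u = rng.random(states.size)
        out = states.copy()
        ts = u < p_ts
        tv1 = (~ts) & (u < p_ts + p_tv)
        tv2 = (~ts) & (~tv1) & (u < p_ts + 2 * p_tv)
        out[ts] ^= 1
        out[tv1] ^= 2
        out[tv2] ^= 3
        return out

    return evolve_k2p


def simulate_alignment(
    tree: PhyloTree,
    length: int,
    model: str = "JC69",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    og_id: str = "sim",
    kappa: float = 2.0,
) -> SequenceGroup:
    """Evolve DNA sequences site-independently down a tree with branch lengths.

    The root state is uniform over A/C/G/T at every site.  Identical seeds
    give byte-identical alignments.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not tree.has_branch_lengths():
        raise TreeValidationError("simulation requires branch lengths on all edges")
    evolve = _substitution_sampler(model, kappa)
    adj = tree._adj
    labels = tree._labels
    internal = tree._internal_nodes()
    root = internal[0] if internal else next(iter(adj))
    states = {root: rng.integers(0, 4, size=length)}
    out: Dict[str, np.ndarray] = {}
    if root in labels:
        out[labels[root]] = states[root]
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v, d in adj[u].items():
            if v in seen:
                continue
            seen.add(v)
            states[v] = evolve(states[u], d, rng)
            if v in labels:
                out[labels[v]] = states[v]
            else:
                stack.append(v)
    records = tuple(
        SequenceRecord(name, "".join(_INDEX_BASE[out[name]]), "dna")
        for name in sorted(out)
    )
    return SequenceGroup(og_id, records)


def jc_distance(s1: str, s2: str) -> Optional[float]:
    """Jukes-Cantor ML distance; ``None`` signals saturation (p >= 3/4)."""
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    if not s1:
        raise ValueError("empty sequences")
    p = sum(a != b for a, b in zip(s1, s2)) / len(s1)
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def quartet_topologies(labels: Sequence[str]) -> List[PhyloTree]:
    """The 3 unrooted topologies on 4 labels, as trees without lengths.

    Ordered by the partner of the first (sorted) label: for sorted labels
    w < x < y < z the pairings are wx|yz, wy|xz, wz|xy.
    """
    w, x, y, z = sorted(labels)
    return [
        parse_newick(f"(({w},{x}),({y},{z}));"),
        parse_newick(f"(({w},{y}),({x},{z}));"),
        parse_newick(f"(({w},{z}),({x},{y}));"),
    ]


def _pick_min(scores: Sequence[float], rng: Optional[np.random.Generator]):
    best = min(scores)
    idx = [i for i, s in enumerate(scores) if s <= best + 1e-12]
    if len(idx) == 1:
        return idx[0], 1
    if rng is None:
        rng = np.random.default_rng()
    return int(rng.choice(idx)), len(idx)


def parsimony_quartet(
    group: SequenceGroup, rng: Optional[np.random.Generator] = None
) -> Tuple[PhyloTree, int]:
    """Fitch parsimony over the 3 quartet topologies (equal character cost).

    Returns the minimum-score topology and the number of tied topologies
    (ties broken uniformly at random under ``rng``).
    """
    if len(group) != 4:
        raise ValueError("parsimony_quartet needs exactly 4 sequences")
    recs = sorted(group.records, key=lambda r: r.species)
    lengths = {len(r.sequence) for r in recs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    enc = [
        np.array([_FITCH_BITS.get(c, 15) for c in r.sequence.upper()], dtype=np.int8)
        for r in recs
    ]

    def fitch_score(i, j, k, l) -> int:
        u = enc[i] & enc[j]
        cost = (u == 0).astype(np.int64)
        u = np.where(u == 0, enc[i] | enc[j], u)
        v = enc[k] & enc[l]
        cost += v == 0
        v = np.where(v == 0, enc[k] | enc[l], v)
        cost += (u & v) == 0
        return int(cost.sum())

    scores = [fitch_score(0, 1, 2, 3), fitch_score(0, 2, 1, 3), fitch_score(0, 3, 1, 2)]
    topologies = quartet_topologies([r.species for r in recs])
    choice, n_tied = _pick_min(scores, rng)
    return topologies[choice], n_tied


def distance_quartet(
    dists: np.ndarray,
    labels: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PhyloTree, int]:
    """Four-point condition: the pairing minimizing the within-pair sum.

    ``dists`` is a symmetric 4x4 matrix aligned with ``labels`` sorted; a
    non-finite entry (saturated estimate) raises
    :class:`SaturatedDistanceError` so the caller can discard the replicate.
    """
    d = np.asarray(dists, dtype=float)
    if d.shape != (4, 4):
        raise ValueError("distance matrix must be 4x4")
    if not np.isfinite(d).all():
        raise SaturatedDistanceError("saturated or missing pairwise distance")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    sums = [d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]]
    topologies = quartet_topologies(labels)
    choice, n_tied = _pick_min(sums, rng)
    return topologies[choice], n_tied


def _kmer_counts(seq: str, k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_quartet(
    group: SequenceGroup, k: int = 4, rng: Optional[np.random.Generator] = None
) -> Tuple[PhyloTree, int]:
    """Quartet from chi-squared statistics on k-mer count vectors.

    The pairwise "distance" is the Pearson chi-squared statistic of the 2 x m
    contingency table of the two sequences' k-mer counts; the topology is
    then chosen by the four-point condition.  This emulates alignment-free
    composition methods (e.g. DNA tetra-mers for k=4).
    """
    if len(group) != 4:
        raise ValueError("kmer_quartet needs exactly 4 sequences")
    recs = sorted(group.records, key=lambda r: r.species)
    if any(len(r.sequence) < k for r in recs):
        raise ValueError(f"sequences shorter than k={k}")
    counts = [_kmer_counts(r.sequence.upper(), k) for r in recs]
    d = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            keys = sorted(set(counts[i]) | set(counts[j]))
            table = np.array(
                [
                    [counts[i].get(x, 0) for x in keys],
                    [counts[j].get(x, 0) for x in keys],
                ],
                dtype=float,
            )
            if np.array_equal(table[0], table[1]):
                stat = 0.0
            else:
                stat = float(
                    stats.chi2_contingency(table, correction=False).statistic
                )
            d[i, j] = d[j, i] = stat
    return distance_quartet(d, [r.species for r in recs], rng)


def _jc_builder(group: SequenceGroup, rng) -> Tuple[PhyloTree, int]:
    recs = sorted(group.records, key=lambda r: r.species)
    d = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            dist = jc_distance(recs[i].sequence, recs[j].sequence)
            d[i, j] = d[j, i] = np.nan if dist is None else dist
    return distance_quartet(d, [r.species for r in recs], rng)


QUARTET_BUILDERS: Dict[str, Callable] = {
    "parsimony": lambda g, rng: parsimony_quartet(g, rng),
    "jc_distance": _jc_builder,
    "kmer4": lambda g, rng: kmer_quartet(g, 4, rng),
}


@dataclass
class LbaStudyResult:
    """Per-method Taxon/Intra on the quartet class plus the replicate log."""

    config: QuartetConfig
    log: pd.DataFrame  # one row per (replicate, method)
    summary: pd.DataFrame  # method, taxon, intra, n, ties, discards

    def taxon(self, method: str) -> float:
        return float(
            self.summary.loc[self.summary["method"] == method, "taxon"].iloc[0]
        )

    def intra(self, method: str) -> float:
        return float(
            self.summary.loc[self.summary["method"] == method, "intra"].iloc[0]
        )


def _intra_from_choices(choices: List[int]) -> float:
    """Mean pairwise RF among inferred quartets, from topology indices.

    All replicates share the leaf set {A,B,C,D}, so the pairwise RF is 1
    when two choices differ and 0 otherwise; the mean over unordered pairs
    follows from the per-topology counts.
    """
    n = len(choices)
    if n < 2:
        return float("nan")
    total = n * (n - 1) // 2
    same = 0
    for c in set(choices):
        m = choices.count(c)
        same += m * (m - 1) // 2
    return (total - same) / total


def lba_study(
    config: QuartetConfig = QuartetConfig(),
    methods: Sequence[str] = ("parsimony", "jc_distance"),
) -> LbaStudyResult:
    """Run the Felsenstein-zone study and score each quartet builder.

    For each replicate: draw alpha, build the quartet, evolve an alignment,
    reconstruct with every method.  Taxon = fraction of incorrect
    topologies among scored replicates (the true topology plays the role of
    the taxonomic reference); Intra = mean pairwise RF between the inferred
    quartets.  Saturated-distance replicates are discarded and counted,
    never imputed.  Fully reproducible from the config seed.
    """
    for m in methods:
        if m not in QUARTET_BUILDERS:
            raise ValueError(
                f"unknown quartet builder {m!r}; available: {sorted(QUARTET_BUILDERS)}"
            )
    rng = np.random.default_rng(config.seed)
    true_split_choice = 1  # AC|BD is the wy|xz pairing of sorted(A,B,C,D)
    rows = []
    choices: Dict[str, List[int]] = {m: [] for m in methods}
    n_wrong: Dict[str, int] = {m: 0 for m in methods}
    n_scored: Dict[str, int] = {m: 0 for m in methods}
    n_ties: Dict[str, int] = {m: 0 for m in methods}
    n_disc: Dict[str, int] = {m: 0 for m in methods}
    rep = 0
    for f in config.f_grid:
        for _ in range(config.n_per_f):
            alpha = float(rng.uniform(*config.alpha_range))
            tree = felsenstein_quartet(alpha, f)
            group = simulate_alignment(
                tree,
                config.seq_length,
                model=config.model,
                rng=rng,
                og_id=f"lba{rep:04d}",
                kappa=config.kappa,
            )
            topologies = quartet_topologies(["A", "B", "C", "D"])
            for m in methods:
                row = {"replicate": rep, "f": f, "alpha": alpha, "method": m}
                try:
                    chosen, tied = QUARTET_BUILDERS[m](group, rng)
                except SaturatedDistanceError:
                    n_disc[m] += 1
                    row.update(choice=None, correct=None, tied=0, discarded=True)
                    rows.append(row)
                    continue
                idx = next(
                    i
                    for i, t in enumerate(topologies)
                    if rf_distance(t, chosen) == 0
                )
                correct = idx == true_split_choice
                choices[m].append(idx)
                n_scored[m] += 1
                n_wrong[m] += 0 if correct else 1
                if tied > 1:
                    n_ties[m] += 1
                row.update(choice=idx, correct=correct, tied=tied, discarded=False)
                rows.append(row)
            rep += 1
    summary = pd.DataFrame(
        [
            {
                "method": m,
                "taxon": n_wrong[m] / n_scored[m] if n_scored[m] else float("nan"),
                "intra": _intra_from_choices(choices[m]),
                "n": n_scored[m],
                "ties": n_ties[m],
                "discards": n_disc[m],
            }
            for m in methods
        ]
    )
    return LbaStudyResult(config, pd.DataFrame(rows), summary)
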