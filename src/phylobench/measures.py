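"""The Intra and Taxon quality measures for tree-building methods.

A *method run* is the collection of trees one method produced, one per
orthologous group (OG) of a class of species.  Two expectations summarize
its quality:

* ``Intra(M) = E[d(M(g_i), M(g_j))]`` — the mean RF distance between trees
  the method built from *different* OGs, computed over the species the two
  OGs share.  All OGs follow the same evolutionary history, so a perfect
  method yields compatible trees and Intra 0; Intra is a consistency
  measure that needs no external truth.
* ``Taxon(M) = E[d(M(g), T_g)]`` — the mean RF distance from each OG's tree
  to the taxonomy-induced reference tree on that OG's species, an
  accuracy-against-consensus measure.

Both are estimated by plain averages: Intra over all unordered OG pairs
sharing at least 4 species (optionally subsampled under an explicit cap and
seed), Taxon over all OGs.  Lower is better for both.  Absolute, relative
(divided by the maximum attainable RF) and 0-1 flavors are kept, along with
the per-OG / per-pair vectors the paired comparisons need.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTable, taxonomic_tree
from .trees import (
    PhyloTree,
    TreeValidationError,
    max_rf,
    read_newick_file,
    relative_rf,
    rf_distance,
    rf_to_reference,
    zero_one_distance,
)

__all__ = [
    "MethodRun",
    "IntraResult",
    "TaxonResult",
    "MeasureResult",
    "MultifurcationWarning",
    "pairwise_shared_distance",
    "intra_measure",
    "taxon_measure",
    "measure_method",
    "summary_table",
    "taxon_store",
    "read_manifest",
    "write_manifest",
]

MIN_SHARED_LEAVES = 4


class MultifurcationWarning(UserWarning):
    """A method tree is not fully resolved; it scores with an advantage."""


@dataclass
class MethodRun:
    """One method's trees across the OGs of a class.

    Methods are expected to produce fully resolved (binary) trees; a
    multifurcating tree is recorded in ``multifurcating`` and warned about
    (an unresolved tree makes fewer statements and therefore fewer
    mistakes — in the extreme a star tree is always "correct").  With
    ``strict=True`` such trees are rejected outright.
    """

    method_id: str
    class_id: str
    trees: Dict[str, PhyloTree]
    strict: bool = False
    multifurcating: List[str] = field(default_factory=list)

    def __post_init__(self):
        for og_id, tree in self.trees.items():
            if tree.n_leaves < 4:
                raise TreeValidationError(
                    f"{self.method_id}/{og_id}: trees need at least 4 leaves"
                )
            if not tree.is_binary():
                if self.strict:
                    raise TreeValidationError(
                        f"{self.method_id}/{og_id}: multifurcating tree rejected "
                        "in strict mode"
                    )
                self.multifurcating.append(og_id)
                warnings.warn(
                    f"{self.method_id}/{og_id}: multifurcating method tree; "
                    "it will score with an advantage",
                    MultifurcationWarning,
                    stacklevel=2,
                )

    @property
    def og_ids(self) -> List[str]:
        return sorted(self.trees)


def pairwise_shared_distance(
    t1: PhyloTree, t2: PhyloTree, min_shared: int = MIN_SHARED_LEAVES
) -> Optional[Tuple[int, float]]:
    """RF distance between two same-method trees over their shared species.

    Both trees are restricted to the intersection of their leaf sets; pairs
    sharing fewer than ``min_shared`` (default 4) species carry no topology
    signal and are excluded (returns ``None``).  The relative value divides
    by ``n_shared - 3``.
    """
    shared = t1.leaves & t2.leaves
    if len(shared) < min_shared:
        return None
    r1 = t1.restrict(shared)
    r2 = t2.restrict(shared)
    d = rf_distance(r1, r2)
    return d, d / (len(shared) - 3)


@dataclass
class IntraResult:
    method_id: str
    per_pair: Dict[Tuple[str, str], Tuple[int, float]]
    n_excluded: int
    sampled: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair)

    @property
    def abs_mean(self) -> float:
        if not self.per_pair:
            return float("nan")
        return float(np.mean([d for d, _ in self.per_pair.values()]))

    @property
    def rel_mean(self) -> float:
        if not self.per_pair:
            return float("nan")
        return float(np.mean([r for _, r in self.per_pair.values()]))


def intra_measure(
    run: MethodRun,
    max_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> IntraResult:
    """Estimate Intra(M) from all unordered OG pairs of a run.

    Enumeration is exact by default.  When ``max_pairs`` is given and the
    pair count exceeds it, a uniform subsample of pairs is drawn with the
    mandatory ``seed`` and the result is flagged as sampled.
    """
    ogs = run.og_ids
    if len(ogs) < 2:
        raise ValueError(f"{run.method_id}: Intra needs at least 2 OGs")
    pairs = list(itertools.combinations(ogs, 2))
    sampled = False
    if max_pairs is not None and len(pairs) > max_pairs:
        if seed is None:
            raise ValueError("subsampling pairs requires an explicit seed")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
        sampled = True
    per_pair: Dict[Tuple[str, str], Tuple[int, float]] = {}
    n_excluded = 0
    for gi, gj in pairs:
        res = pairwise_shared_distance(run.trees[gi], run.trees[gj])
        if res is None:
            n_excluded += 1
        else:
            per_pair[(gi, gj)] = res
    return IntraResult(run.method_id, per_pair, n_excluded, sampled)


@dataclass
class TaxonResult:
    method_id: str
    per_og: pd.DataFrame  # index og_id; columns abs, rel, zero_one; rel may be NaN

    @property
    def n_ogs(self) -> int:
        return len(self.per_og)

    @property
    def abs_mean(self) -> float:
        return float(self.per_og["abs"].mean())

    @property
    def rel_mean(self) -> float:
        # star references (max RF 0) have no defined relative distance
        return float(self.per_og["rel"].mean())

    @property
    def zero_one_mean(self) -> float:
        return float(self.per_og["zero_one"].mean())


def taxon_measure(run: MethodRun, tax: TaxonomyTable) -> TaxonResult:
    """Estimate Taxon(M): per-OG RF distances to the taxonomy reference."""
    unmapped = {
        og_id: sorted(t.leaves - set(tax.species_map))
        for og_id, t in run.trees.items()
        if t.leaves - set(tax.species_map)
    }
    if unmapped:
        raise TreeValidationError(
            f"{run.method_id}: species without taxonomy mapping in OGs {unmapped}"
        )
    rows = []
    for og_id in run.og_ids:
        tree = run.trees[og_id]
        ref = taxonomic_tree(tax, tree.leaves)
        rel = relative_rf(tree, ref)
        rows.append(
            {
                "og_id": og_id,
                "abs": rf_to_reference(tree, ref),
                "rel": np.nan if rel is None else rel,
                "zero_one": zero_one_distance(tree, ref),
                "max_rf": max_rf(tree, ref),
                "n_leaves": tree.n_leaves,
            }
        )
    frame = pd.DataFrame(rows).set_index("og_id")
    return TaxonResult(run.method_id, frame)


@dataclass
class MeasureResult:
    """Joint Intra/Taxon summary for one method (one row of the output table)."""

    method_id: str
    taxon: Optional[TaxonResult]
    intra: IntraResult

    @property
    def taxon_abs(self) -> float:
        return self.taxon.abs_mean if self.taxon else float("nan")

    @property
    def taxon_rel(self) -> float:
        return self.taxon.rel_mean if self.taxon else float("nan")

    @property
    def taxon_01(self) -> float:
        return self.taxon.zero_one_mean if self.taxon else float("nan")

    @property
    def intra_abs(self) -> float:
        return self.intra.abs_mean

    @property
    def intra_rel(self) -> float:
        return self.intra.rel_mean

    @property
    def n_ogs(self) -> int:
        return self.taxon.n_ogs if self.taxon else 0

    @property
    def n_pairs(self) -> int:
        return self.intra.n_pairs


def measure_method(
    run: MethodRun,
    tax: Optional[TaxonomyTable] = None,
    max_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> MeasureResult:
    """Compute both measures for one run (Taxon only if a taxonomy is given)."""
    intra = intra_measure(run, max_pairs=max_pairs, seed=seed)
    taxon = taxon_measure(run, tax) if tax is not None else None
    return MeasureResult(run.method_id, taxon, intra)


def summary_table(results: List[MeasureResult]) -> pd.DataFrame:
    """Per-method summary, sorted ascending by Taxon RF (lower = better).

    Columns: method, taxon_abs, taxon_rel_pct, taxon_01, intra_abs,
    intra_rel_pct.  Ties on taxon_abs break by method id for stable output.
    """
    rows = [
        {
            "method": r.method_id,
            "taxon_abs": r.taxon_abs,
            "taxon_rel_pct": 100.0 * r.taxon_rel,
            "taxon_01": r.taxon_01,
            "intra_abs": r.intra_abs,
            "intra_rel_pct": 100.0 * r.intra_rel,
            "n_ogs": r.n_ogs,
            "n_pairs": r.n_pairs,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["taxon_abs", "method"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def taxon_store(results: List[MeasureResult], flavor: str = "abs") -> pd.DataFrame:
    """Per-OG distance matrix (rows: og_id, columns: method) for comparisons."""
    cols = {}
    for r in results:
        if r.taxon is None:
            raise ValueError(f"{r.method_id}: no Taxon result to store")
        cols[r.method_id] = r.taxon.per_og[flavor]
    return pd.DataFrame(cols)


# -- manifest I/O --------------------------------------------------------------


def read_manifest(path, strict: bool = False) -> Dict[Tuple[str, str], MethodRun]:
    """Load method runs from a manifest TSV.

    Columns: class_id, method_id, og_id, newick_path (relative paths resolve
    against the manifest's directory; each file holds one tree, or the first
    tree of a multi-tree file is taken).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"class_id", "method_id", "og_id", "newick_path"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"manifest missing columns: {sorted(required - set(frame.columns))}"
        )
    if frame.empty:
        raise ValueError(f"manifest {path} lists no trees")
    runs: Dict[Tuple[str, str], MethodRun] = {}
    grouped: Dict[Tuple[str, str], Dict[str, PhyloTree]] = {}
    for row in frame.itertuples(index=False):
        tree_path = Path(row.newick_path)
        if not tree_path.is_absolute():
            tree_path = path.parent / tree_path
        trees = read_newick_file(tree_path)
        grouped.setdefault((row.class_id, row.method_id), {})[str(row.og_id)] = trees[0]
    for (class_id, method_id), trees in grouped.items():
        runs[(class_id, method_id)] = MethodRun(method_id, class_id, trees, strict)
    return runs


def write_manifest(rows: List[Tuple[str, str, str, str]], path) -> None:
    """Write a manifest TSV from (class_id, method_id, og_id, newick_path) rows."""
    frame = pd.DataFrame(
        rows, columns=["class_id", "method_id", "og_id", "newick_path"]
    )
    frame.to_csv(path, sep="\t", index=False)
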