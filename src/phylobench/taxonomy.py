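"""Taxonomy-derived reference trees.

The accuracy side of the benchmark compares each method's tree for an
orthologous group against the topology induced by an accepted taxonomy on
that group's species.  This module loads a taxonomy — either the NCBI
taxdump dialect (``nodes.dmp``/``names.dmp``) or a simple lineage TSV — and
extracts the induced reference tree for any species subset.  Induced trees
carry no branch lengths and are typically multifurcating: a taxonomy only
asserts the groupings it resolves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .trees import PhyloTree, TreeValidationError

__all__ = [
    "TaxonomyTable",
    "TaxonomyError",
    "parse_taxdump",
    "parse_lineage_tsv",
    "parse_mapping_tsv",
    "taxonomic_tree",
]


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonomyTable:
    """Parent-pointer taxonomy plus a species-label -> node mapping.

    ``nodes`` maps node id -> (parent id, rank, name).  The root is its own
    parent (NCBI dialect).  ``species_map`` maps the leaf labels used in
    trees to taxonomy node ids; it may be populated from names (unambiguous
    scientific names) or from an explicit two-column mapping TSV.
    """

    nodes: Dict[str, Tuple[str, str, str]]
    species_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        roots = [n for n, (p, _, _) in self.nodes.items() if p == n]
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for n, (p, _, _) in self.nodes.items():
            if p not in self.nodes:
                raise TaxonomyError(f"node {n} references unknown parent {p}")
        for label, n in self.species_map.items():
            if n not in self.nodes:
                raise TaxonomyError(f"species {label!r} maps to unknown node {n}")

    def lineage(self, node_id: str) -> List[str]:
        """Node ids from the root down to ``node_id`` (inclusive)."""
        path = [node_id]
        seen = {node_id}
        while True:
            parent = self.nodes[path[-1]][0]
            if parent == path[-1]:
                break
            if parent in seen:
                raise TaxonomyError(f"cycle in parent links at node {parent}")
            path.append(parent)
            seen.add(parent)
        return path[::-1]

    def name_of(self, node_id: str) -> str:
        return self.nodes[node_id][2]

    def map_species(self, mapping: Dict[str, str]) -> None:
        """Add leaf-label -> node-id entries (exact ids, no fuzzy matching)."""
        for label, n in mapping.items():
            if n not in self.nodes:
                raise TaxonomyError(f"species {label!r} maps to unknown node {n}")
            self.species_map[label] = n


def _parse_dmp_records(text: str, what: str) -> List[List[str]]:
    """Parse NCBI ``.dmp`` records: fields split by "\\t|\\t", ending "\\t|"."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.rstrip("\r").endswith("\t|"):
            raise TaxonomyError(
                f"{what} line {lineno}: record does not end with tab-pipe terminator"
            )
        body = line.rstrip("\r")[: -len("\t|")]
        records.append(body.split("\t|\t"))
    return records


def parse_taxdump(
    nodes_text: str,
    names_text: str,
    map_names_to_species: bool = True,
) -> TaxonomyTable:
    """Load an NCBI-style taxdump (``nodes.dmp`` + ``names.dmp``).

    Scientific names are preferred as node names; other name classes are
    used only when no scientific name exists.  When ``map_names_to_species``
    is set, every unambiguous name is also registered as a species label so
    small fixtures work without a separate mapping file.
    """
    nodes: Dict[str, Tuple[str, str, str]] = {}
    for lineno, rec in enumerate(_parse_dmp_records(nodes_text, "nodes.dmp"), 1):
        if len(rec) < 3:
            raise TaxonomyError(f"nodes.dmp record {lineno}: fewer than 3 fields")
        tax_id, parent_id, rank = rec[0].strip(), rec[1].strip(), rec[2].strip()
        nodes[tax_id] = (parent_id, rank, tax_id)

    names: Dict[str, str] = {}
    name_class: Dict[str, str] = {}
    for lineno, rec in enumerate(_parse_dmp_records(names_text, "names.dmp"), 1):
        if len(rec) < 4:
            raise TaxonomyError(f"names.dmp record {lineno}: fewer than 4 fields")
        tax_id, name_txt, _unique, cls = (f.strip() for f in rec[:4])
        if tax_id not in nodes:
            raise TaxonomyError(
                f"names.dmp record {lineno}: unknown tax id {tax_id}"
            )
        if tax_id not in names or (
            cls == "scientific name" and name_class.get(tax_id) != "scientific name"
        ):
            names[tax_id] = name_txt
            name_class[tax_id] = cls

    nodes = {
        n: (p, rank, names.get(n, n)) for n, (p, rank, _) in nodes.items()
    }
    table = TaxonomyTable(nodes)
    if map_names_to_species:
        by_name: Dict[str, Optional[str]] = {}
        for n, (_, _, name) in nodes.items():
            by_name[name] = None if name in by_name else n
        table.species_map.update(
            {name: n for name, n in by_name.items() if n is not None}
        )
    return table


def parse_lineage_tsv(text: str) -> TaxonomyTable:
    """Build a taxonomy from a two-column TSV: species label, lineage.

    The lineage is a semicolon-joined path from the root; shared prefixes are
    merged.  A taxon name appearing under two different parents is a
    conflict and raises an error.
    """
    nodes: Dict[str, Tuple[str, str, str]] = {"root": ("root", "no rank", "root")}
    species_map: Dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise TaxonomyError(f"lineage TSV line {lineno}: expected 2 columns")
        label, lineage = parts[0].strip(), parts[1].strip()
        taxa = [t.strip() for t in lineage.split(";") if t.strip()]
        if not taxa:
            raise TaxonomyError(f"lineage TSV line {lineno}: empty lineage")
        parent = "root"
        for name in taxa:
            if name in nodes:
                if nodes[name][0] != parent:
                    raise TaxonomyError(
                        f"lineage TSV line {lineno}: taxon {name!r} appears under "
                        f"both {nodes[name][0]!r} and {parent!r}"
                    )
            else:
                nodes[name] = (parent, "no rank", name)
            parent = name
        if label in species_map and species_map[label] != parent:
            raise TaxonomyError(
                f"lineage TSV line {lineno}: species {label!r} listed twice "
                "with different lineages"
            )
        species_map[label] = parent
    return TaxonomyTable(nodes, species_map)


def parse_mapping_tsv(text: str) -> Dict[str, str]:
    """Two-column TSV: leaf label -> taxonomy node id (or name key)."""
    mapping: Dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise TaxonomyError(f"mapping TSV line {lineno}: expected 2 columns")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def taxonomic_tree(tax: TaxonomyTable, species: Iterable[str]) -> PhyloTree:
    """The taxonomy-induced reference tree on a species set.

    The taxonomy is pruned to the given leaves and single-child chains are
    collapsed, so the result is the minimal (possibly multifurcating)
    topology the taxonomy asserts over those species.  No branch lengths.
    """
    species = list(dict.fromkeys(species))
    if len(species) < 4:
        raise TreeValidationError("taxonomic_tree requires at least 4 species")
    unmapped = sorted(s for s in species if s not in tax.species_map)
    if unmapped:
        raise TaxonomyError(f"species not mapped in the taxonomy: {unmapped}")

    # Integer ids: taxonomy nodes on the union of lineages, plus one leaf
    # node per species label (species sharing a taxon node stay distinct).
    node_ids: Dict[str, int] = {}
    adj: Dict[int, Dict[int, Optional[float]]] = {}
    labels: Dict[int, str] = {}

    def intern(tax_node: str) -> int:
        if tax_node not in node_ids:
            node_ids[tax_node] = len(node_ids)
            adj[node_ids[tax_node]] = {}
        return node_ids[tax_node]

    for s in species:
        path = tax.lineage(tax.species_map[s])
        prev: Optional[int] = None
        for tax_node in path:
            cur = intern(tax_node)
            if prev is not None and cur not in adj[prev]:
                adj[prev][cur] = None
                adj[cur][prev] = None
            prev = cur
        leaf = len(node_ids) + len(labels) + 100000
        labels[leaf] = s
        adj[leaf] = {prev: None}
        adj[prev][leaf] = None

    # Strip the root chain: unlabeled degree-1 nodes cannot exist in the
    # canonical unrooted form.
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if u not in labels and len(adj[u]) == 1:
                (v,) = adj[u]
                del adj[v][u]
                del adj[u]
                changed = True
    return PhyloTree(adj, labels)
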