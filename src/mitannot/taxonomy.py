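"""Taxonomy tree: name lookup, lowest common ancestor, reference-set filters.

The reference database can be restricted to (or purged of) the mitogenomes of
a taxonomic group. The group structure is a rooted tree in the style of the
NCBI taxonomy: every node is a taxon pointing to its direct ancestor, with
the root (origin of life) its own parent. Nodes carry the taxonomy id,
scientific name, optional synonyms and common name, and the labels of
reference mitogenomes classified under the taxon.

Given one or more query taxa, their lowest common ancestor — the shared
ancestor farthest from the root, found at the first intersection of the
root-paths — is determined, and the mitogenome labels in the subtree rooted
there are extracted. The include filter keeps exactly those genomes; the
exclude filter discards them. The two filters partition the reference set.

Both the NCBI taxdump dialect (``nodes.dmp``/``names.dmp``, fields separated
by ``\\t|\\t`` and records terminated by ``\\t|``) and a simple 4-column TSV
are read. ``merged.dmp`` ids are resolved to their replacement at load time;
ids listed in ``delnodes.dmp`` raise.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "AmbiguousTaxonError",
    "EmptyReferenceSetError",
    "load_taxonomy",
    "find_taxa",
    "lca",
    "subtree_genomes",
    "resolve_filter",
]


class TaxonomyError(ValueError):
    """Structural problem in taxonomy data or an unknown taxon."""


class AmbiguousTaxonError(TaxonomyError):
    """A filter query matched more than one taxon."""


class EmptyReferenceSetError(TaxonomyError):
    """A filter left no reference genomes; annotation cannot proceed."""


@dataclass
class TaxonNode:
    tax_id: int
    parent_id: int
    rank: str = "no rank"
    scientific_name: str = ""
    synonyms: list[str] = field(default_factory=list)
    common_name: str | None = None
    genome_labels: list[str] = field(default_factory=list)


def normalize_name(name: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(name.split()).casefold()


@dataclass
class TaxonomyTree:
    """Rooted taxon tree with a normalized-name index.

    ``name_index`` maps every normalized scientific name, synonym and common
    name to the tax_ids bearing it; ``children`` is derived from the parent
    pointers at construction.
    """

    nodes: dict[int, TaxonNode]
    root_id: int
    name_index: dict[str, set[int]] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_structure()
        if not self.name_index:
            self._build_name_index()
        if not self.children:
            self._build_children()

    def _build_name_index(self) -> None:
        for node in self.nodes.values():
            names = [node.scientific_name, *node.synonyms]
            if node.common_name:
                names.append(node.common_name)
            for name in names:
                if name:
                    self.name_index.setdefault(normalize_name(name), set()).add(node.tax_id)

    def _build_children(self) -> None:
        self.children = {tid: [] for tid in self.nodes}
        for node in self.nodes.values():
            if node.tax_id != node.parent_id:
                self.children[node.parent_id].append(node.tax_id)
        for kids in self.children.values():
            kids.sort()

    def _check_structure(self) -> None:
        roots = [t for t, n in self.nodes.items() if n.parent_id == n.tax_id]
        if roots != [self.root_id]:
            raise TaxonomyError(f"expected exactly one root {self.root_id}, found {roots}")
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"taxon {node.tax_id} has unknown parent {node.parent_id}"
                )
        # Every node must reach the root: detects cycles detached from it.
        for tid in self.nodes:
            seen = set()
            cur = tid
            while cur != self.root_id:
                if cur in seen:
                    raise TaxonomyError(f"cycle in taxonomy involving taxon {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    # -- basic queries -----------------------------------------------------

    def node(self, tax_id: int) -> TaxonNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon id: {tax_id}") from None

    def path_to_root(self, tax_id: int) -> list[int]:
        """Tax_ids from the node up to and including the root."""
        path = [tax_id]
        cur = self.node(tax_id)
        while cur.tax_id != self.root_id:
            cur = self.node(cur.parent_id)
            path.append(cur.tax_id)
        return path

    def depth(self, tax_id: int) -> int:
        return len(self.path_to_root(tax_id)) - 1

    @property
    def all_genomes(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out.update(node.genome_labels)
        return out


# -- loading ---------------------------------------------------------------

def _read_lines(source) -> list[str]:
    if isinstance(source, (str, Path)) and os.path.exists(str(source)):
        return Path(source).read_text().splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return str(source).splitlines()


def _split_record(line: str) -> list[str] | None:
    line = line.rstrip("\n")
    if not line.strip() or line.lstrip().startswith("#"):
        return None
    if "\t|" in line:  # NCBI taxdump dialect
        if line.endswith("\t|"):
            line = line[: -len("\t|")]
        return line.split("\t|\t")
    return line.split("\t")


def load_taxonomy(
    nodes_source,
    names_source=None,
    genome_taxon_map: Mapping[str, int] | str | Path | None = None,
    merged_source=None,
    delnodes_source=None,
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from taxdump-style sources.

    ``nodes_source`` rows: tax_id, parent_id, rank[, name] — the 4-column
    simple dialect carries the scientific name inline; the NCBI dialect takes
    names from ``names_source`` (name classes "scientific name", "synonym",
    "equivalent name", "common name"/"genbank common name").

    ``genome_taxon_map`` attaches reference-genome labels to taxa: a mapping
    label → tax_id, or a 2-column TSV. A genome mapped to an unknown taxon is
    an error.
    """
    merged: dict[int, int] = {}
    if merged_source is not None:
        for parts in filter(None, map(_split_record, _read_lines(merged_source))):
            merged[int(parts[0])] = int(parts[1])
    deleted: set[int] = set()
    if delnodes_source is not None:
        for parts in filter(None, map(_split_record, _read_lines(delnodes_source))):
            deleted.add(int(parts[0]))

    def resolve(tid: int) -> int:
        if tid in deleted:
            raise TaxonomyError(f"taxon {tid} is deleted (delnodes)")
        return merged.get(tid, tid)

    nodes: dict[int, TaxonNode] = {}
    for parts in filter(None, map(_split_record, _read_lines(nodes_source))):
        tid = resolve(int(parts[0]))
        parent = resolve(int(parts[1]))
        rank = parts[2].strip() if len(parts) > 2 else "no rank"
        node = TaxonNode(tax_id=tid, parent_id=parent, rank=rank)
        if len(parts) > 3 and parts[3].strip():
            node.scientific_name = parts[3].strip()
        nodes[tid] = node

    if names_source is not None:
        for parts in filter(None, map(_split_record, _read_lines(names_source))):
            tid = resolve(int(parts[0]))
            if tid not in nodes:
                raise TaxonomyError(f"names entry for unknown taxon {tid}")
            name = parts[1].strip()
            name_class = parts[3].strip() if len(parts) > 3 else "scientific name"
            node = nodes[tid]
            if name_class == "scientific name":
                node.scientific_name = name
            elif name_class in ("synonym", "equivalent name"):
                node.synonyms.append(name)
            elif name_class in ("common name", "genbank common name"):
                if node.common_name is None:
                    node.common_name = name
                else:
                    node.synonyms.append(name)

    roots = [t for t, n in nodes.items() if n.parent_id == n.tax_id]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one root, found {sorted(roots)}")
    tree = TaxonomyTree(nodes=nodes, root_id=roots[0])

    if genome_taxon_map is not None:
        if isinstance(genome_taxon_map, Mapping):
            items = list(genome_taxon_map.items())
        else:
            items = [
                (p[0], int(p[1]))
                for p in filter(None, map(_split_record, _read_lines(genome_taxon_map)))
            ]
        for label, tid in items:
            tid = resolve(int(tid))
            if tid not in tree.nodes:
                raise TaxonomyError(f"genome {label!r} mapped to unknown taxon {tid}")
            tree.nodes[tid].genome_labels.append(label)
    return tree


# -- queries ---------------------------------------------------------------

def find_taxa(tree: TaxonomyTree, query) -> list[TaxonNode]:
    """Find taxa by id or name; exact matches precede prefix matches.

    Integer queries (or digit strings) match tax_id exactly. Text queries
    match scientific names, synonyms and common names case-insensitively;
    prefix matches follow exact ones, supporting completion-style lookup.
    An unmatched query yields an empty list.
    """
    if isinstance(query, int) or (isinstance(query, str) and query.strip().isdigit()):
        tid = int(query)
        return [tree.nodes[tid]] if tid in tree.nodes else []
    q = normalize_name(str(query))
    if not q:
        return []
    exact = sorted(tree.name_index.get(q, ()))
    prefix = sorted(
        tid
        for name, tids in tree.name_index.items()
        if name.startswith(q) and name != q
        for tid in tids
        if tid not in set(exact)
    )
    return [tree.nodes[t] for t in exact] + [tree.nodes[t] for t in prefix]


def lca(tree: TaxonomyTree, tax_ids: Iterable[int]) -> TaxonNode:
    """Lowest common ancestor of a non-empty set of taxa.

    Walks each node's path to the root and takes the first intersection —
    the shared ancestor farthest from the root. A single input returns the
    node itself.
    """
    ids = list(dict.fromkeys(tax_ids))
    if not ids:
        raise TaxonomyError("lca of an empty taxon set")
    for tid in ids:
        if tid not in tree.nodes:
            raise TaxonomyError(f"unknown taxon id: {tid}")
    # Ancestor-or-self chain of the first node, ordered deepest-first.
    chain = tree.path_to_root(ids[0])
    keep = set(chain)
    for tid in ids[1:]:
        ancestors = set(tree.path_to_root(tid))
        keep &= ancestors
    for tid in chain:  # deepest surviving ancestor
        if tid in keep:
            return tree.nodes[tid]
    raise TaxonomyError("disjoint root paths: malformed tree")  # pragma: no cover


def subtree_genomes(tree: TaxonomyTree, node: TaxonNode | int) -> set[str]:
    """Union of genome labels over a node and all of its descendants."""
    tid = node.tax_id if isinstance(node, TaxonNode) else int(node)
    tree.node(tid)
    out: set[str] = set()
    stack = [tid]
    while stack:
        cur = stack.pop()
        out.update(tree.nodes[cur].genome_labels)
        stack.extend(tree.children.get(cur, ()))
    return out


def _resolve_query(tree: TaxonomyTree, query) -> TaxonNode:
    hits = find_taxa(tree, query)
    exact_names = [
        h for h in hits
        if isinstance(query, int)
        or (isinstance(query, str) and query.strip().isdigit())
        or normalize_name(str(query)) in {
            normalize_name(n)
            for n in [h.scientific_name, *(h.synonyms), h.common_name or ""]
            if n
        }
    ]
    pool = exact_names or hits
    if not pool:
        raise TaxonomyError(f"no taxon matches {query!r}")
    if len(pool) > 1:
        cands = ", ".join(f"{h.scientific_name} ({h.tax_id})" for h in pool)
        raise AmbiguousTaxonError(f"{query!r} is ambiguous: {cands}")
    return pool[0]


def resolve_filter(
    tree: TaxonomyTree,
    taxa: Iterable,
    mode: str,
    all_genomes: set[str],
) -> set[str]:
    """Resolve an include/exclude taxonomic filter to a genome-label set.

    The queries are resolved to taxa, their LCA taken, and the genome labels
    of the LCA's subtree extracted as S. ``include`` returns S ∩ all_genomes,
    ``exclude`` returns all_genomes ∖ S; the two modes partition the
    reference set. An include filter that leaves nothing raises
    :class:`EmptyReferenceSetError`.
    """
    if mode not in ("include", "exclude"):
        raise TaxonomyError(f"filter mode must be include or exclude, got {mode!r}")
    queries = list(taxa)
    if not queries:
        raise TaxonomyError("empty taxa set for filter")
    resolved = [_resolve_query(tree, q) for q in queries]
    anchor = lca(tree, [n.tax_id for n in resolved])
    selected = subtree_genomes(tree, anchor)
    if mode == "include":
        result = selected & all_genomes
        if not result:
            raise EmptyReferenceSetError(
                f"empty reference set after filtering: no genome of "
                f"{anchor.scientific_name or anchor.tax_id} in the reference database"
            )
        return result
    return all_genomes - selected
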