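"""GO ontology parsing, leaf-term filtering and function-vector averaging.

Annotated term sets are reduced to leaf terms (terms that are not proper
ancestors, via is_a/part_of, of another annotated term), each surviving term
is looked up in a precomputed term-vector table, and the vectors are averaged
within each sub-ontology. The three averages are concatenated in the fixed
(MF, CC, BP) order; with 200-dimensional term vectors this gives the
600-component function encoding. Missing sub-ontologies contribute zero
blocks so the feature layout never varies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from savpath.variant_data import ProteinRecord

logger = logging.getLogger(__name__)

NAMESPACES = ("MF", "CC", "BP")
_NAMESPACE_ALIASES = {
    "molecular_function": "MF",
    "cellular_component": "CC",
    "biological_process": "BP",
    "MF": "MF",
    "CC": "CC",
    "BP": "BP",
}
_NAMESPACE_LONG = {
    "MF": "molecular_function",
    "CC": "cellular_component",
    "BP": "biological_process",
}


class OboParseError(ValueError):
    pass


class OboCycleError(OboParseError):
    """The parsed graph is cyclic; message lists one offending cycle."""


@dataclass
class GoTermNode:
    term_id: str
    namespace: str
    obsolete: bool = False
    name: str = ""


@dataclass
class GoDag:
    """A parsed GO graph restricted to what the encoder needs.

    ``parents`` holds the is_a edges and, when parsed with part_of enabled,
    the part_of edges, always within a single namespace (cross-namespace
    edges are dropped and logged). ``alt_ids`` resolves secondary ids to
    primary ones.
    """

    nodes: dict[str, GoTermNode]
    parents: dict[str, set[str]]
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def resolve(self, term_id: str) -> str | None:
        """Resolve a possibly-secondary id to its primary id, or None."""
        if term_id in self.nodes:
            return term_id
        return self.alt_ids.get(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Proper ancestors of a term via the stored parent edges."""
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term_id, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestor_cache[term_id] = result
        return result

    def namespace_of(self, term_id: str) -> str:
        return self.nodes[term_id].namespace

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.nodes}
        for start in self.nodes:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, list[str]]] = [(start, [start])]
            # iterative DFS with an explicit path for cycle reporting
            path_stack: list[str] = []
            it_stack: list[tuple[str, Iterable[str]]] = [(start, iter(self.parents.get(start, ())))]
            color[start] = GRAY
            path_stack.append(start)
            while it_stack:
                node, it = it_stack[-1]
                advanced = False
                for parent in it:
                    if parent not in self.nodes:
                        continue
                    if color[parent] == GRAY:
                        idx = path_stack.index(parent)
                        cycle = path_stack[idx:] + [parent]
                        raise OboCycleError(
                            "ontology contains a cycle: " + " -> ".join(cycle)
                        )
                    if color[parent] == WHITE:
                        color[parent] = GRAY
                        path_stack.append(parent)
                        it_stack.append((parent, iter(self.parents.get(parent, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    path_stack.pop()
                    it_stack.pop()


def parse_obo(path: str | Path, use_part_of: bool = True) -> GoDag:
    """Parse the OBO subset used here: id, name, namespace, is_a,
    relationship: part_of, is_obsolete, alt_id.

    Obsolete terms are retained but flagged; alt_ids resolve to primary ids;
    cross-namespace edges are dropped with a log entry. A cyclic graph raises
    :class:`OboCycleError` naming one cycle.
    """
    nodes: dict[str, GoTermNode] = {}
    parents: dict[str, set[str]] = {}
    alt_ids: dict[str, str] = {}
    raw_edges: list[tuple[str, str]] = []

    current: dict[str, object] | None = None
    in_term = False

    def flush() -> None:
        nonlocal current
        if not in_term or current is None or "id" not in current:
            current = None
            return
        tid = str(current["id"])
        ns_raw = str(current.get("namespace", ""))
        ns = _NAMESPACE_ALIASES.get(ns_raw)
        if ns is None:
            raise OboParseError(f"term {tid}: unknown namespace {ns_raw!r}")
        nodes[tid] = GoTermNode(
            term_id=tid,
            namespace=ns,
            obsolete=bool(current.get("obsolete", False)),
            name=str(current.get("name", "")),
        )
        for alt in current.get("alt_ids", []):  # type: ignore[union-attr]
            alt_ids[str(alt)] = tid
        for parent in current.get("parents", []):  # type: ignore[union-attr]
            raw_edges.append((tid, str(parent)))
        current = None

    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                current = {"alt_ids": [], "parents": []} if in_term else None
                continue
            if current is None or not line:
                continue
            if line.startswith("id:"):
                current["id"] = line[3:].strip()
            elif line.startswith("name:"):
                current["name"] = line[5:].strip()
            elif line.startswith("namespace:"):
                current["namespace"] = line[10:].strip()
            elif line.startswith("alt_id:"):
                current["alt_ids"].append(line[7:].strip())  # type: ignore[union-attr]
            elif line.startswith("is_a:"):
                current["parents"].append(line[5:].strip().split("!")[0].strip())  # type: ignore[union-attr]
            elif line.startswith("relationship:"):
                rest = line[len("relationship:"):].strip()
                parts = rest.split("!")[0].split()
                if len(parts) >= 2 and parts[0] == "part_of" and use_part_of:
                    current["parents"].append(parts[1])  # type: ignore[union-attr]
            elif line.startswith("is_obsolete:"):
                current["obsolete"] = line[len("is_obsolete:"):].strip() == "true"
        flush()

    for child, parent in raw_edges:
        if parent not in nodes:
            logger.warning("dropping edge %s -> %s: unknown parent", child, parent)
            continue
        if nodes[child].namespace != nodes[parent].namespace:
            logger.warning(
                "dropping cross-namespace edge %s (%s) -> %s (%s)",
                child, nodes[child].namespace, parent, nodes[parent].namespace,
            )
            continue
        parents.setdefault(child, set()).add(parent)

    dag = GoDag(nodes=nodes, parents=parents, alt_ids=alt_ids)
    dag._check_acyclic()
    return dag


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a DAG back to the OBO subset (round-trip with parse_obo)."""
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\n")
        for tid in sorted(dag.nodes):
            node = dag.nodes[tid]
            handle.write(f"\n[Term]\nid: {tid}\n")
            if node.name:
                handle.write(f"name: {node.name}\n")
            handle.write(f"namespace: {_NAMESPACE_LONG[node.namespace]}\n")
            for alt, primary in sorted(dag.alt_ids.items()):
                if primary == tid:
                    handle.write(f"alt_id: {alt}\n")
            for parent in sorted(dag.parents.get(tid, ())):
                handle.write(f"is_a: {parent}\n")
            if node.obsolete:
                handle.write("is_obsolete: true\n")


def leaf_filter(terms: Iterable[str], dag: GoDag) -> set[str]:
    """Drop every term that is a proper ancestor of another term in the set.

    Applied independently within each namespace. Unknown terms are excluded
    with a log entry rather than raising; alt ids are resolved first.
    """
    resolved: set[str] = set()
    for t in terms:
        primary = dag.resolve(t)
        if primary is None:
            logger.warning("leaf_filter: unknown term %s excluded", t)
            continue
        resolved.add(primary)
    by_ns: dict[str, set[str]] = {}
    for t in resolved:
        by_ns.setdefault(dag.namespace_of(t), set()).add(t)
    keep: set[str] = set()
    for ns_terms in by_ns.values():
        ancestors_of_set: set[str] = set()
        for t in ns_terms:
            ancestors_of_set |= dag.ancestors(t)
        keep |= {t for t in ns_terms if t not in ancestors_of_set}
    return keep


@dataclass
class TermVectorTable:
    """Precomputed GO-term embedding vectors, all of one length."""

    vectors: dict[str, np.ndarray]
    dim: int

    @classmethod
    def from_mapping(cls, vectors: Mapping[str, Sequence[float]]) -> "TermVectorTable":
        arrays = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        dims = {a.shape[0] for a in arrays.values()}
        if len(dims) > 1:
            raise ValueError(f"term vectors have inconsistent lengths: {sorted(dims)}")
        dim = dims.pop() if dims else 200
        return cls(vectors=arrays, dim=dim)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.vectors

    def __getitem__(self, term_id: str) -> np.ndarray:
        return self.vectors[term_id]


def read_term_vectors(path: str | Path) -> TermVectorTable:
    """Tab-separated ``go_id  v1 ... vD`` (no header)."""
    vectors: dict[str, list[float]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"line {lineno}: expected go_id plus values")
            vectors[cols[0]] = [float(x) for x in cols[1:]]
    return TermVectorTable.from_mapping(vectors)


def write_term_vectors(table: TermVectorTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        for tid in sorted(table.vectors):
            vals = "\t".join(format(x, ".8g") for x in table.vectors[tid])
            handle.write(f"{tid}\t{vals}\n")


def read_annotations(path: str | Path, dag: GoDag) -> dict[str, dict[str, frozenset[str]]]:
    """Read ``accession<TAB>go_id`` (or semicolon-separated id lists) into
    per-sub-ontology term sets keyed by accession. Namespaces come from the
    DAG; unknown terms are logged and skipped."""
    per_acc: dict[str, dict[str, set[str]]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns, got {len(cols)}")
            acc, terms_s = cols
            for term in (t for t in terms_s.split(";") if t):
                primary = dag.resolve(term)
                if primary is None:
                    logger.warning("line %d: unknown GO term %s skipped", lineno, term)
                    continue
                ns = dag.namespace_of(primary)
                per_acc.setdefault(acc, {}).setdefault(ns, set()).add(primary)
    return {
        acc: {ns: frozenset(terms) for ns, terms in ns_map.items()}
        for acc, ns_map in per_acc.items()
    }


def write_annotations(
    annotations: Mapping[str, Mapping[str, frozenset[str]]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for acc in sorted(annotations):
            terms = sorted(t for ns in annotations[acc].values() for t in ns)
            if terms:
                handle.write(f"{acc}\t{';'.join(terms)}\n")


@dataclass
class FunctionEncoding:
    """Concatenated per-sub-ontology average vectors in (MF, CC, BP) order."""

    values: np.ndarray
    block_dim: int

    def __len__(self) -> int:
        return self.values.shape[0]

    def block(self, namespace: str) -> np.ndarray:
        idx = NAMESPACES.index(namespace)
        return self.values[idx * self.block_dim : (idx + 1) * self.block_dim]


def encode_go(protein: ProteinRecord, dag: GoDag, table: TermVectorTable) -> FunctionEncoding:
    """Average leaf-term vectors per sub-ontology and concatenate.

    Per namespace: resolve and leaf-filter the annotated terms, drop obsolete
    terms and terms absent from the vector table (logged), then take the
    arithmetic mean of the remaining vectors; an empty remainder yields a
    zero block so the output length is always 3 x table dimension.
    """
    blocks: list[np.ndarray] = []
    for ns in NAMESPACES:
        annotated = protein.go_terms.get(ns, frozenset())
        leaves = leaf_filter(annotated, dag)
        vectors = []
        for t in sorted(leaves):
            if dag.nodes[t].obsolete:
                logger.warning("%s: obsolete term %s dropped", protein.accession, t)
                continue
            if t not in table:
                logger.warning("%s: term %s missing from vector table", protein.accession, t)
                continue
            vectors.append(table[t])
        if vectors:
            blocks.append(np.mean(vectors, axis=0))
        else:
            blocks.append(np.zeros(table.dim))
    return FunctionEncoding(values=np.concatenate(blocks), block_dim=table.dim)
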