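"""Similarity clustering and homology-aware fold assignment.

Proteins linked by a retained similarity edge (identity >= 25% at alignment
coverage >= 40% by default) must never be split across cross-validation
folds, so clusters are the connected components of the similarity graph and
whole clusters are assigned to the blind set or to one of k folds.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from savpath.variant_data import Label, ProteinRecord, VariantRecord

BLIND = "BLIND"

DEFAULT_MIN_IDENTITY = 0.25
DEFAULT_MIN_COVERAGE = 0.40


@dataclass(frozen=True)
class SimilarityEdge:
    accession_a: str
    accession_b: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if self.accession_a == self.accession_b:
            raise ValueError(f"self-edge on {self.accession_a}")


@dataclass
class ClusterAssignment:
    """Mapping accession -> cluster id; ids are contiguous from 0.

    Cluster ids are assigned deterministically by the lexicographically
    smallest member accession.
    """

    mapping: dict[str, int]

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for acc, cid in self.mapping.items():
            out[cid].append(acc)
        return {cid: sorted(accs) for cid, accs in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values()))


@dataclass
class FoldAssignment:
    """Mapping cluster id -> fold name (``BLIND`` or ``F1``..``Fk``)."""

    mapping: dict[int, str]
    seed: int
    k: int = 10

    def fold_of_accession(self, clusters: ClusterAssignment) -> dict[str, str]:
        return {acc: self.mapping[cid] for acc, cid in clusters.mapping.items()}

    @property
    def fold_names(self) -> list[str]:
        return [BLIND] + [f"F{i}" for i in range(1, self.k + 1)]


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}
        self.rank = {x: 0 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def connected_components(
    accessions: Sequence[str], edges: Sequence[SimilarityEdge]
) -> ClusterAssignment:
    """Union-find connected components; isolated accessions become singletons."""
    known = set(accessions)
    uf = _UnionFind(accessions)
    for e in edges:
        if e.accession_a not in known or e.accession_b not in known:
            raise ValueError(
                f"edge ({e.accession_a}, {e.accession_b}) references an unknown accession"
            )
        uf.union(e.accession_a, e.accession_b)
    groups: dict[str, list[str]] = defaultdict(list)
    for acc in accessions:
        groups[uf.find(acc)].append(acc)
    # deterministic ids: order components by their smallest member accession
    ordered = sorted(groups.values(), key=min)
    mapping: dict[str, int] = {}
    for cid, members in enumerate(ordered):
        for acc in members:
            mapping[acc] = cid
    return ClusterAssignment(mapping=mapping)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Best local alignment of two sequences -> (identity, coverage).

    identity = identical pairs / aligned columns (gaps included);
    coverage  = aligned span on the shorter sequence / shorter length.
    """
    aligner = _make_aligner()
    alignments = aligner.align(seq_a, seq_b)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    span_a = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    span_b = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    if len(seq_a) <= len(seq_b):
        coverage = span_a / len(seq_a)
    else:
        coverage = span_b / len(seq_b)
    return identity, coverage


def build_edges(
    proteins: Sequence[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[SimilarityEdge]:
    """All-vs-all pairwise alignment edge construction (toy/test scale only).

    For real-scale datasets supply a precomputed edge file (from any fast
    clustering tool) via :func:`read_edge_file` instead.
    """
    edges: list[SimilarityEdge] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            identity, coverage = align_pair(proteins[i].sequence, proteins[j].sequence)
            if identity >= min_identity and coverage >= min_coverage:
                edges.append(
                    SimilarityEdge(
                        accession_a=proteins[i].accession,
                        accession_b=proteins[j].accession,
                        identity=identity,
                        coverage=coverage,
                    )
                )
    return edges


def assign_folds(
    clusters: ClusterAssignment,
    variants: Sequence[VariantRecord],
    blind_fraction: float = 0.10,
    k: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Greedy balanced assignment of whole clusters to BLIND + k folds.

    Clusters are taken largest variant-count first (seeded shuffle breaks
    ties) and each goes to the bin whose deviation from its target (total
    variant count and pathogenic count, both proportional to the bin's
    fraction of the data) is smallest after the addition. The blind bin's
    target fraction is ``blind_fraction``; each fold targets
    ``(1 - blind_fraction) / k``. Clusters are never split.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not (0.0 < blind_fraction < 0.5):
        raise ValueError(f"blind_fraction must be in (0, 0.5), got {blind_fraction}")

    counts: dict[int, int] = defaultdict(int)
    plp_counts: dict[int, int] = defaultdict(int)
    for v in variants:
        cid = clusters.mapping.get(v.protein_accession)
        if cid is None:
            raise ValueError(f"variant protein {v.protein_accession} has no cluster")
        counts[cid] += 1
        if v.label is Label.PLP:
            plp_counts[cid] += 1
    all_cids = sorted(set(clusters.mapping.values()))
    total = sum(counts.values())
    total_plp = sum(plp_counts.values())

    # canonical order (largest first, then smallest member accession), then a
    # seeded shuffle within equal-count groups so ties are randomized but the
    # result is independent of input ordering
    members = clusters.members()
    canonical = sorted(all_cids, key=lambda c: (-counts[c], members[c][0]))
    rng = random.Random(seed)
    shuffled: list[int] = []
    i = 0
    while i < len(canonical):
        j = i
        while j < len(canonical) and counts[canonical[j]] == counts[canonical[i]]:
            j += 1
        group = canonical[i:j]
        rng.shuffle(group)
        shuffled.extend(group)
        i = j

    fold_names = [BLIND] + [f"F{i}" for i in range(1, k + 1)]
    fractions = {BLIND: blind_fraction}
    for name in fold_names[1:]:
        fractions[name] = (1.0 - blind_fraction) / k
    bin_total = {name: 0 for name in fold_names}
    bin_plp = {name: 0 for name in fold_names}

    mapping: dict[int, str] = {}
    for cid in shuffled:
        best_name, best_score = None, None
        for name in fold_names:
            # worst per-class fill ratio relative to the bin's target: the
            # bin whose most-filled class stays lowest takes the cluster,
            # which keeps every bin near its target size and label balance
            ratios = []
            if total_plp > 0:
                t_plp = fractions[name] * total_plp
                ratios.append((bin_plp[name] + plp_counts[cid]) / t_plp)
            if total - total_plp > 0:
                t_blb = fractions[name] * (total - total_plp)
                blb_count = counts[cid] - plp_counts[cid]
                ratios.append((bin_total[name] - bin_plp[name] + blb_count) / t_blb)
            score = max(ratios) if ratios else 0.0
            if best_score is None or score < best_score:
                best_name, best_score = name, score
        assert best_name is not None
        mapping[cid] = best_name
        bin_total[best_name] += counts[cid]
        bin_plp[best_name] += plp_counts[cid]
    return FoldAssignment(mapping=mapping, seed=seed, k=k)


def audit_leakage(
    folds: FoldAssignment,
    edges: Sequence[SimilarityEdge],
    clusters: ClusterAssignment,
) -> list[SimilarityEdge]:
    """Return every similarity edge whose endpoints sit in different folds."""
    crossing = []
    for e in edges:
        fa = folds.mapping[clusters.mapping[e.accession_a]]
        fb = folds.mapping[clusters.mapping[e.accession_b]]
        if fa != fb:
            crossing.append(e)
    return crossing


# --- file formats -----------------------------------------------------------


def read_edge_file(path: str | Path) -> list[SimilarityEdge]:
    """Tab-separated ``accession_a  accession_b  identity  coverage``."""
    edges = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(cols)}")
            edges.append(
                SimilarityEdge(cols[0], cols[1], float(cols[2]), float(cols[3]))
            )
    return edges


def write_edge_file(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    with open(path, "w") as handle:
        for e in edges:
            handle.write(f"{e.accession_a}\t{e.accession_b}\t{e.identity:.4f}\t{e.coverage:.4f}\n")


def write_cluster_file(clusters: ClusterAssignment, path: str | Path) -> None:
    """Tab-separated ``accession  cluster_id``."""
    with open(path, "w") as handle:
        handle.write("accession\tcluster_id\n")
        for acc in sorted(clusters.mapping):
            handle.write(f"{acc}\t{clusters.mapping[acc]}\n")


def read_cluster_file(path: str | Path) -> ClusterAssignment:
    mapping: dict[str, int] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["accession", "cluster_id"]:
            raise ValueError(f"unexpected cluster-file header: {header}")
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            acc, cid = line.split("\t")
            mapping[acc] = int(cid)
    return ClusterAssignment(mapping=mapping)


def write_fold_file(
    folds: FoldAssignment, clusters: ClusterAssignment, path: str | Path
) -> None:
    """Tab-separated ``accession  cluster_id  fold``."""
    with open(path, "w") as handle:
        handle.write("accession\tcluster_id\tfold\n")
        for acc in sorted(clusters.mapping):
            cid = clusters.mapping[acc]
            handle.write(f"{acc}\t{cid}\t{folds.mapping[cid]}\n")


def read_fold_file(path: str | Path) -> tuple[ClusterAssignment, dict[str, str]]:
    """Read the fold file back into cluster and accession->fold mappings."""
    cluster_map: dict[str, int] = {}
    fold_map: dict[str, str] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["accession", "cluster_id", "fold"]:
            raise ValueError(f"unexpected fold-file header: {header}")
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            acc, cid, fold = line.split("\t")
            cluster_map[acc] = int(cid)
            fold_map[acc] = fold
    return ClusterAssignment(mapping=cluster_map), fold_map
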