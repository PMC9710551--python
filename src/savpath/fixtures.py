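"""Self-contained synthetic inputs with controllable class signal.

Generates toy proteins, variants, a small three-namespace GO DAG, a term
vector table and mock embedding backends. Class signal is injected two ways:

* ``embedding_separation`` shifts the mock backends' output at the variant
  position of pathogenic variant sequences by a fixed vector of that length
  (in pooled-standard-deviation units) lying in a random 10-D subspace of
  the embedding space, so PCA retains it;
* ``go_signal`` is the probability that a protein's GO terms are drawn from
  a label-biased leaf pool instead of uniformly, making the averaged GO
  block informative in proportion to it.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from savpath.embeddings import MockBackend, apply_substitution
from savpath.go_encoding import (
    GoDag,
    GoTermNode,
    TermVectorTable,
    encode_go,
    write_annotations,
    write_obo,
    write_term_vectors,
)
from savpath.embeddings import encode_variant_positional
from savpath.predictor import FeatureVector, assemble_features
from savpath.variant_data import (
    Label,
    ProteinRecord,
    Source,
    VariantRecord,
    write_fasta,
    write_variant_table,
)

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 50
    mean_length: int = 60
    n_variants: int = 200
    plp_fraction: float = 0.5
    embedding_separation: float = 0.0
    go_signal: float = 0.0
    seed: int = 0
    esm_dim: int = 24
    t5_dim: int = 16
    go_dim: int = 8

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.mean_length, self.n_variants) < 1:
            raise ValueError("counts must be positive")
        for frac in (self.plp_fraction, self.go_signal):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    proteins: list[ProteinRecord]
    variants: list[VariantRecord]
    dag: GoDag
    table: TermVectorTable
    backends: tuple[MockBackend, MockBackend]
    contaminants: list[VariantRecord] = field(default_factory=list)

    @property
    def protein_map(self) -> dict[str, ProteinRecord]:
        return {p.accession: p for p in self.proteins}


def make_toy_dag() -> GoDag:
    """A 30-node DAG: per namespace one root, three mids, six leaves."""
    nodes: dict[str, GoTermNode] = {}
    parents: dict[str, set[str]] = {}
    for ns_index, ns in enumerate(("MF", "CC", "BP")):
        base = (ns_index + 1) * 1000000
        root = f"GO:{base:07d}"
        nodes[root] = GoTermNode(root, ns, name=f"{ns} root")
        mids = [f"GO:{base + m:07d}" for m in (1, 2, 3)]
        for mid in mids:
            nodes[mid] = GoTermNode(mid, ns)
            parents[mid] = {root}
        for li, leaf_offset in enumerate((4, 5, 6, 7, 8, 9)):
            leaf = f"GO:{base + leaf_offset:07d}"
            nodes[leaf] = GoTermNode(leaf, ns)
            parents[leaf] = {mids[li % 3]}
    return GoDag(nodes=nodes, parents=parents)


def _leaf_pools(dag: GoDag) -> dict[str, tuple[list[str], list[str]]]:
    """Per namespace: (pathogenic-pool leaves, benign-pool leaves)."""
    pools = {}
    for ns_index, ns in enumerate(("MF", "CC", "BP")):
        base = (ns_index + 1) * 1000000
        patho = [f"GO:{base + o:07d}" for o in (4, 5, 6)]
        benign = [f"GO:{base + o:07d}" for o in (7, 8, 9)]
        pools[ns] = (patho, benign)
    return pools


def _make_term_table(dag: GoDag, go_dim: int, rng: np.random.Generator) -> TermVectorTable:
    pools = _leaf_pools(dag)
    directions = {ns: _unit(rng.normal(size=go_dim)) for ns in pools}
    vectors: dict[str, np.ndarray] = {}
    for tid, node in dag.nodes.items():
        vectors[tid] = rng.normal(0.0, 0.3, size=go_dim)
    for ns, (patho, benign) in pools.items():
        for t in patho:
            vectors[t] = vectors[t] + directions[ns]
        for t in benign:
            vectors[t] = vectors[t] - directions[ns]
    return TermVectorTable(vectors=vectors, dim=go_dim)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _class_shift(dim: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """A vector of length separation * sigma lying in a random 10-D subspace."""
    subspace_dim = min(10, dim)
    basis, _ = np.linalg.qr(rng.normal(size=(dim, subspace_dim)))
    direction = _unit(basis @ _unit(rng.normal(size=subspace_dim)))
    sigma = 1.0 / np.sqrt(3.0)  # per-coordinate std of the uniform(-1, 1) mock
    return separation * sigma * direction


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    rng = np.random.default_rng(spec.seed)
    dag = make_toy_dag()
    table = _make_term_table(dag, spec.go_dim, rng)
    pools = _leaf_pools(dag)

    # sequences
    lengths = rng.integers(
        max(20, int(spec.mean_length * 0.75)),
        int(spec.mean_length * 1.25) + 1,
        size=spec.n_proteins,
    )
    raw_proteins = [
        ProteinRecord(
            accession=f"SP{i:05d}",
            sequence="".join(rng.choice(list(_RESIDUES), size=length)),
        )
        for i, length in enumerate(lengths)
    ]

    # exact label counts, hosted on disjoint protein subsets so a protein's
    # annotation can be biased toward the label of its variants
    n_plp = round(spec.plp_fraction * spec.n_variants)
    n_blb = spec.n_variants - n_plp
    order = rng.permutation(spec.n_proteins)
    if n_plp == 0:
        n_plp_hosts = 0
    elif n_blb == 0:
        n_plp_hosts = spec.n_proteins
    else:
        n_plp_hosts = min(
            spec.n_proteins - 1, max(1, round(spec.n_proteins * n_plp / spec.n_variants))
        )
    plp_hosts = [raw_proteins[i] for i in order[:n_plp_hosts]]
    blb_hosts = [raw_proteins[i] for i in order[n_plp_hosts:]]
    host_label = {p.accession: Label.PLP for p in plp_hosts}
    host_label.update({p.accession: Label.BLB for p in blb_hosts})

    backend1 = MockBackend("mockA", spec.esm_dim, seed_salt=f"A{spec.seed}")
    backend2 = MockBackend("mockB", spec.t5_dim, seed_salt=f"B{spec.seed}")
    shift1 = _class_shift(spec.esm_dim, spec.embedding_separation, rng)
    shift2 = _class_shift(spec.t5_dim, spec.embedding_separation, rng)

    variants: list[VariantRecord] = []
    used: set[tuple[str, int, str]] = set()

    def draw_variant(host: ProteinRecord, label: Label) -> VariantRecord:
        for _ in range(200):
            pos = int(rng.integers(1, len(host.sequence) + 1))
            wt = host.sequence[pos - 1]
            mut = str(rng.choice([r for r in _RESIDUES if r != wt]))
            if (host.accession, pos, mut) not in used:
                break
        used.add((host.accession, pos, mut))
        return VariantRecord(
            protein_accession=host.accession,
            position=pos,
            wt_residue=wt,
            mut_residue=mut,
            label=label,
            disease_ids=frozenset({"OMIM:600001"}) if label is Label.PLP else frozenset(),
            source=Source.OTHER,
        )

    for i in range(n_plp):
        variants.append(draw_variant(plp_hosts[i % len(plp_hosts)], Label.PLP))
    for i in range(n_blb):
        variants.append(draw_variant(blb_hosts[i % len(blb_hosts)], Label.BLB))

    # inject the embedding-space class shift at pathogenic variant positions
    if spec.embedding_separation > 0:
        for v in variants:
            if v.label is not Label.PLP:
                continue
            host = next(p for p in raw_proteins if p.accession == v.protein_accession)
            mut_seq = apply_substitution(host.sequence, v.position, v.wt_residue, v.mut_residue)
            backend1.signal_map.setdefault(mut_seq, []).append((v.position - 1, shift1))
            backend2.signal_map.setdefault(mut_seq, []).append((v.position - 1, shift2))

    # label-biased GO annotation
    proteins: list[ProteinRecord] = []
    for p in raw_proteins:
        label = host_label.get(p.accession)
        go_terms: dict[str, frozenset[str]] = {}
        for ns, (patho_pool, benign_pool) in pools.items():
            n_terms = int(rng.integers(1, 4))
            biased = label is not None and rng.random() < spec.go_signal
            if biased:
                pool = patho_pool if label is Label.PLP else benign_pool
            else:
                pool = patho_pool + benign_pool
            chosen = rng.choice(pool, size=min(n_terms, len(pool)), replace=False)
            go_terms[ns] = frozenset(str(t) for t in chosen)
        proteins.append(p.with_go_terms(go_terms))

    return FixtureBundle(
        spec=spec,
        proteins=proteins,
        variants=variants,
        dag=dag,
        table=table,
        backends=(backend1, backend2),
    )


def encode_bundle(
    bundle: FixtureBundle,
) -> tuple[np.ndarray, list[Label], list[tuple[str, int]]]:
    """Encode every variant of a bundle into the feature matrix."""
    protein_map = bundle.protein_map
    rows: list[FeatureVector] = []
    go_cache: dict[str, np.ndarray] = {}
    layout: list[tuple[str, int]] | None = None
    for v in bundle.variants:
        protein = protein_map[v.protein_accession]
        pos_enc = encode_variant_positional(protein.sequence, v, bundle.backends)
        func = encode_go(protein, bundle.dag, bundle.table)
        fv = assemble_features(pos_enc, func)
        rows.append(fv)
        if layout is None:
            layout = fv.layout
    X = np.stack([fv.values for fv in rows])
    return X, [v.label for v in bundle.variants], layout or []


def make_smoke_bundle(seed: int) -> FixtureBundle:
    """A small end-to-end bundle (~50 proteins / 500 variants) that also
    carries contaminant records (uncertain, somatic, conflicting, duplicate,
    unlinked-to-disease) so the curation stage has work to do."""
    bundle = make_fixture(
        FixtureSpec(
            n_proteins=50,
            mean_length=80,
            n_variants=500,
            plp_fraction=0.4,
            embedding_separation=2.0,
            go_signal=0.5,
            seed=seed,
        )
    )
    rng = np.random.default_rng(seed + 1)
    hosts = bundle.proteins
    contaminants: list[VariantRecord] = []

    def pick_site(host: ProteinRecord) -> tuple[int, str, str]:
        pos = int(rng.integers(1, len(host.sequence) + 1))
        wt = host.sequence[pos - 1]
        mut = str(rng.choice([r for r in _RESIDUES if r != wt]))
        return pos, wt, mut

    for i in range(5):  # uncertain significance
        host = hosts[int(rng.integers(len(hosts)))]
        pos, wt, mut = pick_site(host)
        contaminants.append(VariantRecord(host.accession, pos, wt, mut, Label.US))
    for i in range(5):  # somatic
        host = hosts[int(rng.integers(len(hosts)))]
        pos, wt, mut = pick_site(host)
        contaminants.append(
            VariantRecord(host.accession, pos, wt, mut, Label.BLB, somatic=True)
        )
    for i in range(3):  # pathogenic without a disease association
        host = hosts[int(rng.integers(len(hosts)))]
        pos, wt, mut = pick_site(host)
        contaminants.append(VariantRecord(host.accession, pos, wt, mut, Label.PLP))
    # conflicting pair and a concordant duplicate of existing variants
    first = bundle.variants[0]
    opposite = Label.BLB if first.label is Label.PLP else Label.PLP
    contaminants.append(
        VariantRecord(
            first.protein_accession, first.position, first.wt_residue, first.mut_residue,
            opposite,
            disease_ids=frozenset({"OMIM:600002"}) if opposite is Label.PLP else frozenset(),
            source=Source.CLINVAR,
        )
    )
    second = bundle.variants[1]
    contaminants.append(
        VariantRecord(
            second.protein_accession, second.position, second.wt_residue,
            second.mut_residue, second.label,
            disease_ids=second.disease_ids, source=Source.HUMSAVAR,
        )
    )
    bundle.contaminants = contaminants
    return bundle


def write_precomputed_embeddings(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Export the mock backends' matrices (signal included) as npz stores
    keyed by sequence hash, consumable by the precomputed CLI backend."""
    from savpath.embeddings import PrecomputedBackend

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = {p.sequence for p in bundle.proteins}
    for v in list(bundle.variants) + list(bundle.contaminants):
        host = bundle.protein_map[v.protein_accession]
        sequences.add(apply_substitution(host.sequence, v.position, v.wt_residue, v.mut_residue))
    paths = {}
    for backend in bundle.backends:
        store = {
            PrecomputedBackend.sequence_key(seq): backend.embed(seq) for seq in sequences
        }
        path = outdir / f"{backend.name}.npz"
        np.savez(path, **store)
        paths[backend.name] = path
    return paths


def write_fixture_files(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the same formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "variants": outdir / "variants.tsv",
        "obo": outdir / "go.obo",
        "annotations": outdir / "annotations.tsv",
        "vectors": outdir / "term_vectors.tsv",
    }
    write_fasta(bundle.proteins, paths["fasta"])
    write_variant_table(list(bundle.variants) + list(bundle.contaminants), paths["variants"])
    write_obo(bundle.dag, paths["obo"])
    write_annotations({p.accession: p.go_terms for p in bundle.proteins}, paths["annotations"])
    write_term_vectors(bundle.table, paths["vectors"])
    return paths
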