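"""Per-residue embedding backends and positional variant encoding.

A backend maps a sequence of length L to an L x D real matrix. The variant
encoding embeds the wild-type and the substituted sequence with two backends
and concatenates the rows at the variant position in the fixed block order
(backend-1 variant, backend-1 wild-type, backend-2 variant, backend-2
wild-type); with the default backend dimensions (1280, 1024) this yields a
4608-component vector.

Backends with a bounded input length (1024 residues for the default primary
backend) trigger a 201-residue window centred on the variant position; the
window is shifted, never truncated, at the termini so the backend always sees
a constant-size input when the sequence is long enough.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from savpath.variant_data import VariantRecord

DEFAULT_WINDOW = 201
ESM_DIM = 1280
T5_DIM = 1024
ESM_MAX_LENGTH = 1024


class BackendError(RuntimeError):
    """An embedding backend failed; message carries backend and context."""


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract for per-residue embedding backends.

    ``embed`` must be deterministic: equal sequences give equal matrices.
    ``max_length`` is None for backends without a hard input-length limit.
    """

    name: str
    dim: int
    max_length: int | None

    def embed(self, sequence: str) -> np.ndarray: ...


def extract_window(
    sequence: str,
    position: int,
    max_length: int | None,
    window: int = DEFAULT_WINDOW,
) -> tuple[str, int]:
    """Return the subsequence seen by a length-limited backend.

    If the sequence fits in ``max_length`` (or the backend is unbounded) it is
    returned unchanged. Otherwise a ``window``-residue stretch centred on the
    1-based ``position`` is cut out, shifting at the termini so the full
    window length is kept whenever the sequence allows it. The returned
    position is 1-based within the subsequence.
    """
    length = len(sequence)
    if not (1 <= position <= length):
        raise ValueError(f"position {position} out of range 1..{length}")
    if max_length is None or length <= max_length:
        return sequence, position
    if length <= window:
        return sequence, position
    half = window // 2
    start = position - half  # 1-based
    end = position + (window - 1 - half)
    if start < 1:
        start, end = 1, window
    elif end > length:
        start, end = length - window + 1, length
    return sequence[start - 1 : end], position - start + 1


def apply_substitution(sequence: str, position: int, wt: str, mut: str) -> str:
    """Apply a single substitution (1-based), validating the wild-type residue."""
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} out of range 1..{len(sequence)}")
    if sequence[position - 1] != wt:
        raise ValueError(
            f"position {position} holds {sequence[position - 1]!r}, expected {wt!r}"
        )
    return sequence[: position - 1] + mut + sequence[position:]


@dataclass
class MockBackend:
    """Deterministic pseudo-random backend standing in for a language model.

    Every residue's vector is a pure function of (seed salt, full subsequence
    content, residue index): changing any single residue reseeds the whole
    matrix, mimicking the context sensitivity of a real language model.
    Values are bounded in [-1, 1]. An optional ``signal_map`` adds a fixed
    vector to chosen rows of chosen sequences (used by the synthetic fixtures
    to inject class-conditional signal); it is keyed by exact sequence
    content, so determinism is preserved.
    """

    name: str
    dim: int
    max_length: int | None = None
    seed_salt: str = ""
    signal_map: dict[str, list[tuple[int, np.ndarray]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")

    def _seed_for(self, sequence: str) -> int:
        digest = hashlib.blake2b(
            f"{self.seed_salt}|{self.name}|{sequence}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(digest, "little")

    def embed(self, sequence: str) -> np.ndarray:
        rng = np.random.default_rng(self._seed_for(sequence))
        matrix = rng.uniform(-1.0, 1.0, size=(len(sequence), self.dim))
        for row, shift in self.signal_map.get(sequence, ()):
            matrix[row] += shift
        return matrix


def mock_backend(
    name: str, dim: int, seed_salt: str = "", max_length: int | None = None
) -> MockBackend:
    """Convenience constructor for :class:`MockBackend`."""
    return MockBackend(name=name, dim=dim, max_length=max_length, seed_salt=seed_salt)


@dataclass
class PrecomputedBackend:
    """Backend serving matrices from a store keyed by sequence content.

    The store maps the hex SHA-1 of the sequence to an L x D matrix. An
    on-disk ``.npz`` file with those hashes as keys is accepted. This is the
    route for plugging real language-model embeddings in without shipping the
    models: compute matrices elsewhere, key them by sequence hash.
    """

    name: str
    dim: int
    store: Mapping[str, np.ndarray]
    max_length: int | None = None

    @staticmethod
    def sequence_key(sequence: str) -> str:
        return hashlib.sha1(sequence.encode()).hexdigest()

    @classmethod
    def from_npz(cls, name: str, dim: int, path: str | Path,
                 max_length: int | None = None) -> "PrecomputedBackend":
        return cls(name=name, dim=dim, store=dict(np.load(path)), max_length=max_length)

    def embed(self, sequence: str) -> np.ndarray:
        key = self.sequence_key(sequence)
        if key not in self.store:
            raise BackendError(
                f"backend {self.name}: no precomputed embedding for sequence "
                f"of length {len(sequence)} (key {key})"
            )
        matrix = np.asarray(self.store[key], dtype=float)
        if matrix.shape != (len(sequence), self.dim):
            raise BackendError(
                f"backend {self.name}: stored matrix has shape {matrix.shape}, "
                f"expected ({len(sequence)}, {self.dim})"
            )
        return matrix


class CachingBackend:
    """Memoizes another backend keyed by (backend name, subsequence hash)."""

    def __init__(self, inner: EmbeddingBackend) -> None:
        self.inner = inner
        self.name = inner.name
        self.dim = inner.dim
        self.max_length = inner.max_length
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, sequence: str) -> np.ndarray:
        key = hashlib.sha1(sequence.encode()).hexdigest()
        if key not in self._cache:
            self._cache[key] = self.inner.embed(sequence)
        return self._cache[key]


@dataclass
class PositionalEncoding:
    """Concatenated embedding rows at the variant position.

    ``layout`` lists (block name, length) in concatenation order.
    """

    values: np.ndarray
    layout: list[tuple[str, int]]

    def __len__(self) -> int:
        return self.values.shape[0]

    def block(self, name: str) -> np.ndarray:
        offset = 0
        for block_name, length in self.layout:
            if block_name == name:
                return self.values[offset : offset + length]
            offset += length
        raise KeyError(name)


def encode_variant_positional(
    wt_sequence: str,
    variant: VariantRecord,
    backends: Sequence[EmbeddingBackend],
    window: int = DEFAULT_WINDOW,
) -> PositionalEncoding:
    """Encode one variant from the embeddings of both sequences.

    For each backend (in order) the variant-sequence row comes first, then
    the wild-type row, both taken at the (window-adjusted) variant position.
    """
    if len(backends) != 2:
        raise ValueError(f"expected exactly 2 backends, got {len(backends)}")
    mut_sequence = apply_substitution(
        wt_sequence, variant.position, variant.wt_residue, variant.mut_residue
    )
    blocks: list[np.ndarray] = []
    layout: list[tuple[str, int]] = []
    for backend in backends:
        sub_wt, adj = extract_window(wt_sequence, variant.position, backend.max_length, window)
        sub_mut, adj_mut = extract_window(
            mut_sequence, variant.position, backend.max_length, window
        )
        assert adj == adj_mut  # same length, same position, same window
        assert sub_wt[adj - 1] == variant.wt_residue
        assert sub_mut[adj - 1] == variant.mut_residue
        try:
            row_mut = backend.embed(sub_mut)[adj - 1]
            row_wt = backend.embed(sub_wt)[adj - 1]
        except Exception as exc:  # noqa: BLE001 - context per contract
            raise BackendError(
                f"backend {backend.name} failed on {variant.protein_accession} "
                f"{variant.substitution}: {exc}"
            ) from exc
        blocks.extend([row_mut, row_wt])
        layout.extend(
            [(f"{backend.name}_variant", backend.dim), (f"{backend.name}_wildtype", backend.dim)]
        )
    return PositionalEncoding(values=np.concatenate(blocks), layout=layout)
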