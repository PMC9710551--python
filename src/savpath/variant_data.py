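"""Domain records, file parsing and dataset curation.

Positions are 1-based everywhere outside array indexing, following HGVS and
UniProt convention. Variant substitution tokens are accepted both in compact
form (``A123V``) and in HGVS protein form (``p.Ala123Val``).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_RESIDUE = "X"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Xaa": "X",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

_COMPACT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_HGVS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


class Label(enum.Enum):
    """Clinical significance class of a variant."""

    PLP = "PLP"   # pathogenic / likely pathogenic
    BLB = "BLB"   # benign / likely benign
    US = "US"     # uncertain significance

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Source(enum.Enum):
    HUMSAVAR = "HUMSAVAR"
    CLINVAR = "CLINVAR"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class VariantValidationError(ValueError):
    """Base class for variant-vs-sequence consistency failures."""


class UnknownAccessionError(VariantValidationError):
    pass


class PositionOutOfRangeError(VariantValidationError):
    pass


class ResidueMismatchError(VariantValidationError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional per-sub-ontology GO annotation.

    ``go_terms`` maps sub-ontology name (``MF``, ``CC``, ``BP``) to a frozen
    set of GO identifiers.
    """

    accession: str
    sequence: str
    go_terms: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")

    @property
    def has_ambiguous(self) -> bool:
        return AMBIGUOUS_RESIDUE in self.sequence

    def with_go_terms(self, go_terms: Mapping[str, frozenset[str]]) -> "ProteinRecord":
        return replace(self, go_terms=dict(go_terms))


@dataclass(frozen=True)
class VariantRecord:
    """A single amino acid substitution on a protein."""

    protein_accession: str
    position: int  # 1-based
    wt_residue: str
    mut_residue: str
    label: Label
    somatic: bool = False
    disease_ids: frozenset[str] = frozenset()
    source: Source = Source.OTHER

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"{self.protein_accession}: position {self.position} is not 1-based"
            )
        if self.wt_residue == self.mut_residue:
            raise ValueError(
                f"{self.protein_accession} {self.substitution}: "
                "wild-type and substituted residues are identical"
            )

    @property
    def substitution(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the substitution, independent of provenance."""
        return (self.protein_accession, self.position, self.wt_residue, self.mut_residue)


@dataclass
class CuratedDataset:
    """Output of :func:`curate`: retained variants plus an exclusion log."""

    proteins: dict[str, ProteinRecord]
    variants: list[VariantRecord]
    provenance_log: list[tuple[VariantRecord, str]]


def parse_substitution(token: str) -> tuple[str, int, str]:
    """Parse ``A123V`` or ``p.Ala123Val`` into (wt, 1-based position, mut)."""
    m = _COMPACT_RE.match(token)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _HGVS_RE.match(token)
    if m:
        wt3, pos, mut3 = m.group(1), int(m.group(2)), m.group(3)
        if wt3 not in _THREE_TO_ONE or mut3 not in _THREE_TO_ONE:
            raise ParseError(f"unknown amino-acid code in substitution token {token!r}")
        return _THREE_TO_ONE[wt3], pos, _THREE_TO_ONE[mut3]
    raise ParseError(f"cannot parse substitution token {token!r}")


def format_substitution_hgvs(wt: str, position: int, mut: str) -> str:
    return f"p.{_ONE_TO_THREE[wt]}{position}{_ONE_TO_THREE[mut]}"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records, preserving entry order.

    The accession is the first whitespace-delimited token of the header.
    A hand-rolled reader is used (rather than Bio.SeqIO) so that parse errors
    can name the offending line number.
    """
    records: list[ProteinRecord] = []
    accession: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if accession is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"line {header_line}: entry {accession!r} has an empty sequence")
        records.append(ProteinRecord(accession=accession, sequence=seq))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                tokens = line[1:].split()
                if not tokens:
                    raise ParseError(f"line {lineno}: FASTA header has no accession")
                accession, header_line, chunks = tokens[0], lineno, []
            else:
                if accession is None:
                    raise ParseError(f"line {lineno}: sequence data before any FASTA header")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


VARIANT_TABLE_COLUMNS = ("accession", "substitution", "label", "somatic", "disease_ids", "source")


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in {"1", "true", "yes", "somatic"}:
        return True
    if t in {"0", "false", "no", "germline", ""}:
        return False
    raise ParseError(f"cannot parse boolean flag {token!r}")


def read_variant_table(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord],
    on_error: str = "raise",
) -> tuple[list[VariantRecord], list[tuple[str, str]]]:
    """Read the tab-separated variant table and validate against sequences.

    Columns: ``accession substitution label somatic disease_ids source``
    (header line required; ``disease_ids`` semicolon-separated, may be empty).

    With ``on_error="raise"`` (default), an unknown accession, an
    out-of-range position and a wild-type mismatch each raise a distinct
    error. With ``on_error="log"``, the offending line is skipped and
    recorded as ``(line description, reason)`` in the returned problem list,
    which :func:`curate`-style workflows fold into the exclusion log.

    A variant whose sequence position holds the ambiguous residue ``X`` is
    accepted here (its wild-type letter cannot be checked) and is excluded
    later by :func:`curate`.
    """
    if on_error not in {"raise", "log"}:
        raise ValueError(f"on_error must be 'raise' or 'log', got {on_error!r}")
    variants: list[VariantRecord] = []
    problems: list[tuple[str, str]] = []

    def fail(exc: VariantValidationError, desc: str, reason: str) -> None:
        if on_error == "raise":
            raise exc
        problems.append((desc, reason))

    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != list(VARIANT_TABLE_COLUMNS):
            raise ParseError(
                f"line 1: expected header {list(VARIANT_TABLE_COLUMNS)}, got {header}"
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != len(VARIANT_TABLE_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(VARIANT_TABLE_COLUMNS)} columns, "
                    f"got {len(cols)}"
                )
            acc, sub_token, label_s, somatic_s, dis_s, source_s = (c.strip() for c in cols)
            wt, pos, mut = parse_substitution(sub_token)
            desc = f"{acc} {wt}{pos}{mut}"
            try:
                label = Label(label_s)
            except ValueError:
                raise ParseError(f"line {lineno}: unknown label {label_s!r}") from None
            try:
                source = Source(source_s) if source_s else Source.OTHER
            except ValueError:
                raise ParseError(f"line {lineno}: unknown source {source_s!r}") from None
            disease_ids = frozenset(d for d in dis_s.split(";") if d)

            protein = proteins.get(acc)
            if protein is None:
                fail(
                    UnknownAccessionError(f"line {lineno}: unknown accession {acc!r}"),
                    desc,
                    "no_sequence",
                )
                continue
            if pos > len(protein.sequence):
                fail(
                    PositionOutOfRangeError(
                        f"line {lineno}: {acc} position {pos} exceeds sequence "
                        f"length {len(protein.sequence)}"
                    ),
                    desc,
                    "position_out_of_range",
                )
                continue
            seq_residue = protein.sequence[pos - 1]
            if seq_residue != wt and seq_residue != AMBIGUOUS_RESIDUE:
                fail(
                    ResidueMismatchError(
                        f"line {lineno}: {acc} position {pos} holds {seq_residue!r}, "
                        f"variant claims wild-type {wt!r}"
                    ),
                    desc,
                    "wt_mismatch",
                )
                continue
            variants.append(
                VariantRecord(
                    protein_accession=acc,
                    position=pos,
                    wt_residue=wt,
                    mut_residue=mut,
                    label=label,
                    somatic=_parse_bool(somatic_s),
                    disease_ids=disease_ids,
                    source=source,
                )
            )
    return variants, problems


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(VARIANT_TABLE_COLUMNS) + "\n")
        for v in variants:
            handle.write(
                "\t".join(
                    (
                        v.protein_accession,
                        v.substitution,
                        v.label.value,
                        "1" if v.somatic else "0",
                        ";".join(sorted(v.disease_ids)),
                        v.source.value,
                    )
                )
                + "\n"
            )


def curate(
    records: Sequence[VariantRecord],
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> CuratedDataset:
    """Apply the dataset-curation rules and log every exclusion.

    Rules, applied per record and then per unique substitution key across all
    sources combined:

    * records referencing proteins absent from ``proteins`` (when given) are
      excluded with reason ``no_sequence``;
    * variants whose sequence position holds ``X`` are excluded with reason
      ``ambiguous_residue``;
    * ``US`` labels are excluded (``us_label``), somatic records are excluded
      (``somatic``);
    * ``PLP`` records with no disease association are excluded
      (``no_disease_association``);
    * keys carrying both ``PLP`` and ``BLB`` among the surviving records are
      dropped entirely (``conflict``);
    * concordant duplicates of a key collapse to one retained record (disease
      ids merged); the extra copies are logged as ``duplicate``.

    The function never raises on data content: ``len(records)`` always equals
    ``len(retained) + len(provenance_log)``.
    """
    log: list[tuple[VariantRecord, str]] = []
    survivors: dict[tuple[str, int, str, str], list[VariantRecord]] = {}

    for rec in records:
        if proteins is not None:
            protein = proteins.get(rec.protein_accession)
            if protein is None:
                log.append((rec, "no_sequence"))
                continue
            if rec.position > len(protein.sequence):
                log.append((rec, "position_out_of_range"))
                continue
            if protein.sequence[rec.position - 1] == AMBIGUOUS_RESIDUE:
                log.append((rec, "ambiguous_residue"))
                continue
        if rec.label is Label.US:
            log.append((rec, "us_label"))
            continue
        if rec.somatic:
            log.append((rec, "somatic"))
            continue
        if rec.label is Label.PLP and not rec.disease_ids:
            log.append((rec, "no_disease_association"))
            continue
        survivors.setdefault(rec.key, []).append(rec)

    retained: list[VariantRecord] = []
    for key, group in survivors.items():
        labels = {r.label for r in group}
        if Label.PLP in labels and Label.BLB in labels:
            for r in group:
                log.append((r, "conflict"))
            continue
        merged_ids = frozenset().union(*(r.disease_ids for r in group))
        retained.append(replace(group[0], disease_ids=merged_ids))
        for r in group[1:]:
            log.append((r, "duplicate"))

    kept_proteins: dict[str, ProteinRecord] = {}
    if proteins is not None:
        kept_accessions = {v.protein_accession for v in retained}
        kept_proteins = {a: proteins[a] for a in kept_accessions}
    return CuratedDataset(proteins=kept_proteins, variants=retained, provenance_log=log)


def write_exclusion_log(log: Iterable[tuple[VariantRecord, str]], path: str | Path) -> None:
    """Write the exclusion log as ``accession substitution reason``."""
    with open(path, "w") as handle:
        handle.write("accession\tsubstitution\treason\n")
        for rec, reason in log:
            handle.write(f"{rec.protein_accession}\t{rec.substitution}\t{reason}\n")
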