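"""Sequence and label I/O, residue canonicalization, cross-validation folds.

FASTA parsing is done by hand (rather than through Bio.SeqIO) so that
malformed input can be reported with the offending line number, which the
error contract requires.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

AFP = "AFP"
NONAFP = "NONAFP"

#: The 20 canonical one-letter residue codes, alphabetical.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Symbols tolerated in raw input but absent from the canonical alphabet.
NONSTANDARD_SYMBOLS = frozenset("BJOUXZ*-.")

#: Ambiguity codes resolved to the most frequent residue they stand for.
_MOST_FREQUENT_MAP = {"B": "N", "Z": "Q", "U": "C"}

CANONICALIZE_POLICIES = ("strict", "drop", "map_to_most_frequent")


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class AlphabetError(ValueError):
    """Sequence contains symbols outside the canonical residue alphabet."""


class DatasetError(ValueError):
    """Inconsistent dataset bookkeeping (duplicate ids, missing labels...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an optional binary AFP / non-AFP label."""

    id: str
    sequence: str
    description: str = ""
    label: str | None = None

    def __post_init__(self):
        if not self.id:
            raise DatasetError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise DatasetError(f"record {self.id!r}: empty sequence")
        if self.label not in (None, AFP, NONAFP):
            raise DatasetError(f"record {self.id!r}: bad label {self.label!r}")

    def with_label(self, label: str | None) -> "ProteinRecord":
        return replace(self, label=label)


@dataclass
class LabeledDataset:
    """An ordered collection of records plus an optional fold assignment."""

    records: list[ProteinRecord]
    fold_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def record(self, rec_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    @property
    def positives(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.label == AFP]

    @property
    def negatives(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.label == NONAFP]


def canonicalize(sequence: str, policy: str = "strict") -> str:
    """Map a raw sequence onto the 20-letter canonical alphabet.

    Policies: ``strict`` raises on any nonstandard symbol; ``drop`` removes
    them; ``map_to_most_frequent`` maps B->N, Z->Q, U->C and drops the rest.
    """
    if policy not in CANONICALIZE_POLICIES:
        raise ValueError(
            f"unknown policy {policy!r}; expected one of {CANONICALIZE_POLICIES}"
        )
    seq = sequence.upper()
    bad = [(i, c) for i, c in enumerate(seq) if c not in _CANONICAL_SET]
    if not bad:
        return seq
    if policy == "strict":
        shown = ", ".join(f"{c}@{i}" for i, c in bad[:10])
        raise AlphabetError(
            f"nonstandard symbols under strict policy: {shown}"
            + (" ..." if len(bad) > 10 else "")
        )
    if policy == "drop":
        return "".join(c for c in seq if c in _CANONICAL_SET)
    out = []
    for c in seq:
        if c in _CANONICAL_SET:
            out.append(c)
        elif c in _MOST_FREQUENT_MAP:
            out.append(_MOST_FREQUENT_MAP[c])
        # anything else (X, gaps, stops) is dropped
    return "".join(out)


def read_fasta(path: str | Path, policy: str = "strict") -> list[ProteinRecord]:
    """Read a FASTA file into records, canonicalizing with *policy*.

    Order is preserved and sequences are uppercased.  Malformed headers or
    empty entries raise :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        raw = "".join(chunks)
        if not raw:
            raise FastaParseError(f"entry {header!r} has an empty sequence", header_line)
        parts = header.split(None, 1)
        rec_id, desc = parts[0], (parts[1] if len(parts) > 1 else "")
        try:
            seq = canonicalize(raw, policy)
        except AlphabetError as exc:
            raise FastaParseError(f"entry {rec_id!r}: {exc}", header_line) from exc
        if not seq:
            raise FastaParseError(
                f"entry {rec_id!r}: no canonical residues remain", header_line
            )
        records.append(ProteinRecord(id=rec_id, sequence=seq, description=desc))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(";"):
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
            else:
                if header is None:
                    raise FastaParseError("sequence data before first header", lineno)
                chunks.append(line.replace(" ", ""))
    flush()

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"duplicate FASTA ids: {dupes}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_label_table(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Read a 2/3-column TSV (id, label[, subset]) of AFP / NONAFP labels.

    Returns ``(labels, subsets)``; *subsets* holds only the ids for which a
    third column was present.
    """
    labels: dict[str, str] = {}
    subsets: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DatasetError(f"{path}: line {lineno}: expected >=2 columns")
            rec_id, label = parts[0], parts[1].upper()
            if label not in (AFP, NONAFP):
                raise DatasetError(
                    f"{path}: line {lineno}: label must be AFP or NONAFP, got {parts[1]!r}"
                )
            if rec_id in labels:
                raise DatasetError(f"{path}: line {lineno}: duplicate id {rec_id!r}")
            labels[rec_id] = label
            if len(parts) > 2 and parts[2]:
                subsets[rec_id] = int(parts[2])
    return labels, subsets


def attach_labels(
    records: Sequence[ProteinRecord], labels: dict[str, str]
) -> LabeledDataset:
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise DatasetError(f"records without labels: {missing[:10]}")
    return LabeledDataset([r.with_label(labels[r.id]) for r in records])


def assign_folds(
    dataset: LabeledDataset,
    positive_subsets: dict[str, int],
    n_folds: int,
    seed: int,
) -> LabeledDataset:
    """Assign every record to a cross-validation fold in ``[1..n_folds]``.

    Positives go to their declared subset; negatives are Fisher-Yates
    shuffled with *seed* and dealt round-robin, so negative fold sizes
    differ by at most one.  Deterministic for a fixed seed.
    """
    fold_of: dict[str, int] = {}
    for rec in dataset.positives:
        if rec.id not in positive_subsets:
            raise DatasetError(f"positive record {rec.id!r} missing from subset table")
        subset = positive_subsets[rec.id]
        if not 1 <= subset <= n_folds:
            raise DatasetError(
                f"record {rec.id!r}: subset {subset} outside [1..{n_folds}]"
            )
        fold_of[rec.id] = subset
    neg_ids = [r.id for r in dataset.negatives]
    rng = random.Random(seed)
    rng.shuffle(neg_ids)
    for i, rec_id in enumerate(neg_ids):
        fold_of[rec_id] = (i % n_folds) + 1
    unlabeled = [r.id for r in dataset.records if r.id not in fold_of]
    if unlabeled:
        raise DatasetError(f"records without AFP/NONAFP labels: {unlabeled[:10]}")
    return LabeledDataset(records=list(dataset.records), fold_of=fold_of)


def write_fold_table(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tfold\n")
        for rec in dataset.records:
            fh.write(f"{rec.id}\t{dataset.fold_of[rec.id]}\n")
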