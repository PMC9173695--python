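"""Transcript I/O, length filtering, one-hot encoding and stratified splitting.

Transcripts are handled as DNA: ``U`` is mapped to ``T`` on input and
sequences are uppercased. IUPAC ambiguity codes (N, R, Y, ...) are kept in
the sequence string and encoded as all-zero rows, so the row sum of a
one-hot matrix counts unambiguous bases. The positive class throughout the
package is ``lncRNA``; ``mRNA`` (protein-coding transcript) is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from sklearn.model_selection import train_test_split

LNCRNA = "lncRNA"
MRNA = "mRNA"
LABELS = (LNCRNA, MRNA)

#: one-hot channel order, fixed across the package
CHANNELS = "ACGT"

_IUPAC = set("ACGTNRYSWKMBDHV")
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input (with line number)."""


@dataclass
class SequenceRecord:
    """One transcript: identifier, normalized residues, optional class label."""

    id: str
    residues: str
    label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"record {self.id!r}: label must be one of {LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LengthFilterReport:
    """Bookkeeping for a min/max length filter: kept = total - below - above."""

    total: int
    below_min: int
    above_max: int
    kept: int
    min_len: int = 200
    max_len: int = 3000

    def __post_init__(self) -> None:
        if min(self.total, self.below_min, self.above_max, self.kept) < 0:
            raise ValueError("counts must be non-negative")
        if self.kept != self.total - self.below_min - self.above_max:
            raise ValueError("inconsistent report: kept != total - below_min - above_max")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("total\tbelow_min\tabove_max\tkept\tmin_len\tmax_len\n")
            fh.write(
                f"{self.total}\t{self.below_min}\t{self.above_max}\t"
                f"{self.kept}\t{self.min_len}\t{self.max_len}\n"
            )


@dataclass
class EncodedDataset:
    """Padded one-hot tensor (N, Lmax, 4) with labels, lengths and ids.

    Labels are integers: 1 = lncRNA (positive class), 0 = mRNA.
    Rows at or beyond each record's true length are all zero.
    """

    tensor: np.ndarray
    labels: np.ndarray
    lengths: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or self.tensor.shape[2] != 4:
            raise ValueError("tensor must have shape (N, Lmax, 4)")
        n = self.tensor.shape[0]
        if not (len(self.labels) == len(self.lengths) == n):
            raise ValueError("labels/lengths must match tensor rows")
        if self.ids and len(self.ids) != n:
            raise ValueError("ids must match tensor rows")

    def __len__(self) -> int:
        return self.tensor.shape[0]

    @property
    def input_length(self) -> int:
        return self.tensor.shape[1]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            tensor=self.tensor[idx],
            labels=self.labels[idx],
            lengths=self.lengths[idx],
            ids=[self.ids[i] for i in idx] if self.ids else [],
        )


@dataclass
class SplitSpec:
    """Stratified train/test split parameters (default 80/20)."""

    test_fraction: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie strictly between 0 and 1")


def normalize_residues(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, map RNA U to T, and reject non-IUPAC characters."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(
            f"record {record_id!r}: non-IUPAC nucleotide characters {sorted(bad)}"
        )
    return seq


def _prescan_fasta(path: str | Path) -> None:
    """Structural check producing line-numbered errors for malformed FASTA."""
    last_header_line = None
    seen_seq = False
    seen_any = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if last_header_line is not None and not seen_seq:
                    raise FastaParseError(
                        f"{path}:{last_header_line}: FASTA entry has no sequence"
                    )
                if not stripped[1:].split():
                    raise FastaParseError(f"{path}:{lineno}: FASTA header has no id")
                last_header_line = lineno
                seen_seq = False
            else:
                if last_header_line is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                seen_seq = True
            seen_any = True
    if seen_any and last_header_line is not None and not seen_seq:
        raise FastaParseError(f"{path}:{last_header_line}: FASTA entry has no sequence")


def read_fasta(path: str | Path, *, source: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    The id is the header token before the first whitespace. An empty file
    yields an empty list; structural problems raise :class:`FastaParseError`
    naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_fasta(path)
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=normalize_residues(str(entry.seq), record_id=entry.id),
                source=source,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) TSV; label must be lncRNA or mRNA."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            seq_id, label = parts
            if lineno == 1 and label not in LABELS:
                continue  # header row
            if label not in LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            labels[seq_id] = label
    return labels


def write_labels_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(
    records: list[SequenceRecord], labels: dict[str, str]
) -> list[SequenceRecord]:
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"records without labels: {missing[:10]}")
    return [
        SequenceRecord(r.id, r.residues, label=labels[r.id], source=r.source)
        for r in records
    ]


def filter_by_length(
    records: Sequence[SequenceRecord], min_len: int = 200, max_len: int = 3000
) -> tuple[list[SequenceRecord], LengthFilterReport]:
    """Keep records with min_len <= length <= max_len (inclusive bounds).

    "Shorter than min" and "longer than max" are discarded; the report
    satisfies kept = total - below_min - above_max.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    kept, below, above = [], 0, 0
    for rec in records:
        n = len(rec)
        if n < min_len:
            below += 1
        elif n > max_len:
            above += 1
        else:
            kept.append(rec)
    report = LengthFilterReport(
        total=len(records),
        below_min=below,
        above_max=above,
        kept=len(kept),
        min_len=min_len,
        max_len=max_len,
    )
    return kept, report


def drop_exact_duplicates(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], int]:
    """Keep the first record of each identical residue string (order stable)."""
    seen: set[str] = set()
    kept = []
    for rec in records:
        if rec.residues in seen:
            continue
        seen.add(rec.residues)
        kept.append(rec)
    return kept, len(records) - len(kept)


def one_hot_encode(record: SequenceRecord, max_len: int = 3000) -> np.ndarray:
    """Encode residues as an (max_len, 4) binary matrix, channels A,C,G,T.

    Ambiguity codes and padding positions are all-zero rows; the caller must
    filter or truncate sequences longer than ``max_len`` first.
    """
    L = len(record)
    if L > max_len:
        raise ValueError(
            f"record {record.id!r} has length {L} > max_len {max_len}; "
            "filter or truncate first"
        )
    mat = np.zeros((max_len, 4), dtype=np.float32)
    for p, base in enumerate(record.residues):
        ch = _CHANNEL_INDEX.get(base)
        if ch is not None:
            mat[p, ch] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray, length: int | None = None) -> str:
    """Inverse of :func:`one_hot_encode` on unambiguous rows ('N' for zero rows)."""
    if length is None:
        nz = np.flatnonzero(mat.sum(axis=1))
        length = int(nz[-1]) + 1 if nz.size else 0
    out = []
    for p in range(length):
        row = mat[p]
        out.append(CHANNELS[int(row.argmax())] if row.sum() > 0 else "N")
    return "".join(out)


def encode_dataset(
    records: Sequence[SequenceRecord], max_len: int = 3000
) -> EncodedDataset:
    """One-hot encode labeled records into a padded training tensor."""
    unlabeled = [r.id for r in records if r.label is None]
    if unlabeled:
        raise ValueError(f"records without labels: {unlabeled[:10]}")
    tensor = np.stack([one_hot_encode(r, max_len) for r in records])
    labels = np.array([1 if r.label == LNCRNA else 0 for r in records], dtype=np.int64)
    lengths = np.array([len(r) for r in records], dtype=np.int64)
    return EncodedDataset(tensor, labels, lengths, ids=[r.id for r in records])


def stratified_split(
    records: Sequence[SequenceRecord], spec: SplitSpec
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Deterministic stratified split into (train, test) by record label."""
    unlabeled = [r.id for r in records if r.label is None]
    if unlabeled:
        raise ValueError(f"cannot stratify records without labels: {unlabeled[:10]}")
    labels = [r.label for r in records]
    train, test = train_test_split(
        list(records),
        test_size=spec.test_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    return list(train), list(test)
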