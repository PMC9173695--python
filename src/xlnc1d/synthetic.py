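"""Synthetic transcript generator with known ground truth.

The generator emulates the statistical contrast a coding/non-coding
classifier exploits. mRNA-like sequences carry a single long open reading
frame: a 5' UTR, an ATG start codon, a codon body drawn from the 61 non-stop
codons, exactly one terminal stop codon and a 3' UTR. Optionally a "domain"
motif is planted in-frame inside the ORF at recorded coordinates, standing
in for the conserved protein-domain signal of real transcripts. lncRNA-like
sequences are i.i.d. nucleotides at a chosen GC content, hence rich in
in-frame stop codons and free of the planted motif — which makes motif
attribution specificity testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequence_io import LNCRNA, MRNA, SequenceRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

_BASES = "ACGT"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
#: the 61 sense codons used for ORF bodies
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

#: default planted "domain" motif: 57 nt (one convolution kernel width),
#: length divisible by 3 and free of in-frame stop codons
DEFAULT_MOTIF = ("GATTACA" * 9)[:57]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset (defaults are the study conditions)."""

    n_per_class: int = 100
    length_range: tuple[int, int] = (200, 3000)
    utr5_range: tuple[int, int] = (10, 90)
    motif: str | None = None
    motif_rate: float = 0.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (200 <= lo <= hi <= 3000):
            raise ValueError("length_range must lie within [200, 3000]")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.motif is not None:
            if len(self.motif) % 3 != 0:
                raise ValueError("motif length must be divisible by 3 (planted in-frame)")
            for i in range(0, len(self.motif), 3):
                if self.motif[i : i + 3] in STOP_CODONS:
                    raise ValueError("motif must not contain an in-frame stop codon")
        u_lo, u_hi = self.utr5_range
        if not 0 <= u_lo <= u_hi:
            raise ValueError("utr5_range must be 0 <= min <= max")


@dataclass
class MotifAnnotation:
    """Planted motif ground truth, 0-based half-open, frame relative to seq start."""

    seq_id: str
    start: int
    end: int
    frame: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(_BASES), size=n, p=probs)) if n else ""


def _utr5_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    """5' UTR bases with ATG occurrences masked out, so the ORF start is the
    first ATG of the sequence (keeps the ORF scan well-defined)."""
    seq = _random_bases(rng, n, gc)
    while START_CODON in seq:
        seq = seq.replace(START_CODON, "ACG")
    return seq


def _mrna_like(
    rng: np.random.Generator, spec: SyntheticSpec, seq_id: str
) -> tuple[SequenceRecord, MotifAnnotation | None]:
    lo, hi = spec.length_range
    total = int(rng.integers(lo, hi + 1))
    motif = spec.motif
    motif_codons = len(motif) // 3 if motif else 0

    # reserve start + stop codons; split the rest between UTRs and the body
    u_lo, u_hi = spec.utr5_range
    utr5 = int(rng.integers(u_lo, u_hi + 1))
    # body must hold the motif plus some context
    min_body_codons = max(motif_codons, 20)
    max_body_nt = total - utr5 - 6
    if max_body_nt < min_body_codons * 3:
        utr5 = max(0, total - 6 - min_body_codons * 3)
        max_body_nt = total - utr5 - 6
    if max_body_nt < min_body_codons * 3:
        raise ValueError(
            f"motif of {motif_codons} codons does not fit an ORF within "
            f"length_range {spec.length_range}"
        )
    body_codons = int(rng.integers(min_body_codons, max_body_nt // 3 + 1))
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), body_codons)]

    annotation = None
    plant = motif is not None and rng.random() < spec.motif_rate
    if plant:
        at = int(rng.integers(0, body_codons - motif_codons + 1))
        for j in range(motif_codons):
            body[at + j] = motif[3 * j : 3 * j + 3]
        start = utr5 + 3 + at * 3  # after UTR and ATG
        annotation = MotifAnnotation(
            seq_id=seq_id, start=start, end=start + len(motif), frame=start % 3
        )

    stop = STOP_CODONS[int(rng.integers(0, 3))]
    core = _utr5_bases(rng, utr5, spec.gc_content) + START_CODON + "".join(body) + stop
    utr3 = total - len(core)
    seq = core + _random_bases(rng, max(utr3, 0), spec.gc_content)
    rec = SequenceRecord(seq_id, seq, label=MRNA, source="synthetic")
    return rec, annotation


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[MotifAnnotation]]:
    """Generate n_per_class mRNA-like and lncRNA-like labeled records.

    Fully reproducible given ``spec.seed``; motif coordinates of planted
    motifs are returned as ground-truth annotations.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    annotations: list[MotifAnnotation] = []
    for i in range(spec.n_per_class):
        rec, ann = _mrna_like(rng, spec, f"mrna_{i:05d}")
        records.append(rec)
        if ann is not None:
            annotations.append(ann)
    lo, hi = spec.length_range
    for i in range(spec.n_per_class):
        n = int(rng.integers(lo, hi + 1))
        records.append(
            SequenceRecord(
                f"lnc_{i:05d}",
                _random_bases(rng, n, spec.gc_content),
                label=LNCRNA,
                source="synthetic",
            )
        )
    return records, annotations


def shuffle_control(record: SequenceRecord, seed: int) -> SequenceRecord:
    """Mononucleotide shuffle: same composition, ORF structure destroyed."""
    rng = np.random.default_rng(seed)
    shuffled = "".join(rng.permutation(list(record.residues)))
    return SequenceRecord(
        f"{record.id}_shuf", shuffled, label=record.label, source="shuffle_control"
    )


def find_orf(seq: str) -> tuple[int, int] | None:
    """ORF anchored at the first ATG: (start, end) half-open, end after the
    first in-frame stop codon; None if no ATG or no downstream in-frame stop.

    For generated mRNA-like records the 5' UTR contains no ATG, so the first
    ATG is the constructed start and ``end - start - 6`` is the body length.
    """
    start = seq.find(START_CODON)
    if start < 0:
        return None
    for p in range(start + 3, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return start, p + 3
    return None


def scan_in_frame_stops(seq: str, start: int) -> list[int]:
    """Positions of stop codons in the frame anchored at ``start``."""
    return [
        p for p in range(start, len(seq) - 2, 3) if seq[p : p + 3] in STOP_CODONS
    ]


def write_annotations_tsv(
    annotations: Iterable[MotifAnnotation], path: str | Path
) -> None:
    """BED-like TSV (0-based half-open): seq_id, start, end, frame."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tframe\n")
        for a in annotations:
            fh.write(f"{a.seq_id}\t{a.start}\t{a.end}\t{a.frame}\n")


def read_annotations_tsv(path: str | Path) -> list[MotifAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            seq_id, start, end, frame = line.rstrip("\n").split("\t")
            out.append(MotifAnnotation(seq_id, int(start), int(end), int(frame)))
    return out
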