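"""Sequence and annotation I/O.

Protein sequences are plain FASTA.  Linker/domain annotations travel in a
TSV sidecar with a ``seq_id<TAB>start<TAB>end<TAB>label`` header, 1-based
inclusive coordinates, and ``#`` comment lines.  Annotation files only need
to list linker segments: every residue not covered by a linker interval is
a domain residue.  Internally labels are 0-based numpy vectors (1 = linker,
0 = domain); the 1-based convention exists only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, upper case.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

LINKER, DOMAIN = 1, 0


@dataclass(frozen=True)
class ProteinSequence:
    """A sanitized protein sequence over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SegmentAnnotation:
    """A labelled interval, 1-based and inclusive on both ends."""

    seq_id: str
    start: int
    end: int
    label: Literal["linker", "domain"]

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval ({self.start}, {self.end}) for {self.seq_id!r}"
            )
        if self.label not in ("linker", "domain"):
            raise ValueError(f"unknown segment label {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedCorpus:
    """Sequences plus per-residue binary truth labels (1 = linker)."""

    sequences: list[ProteinSequence]
    labels: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("one label vector per sequence required")
        for seq, lab in zip(self.sequences, self.labels):
            if len(lab) != len(seq):
                raise ValueError(
                    f"label vector length {len(lab)} != sequence length "
                    f"{len(seq)} for {seq.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(zip(self.sequences, self.labels))


def sanitize_residues(
    seq_id: str, raw: str, policy: Literal["error", "drop"] = "drop"
) -> str:
    """Upper-case *raw*, strip whitespace, and handle non-standard residues.

    ``drop`` (default) removes letters outside the 20-standard alphabet
    (X, B, Z, U, O, ...) with a logged warning; ``error`` raises.
    """
    cleaned = "".join(raw.split()).upper()
    bad = [c for c in cleaned if c not in _STANDARD_SET]
    if bad:
        if policy == "error":
            raise ValueError(
                f"sequence {seq_id!r} contains non-standard residues {sorted(set(bad))}"
            )
        logger.warning(
            "sequence %r: dropping %d non-standard residue(s) %s",
            seq_id, len(bad), sorted(set(bad)),
        )
        cleaned = "".join(c for c in cleaned if c in _STANDARD_SET)
    return cleaned


def read_fasta(
    path: str | Path, sanitize_policy: Literal["error", "drop"] = "drop"
) -> list[ProteinSequence]:
    """Read a (multi-record, multi-line) FASTA file into ProteinSequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        residues = sanitize_residues(rec.id, str(rec.seq), sanitize_policy)
        if not residues:
            raise ValueError(f"record {rec.id!r} has no standard residues")
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


def _parse_annotation_rows(path: str | Path) -> list[SegmentAnnotation]:
    rows: list[SegmentAnnotation] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[:4] != ["seq_id", "start", "end", "label"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header "
                        "'seq_id<TAB>start<TAB>end<TAB>label'"
                    )
                header_seen = True
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            seq_id, start, end, label = parts
            rows.append(SegmentAnnotation(seq_id, int(start), int(end), label))
    if not header_seen:
        raise ValueError(f"{path}: empty annotation file")
    return rows


def labels_from_segments(
    length: int, segments: Iterable[SegmentAnnotation]
) -> np.ndarray:
    """Fill a 0/1 label vector from 1-based inclusive linker intervals.

    Linker intervals must not overlap; explicit domain rows are validated
    for consistency (they must not cover a linker residue) but add nothing.
    """
    labels = np.zeros(length, dtype=np.int8)
    domain_rows = []
    for seg in segments:
        if seg.end > length:
            raise ValueError(
                f"interval ({seg.start}, {seg.end}) out of bounds for "
                f"{seg.seq_id!r} of length {length}"
            )
        if seg.label == "domain":
            domain_rows.append(seg)
            continue
        span = slice(seg.start - 1, seg.end)
        if labels[span].any():
            raise ValueError(
                f"overlapping linker intervals at ({seg.start}, {seg.end}) "
                f"for {seg.seq_id!r}"
            )
        labels[span] = LINKER
    for seg in domain_rows:
        if labels[seg.start - 1 : seg.end].any():
            raise ValueError(
                f"domain interval ({seg.start}, {seg.end}) for {seg.seq_id!r} "
                "overlaps a linker interval"
            )
    return labels


def read_annotations(
    path: str | Path, corpus: Sequence[ProteinSequence]
) -> AnnotatedCorpus:
    """Combine sequences with a linker-interval TSV into a labelled corpus.

    Sequences with no annotation rows get all-domain labels.
    """
    by_id = {seq.id: seq for seq in corpus}
    rows_by_id: dict[str, list[SegmentAnnotation]] = {seq.id: [] for seq in corpus}
    for row in _parse_annotation_rows(path):
        if row.seq_id not in by_id:
            raise ValueError(f"annotation references unknown sequence {row.seq_id!r}")
        rows_by_id[row.seq_id].append(row)
    labels = [
        labels_from_segments(len(by_id[sid]), rows_by_id[sid]) for sid in by_id
    ]
    return AnnotatedCorpus(sequences=list(corpus), labels=labels)


def segments_from_labels(seq_id: str, labels: np.ndarray) -> list[SegmentAnnotation]:
    """Run-length encode the maximal runs of 1s as 1-based linker intervals."""
    labels = np.asarray(labels).astype(np.int8)
    out = []
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    for s, e in zip(starts, ends):
        out.append(SegmentAnnotation(seq_id, int(s) + 1, int(e), "linker"))
    return out


def write_annotations(
    path: str | Path, segments: Iterable[SegmentAnnotation]
) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tlabel\n")
        for seg in segments:
            fh.write(f"{seg.seq_id}\t{seg.start}\t{seg.end}\t{seg.label}\n")


def write_predictions(path: str | Path, results: Iterable["PredictionResult"]) -> None:
    """Write per-residue predictions plus the derived linker segments.

    The per-residue block is ``seq_id  pos  linker_vote_fraction  label``;
    the trailing ``#SEGMENTS`` block is in annotation-TSV format so that
    predictions round-trip through :func:`read_annotations`.
    """
    results = list(results)
    with open(path, "w") as fh:
        fh.write("seq_id\tpos\tlinker_vote_fraction\tlabel\n")
        for res in results:
            for j, (v, lab) in enumerate(zip(res.vote_fraction, res.labels), 1):
                fh.write(f"{res.seq_id}\t{j}\t{v:.6g}\t{int(lab)}\n")
        fh.write("#SEGMENTS\n")
        fh.write("seq_id\tstart\tend\tlabel\n")
        for res in results:
            for seg in res.segments:
                fh.write(f"{seg.seq_id}\t{seg.start}\t{seg.end}\t{seg.label}\n")


def read_prediction_segments(path: str | Path) -> list[SegmentAnnotation]:
    """Read back only the #SEGMENTS block of a prediction file."""
    rows: list[SegmentAnnotation] = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "#SEGMENTS":
                in_block = True
                continue
            if not in_block or not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts == ["seq_id", "start", "end", "label"]:
                continue
            rows.append(SegmentAnnotation(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return rows
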