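"""Sequence I/O, six-frame translation, and open-reading-frame extraction.

Transcripts are nucleotide records over {A,C,G,T,N}; RNA input (U) is mapped
to DNA.  Translation uses the standard genetic code (NCBI table 1 -- nuclear
transcripts of a non-ciliate metazoan need nothing else), renders stop codons
as ``*`` and any codon containing ``N`` as ``X``.

An ORF here is a stop-to-stop segment of a reading frame, *not* an
ATG-anchored one: assembled transcripts are frequently truncated, and
precursor fragments lacking the initiator methionine are still worth
reporting.  An M-anchored mode is available via ``require_start``.

Coordinates are 0-based half-open on the forward strand of the transcript,
so that ``transcript.seq[nt_start:nt_end]`` (reverse-complemented first for
minus-strand ORFs) re-translates exactly to ``aa_seq``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTN")

#: (strand, frame) keys in canonical order.
FRAME_KEYS = (("+", 1), ("+", 2), ("+", 3), ("-", 1), ("-", 2), ("-", 3))


class FastaError(ValueError):
    """Raised for malformed FASTA input (empty, duplicate ids, bad symbols)."""


@dataclass(frozen=True)
class Transcript:
    """A nucleotide record: uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "Transcript":
        return Transcript(self.id, str(Seq(self.seq).reverse_complement()))


@dataclass(frozen=True)
class Orf:
    """A translated stop-free segment with forward-strand coordinates."""

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 1-3
    aa_seq: str
    nt_start: int  # 0-based, forward strand, half-open
    nt_end: int
    complete_start: bool  # initiator M at position 1
    complete_stop: bool  # in-frame stop codon follows

    @property
    def orf_id(self) -> str:
        return (
            f"{self.transcript_id}|{self.strand}{self.frame}"
            f"|{self.nt_start}-{self.nt_end}"
        )

    def __len__(self) -> int:
        return len(self.aa_seq)


def _clean_seq(raw: str, record_id: str) -> str:
    seq = "".join(raw.split()).upper().replace("U", "T")
    for offset, ch in enumerate(seq):
        if ch not in NT_ALPHABET:
            raise FastaError(
                f"record {record_id!r}: illegal character {ch!r} at offset {offset}"
            )
    return seq


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a (multi-line, CRLF-tolerant) FASTA file of nucleotide records.

    Raises :class:`FastaError` on an empty file, duplicate record ids, or
    characters outside {A,C,G,T,N,U} (case-insensitive; U is mapped to T).
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FastaError(f"duplicate record id {record.id!r}")
        seen.add(record.id)
        transcripts.append(Transcript(record.id, _clean_seq(str(record.seq), record.id)))
    if not transcripts:
        raise FastaError(f"no FASTA records found in {path}")
    return transcripts


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate_frame(seq: str) -> str:
    """Translate a DNA string from its first base; trailing 1-2 nt dropped."""
    usable = len(seq) - len(seq) % 3
    if usable == 0:
        return ""
    return str(Seq(seq[:usable]).translate())


def translate_six_frames(t: Transcript) -> dict[tuple[str, int], str]:
    """Translate all six reading frames, keyed by (strand, frame 1-3)."""
    if len(t.seq) < 3:
        warnings.warn(f"transcript {t.id!r} shorter than one codon; no frames")
        return {}
    rc = str(Seq(t.seq).reverse_complement())
    frames: dict[tuple[str, int], str] = {}
    for f in (1, 2, 3):
        frames[("+", f)] = translate_frame(t.seq[f - 1 :])
        frames[("-", f)] = translate_frame(rc[f - 1 :])
    return frames


def _segment_coords(
    strand: str, frame: int, aa_start: int, aa_end: int, seq_len: int
) -> tuple[int, int]:
    """Forward-strand nt span of aa positions [aa_start, aa_end) in a frame."""
    off = frame - 1
    lo = off + 3 * aa_start
    hi = off + 3 * aa_end
    if strand == "+":
        return lo, hi
    return seq_len - hi, seq_len - lo


def extract_orfs(
    t: Transcript,
    min_aa_len: int = 50,
    require_start: bool = False,
    frames: dict[tuple[str, int], str] | None = None,
) -> list[Orf]:
    """Split each frame at stop codons into ORFs of at least ``min_aa_len``.

    With ``require_start=True`` each segment is trimmed to its first M and
    discarded if none is present.
    """
    if frames is None:
        frames = translate_six_frames(t)
    orfs: list[Orf] = []
    for (strand, frame), aa in frames.items():
        pos = 0
        for chunk in aa.split("*"):
            start, end = pos, pos + len(chunk)
            pos = end + 1  # skip the '*'
            if require_start:
                m = chunk.find("M")
                if m < 0:
                    continue
                chunk = chunk[m:]
                start += m
            if len(chunk) < min_aa_len:
                continue
            nt_start, nt_end = _segment_coords(strand, frame, start, end, len(t.seq))
            orfs.append(
                Orf(
                    transcript_id=t.id,
                    strand=strand,
                    frame=frame,
                    aa_seq=chunk,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    complete_start=chunk.startswith("M"),
                    complete_stop=end < len(aa),
                )
            )
    orfs.sort(key=lambda o: (o.strand, o.frame, o.nt_start))
    return orfs


def orf_nt_seq(orf: Orf, transcript: Transcript) -> str:
    """The coding nucleotides of an ORF, read 5'->3' on its own strand."""
    span = transcript.seq[orf.nt_start : orf.nt_end]
    if orf.strand == "-":
        span = str(Seq(span).reverse_complement())
    return span


def orf_table(orfs: Iterable[Orf]):
    """ORF metadata as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "transcript_id": o.transcript_id,
                "strand": o.strand,
                "frame": o.frame,
                "nt_start": o.nt_start,
                "nt_end": o.nt_end,
                "aa_len": len(o.aa_seq),
                "complete_start": o.complete_start,
                "complete_stop": o.complete_stop,
            }
            for o in orfs
        ],
        columns=[
            "transcript_id",
            "strand",
            "frame",
            "nt_start",
            "nt_end",
            "aa_len",
            "complete_start",
            "complete_stop",
        ],
    )
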