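"""Synthetic transcriptome generation for end-to-end testing.

Real cubomedusan preprohormone transcripts have a fixed anatomy: a signal
peptide, a short propeptide ending at a dibasic junction, a run of immature
peptide units -- each ``[flank residue] + core + G + basic motif`` -- and an
acidic tail before the stop codon.  :func:`build_transcriptome` emits seven
such precursors whose peptide cores, flank conventions, copy numbers and
N->C order follow the *Tripedalia cystophora* repertoire (an RFamide, a
short poly-Arg RFamide, a VWamide, an LWamide, an RAamide, an RYamide and a
cyclic FRamide precursor), reverse-translates them with random synonymous
codons, embeds them on a random strand between random UTRs, and adds
composition-preserving shuffled decoys.  A JSON manifest records the ground
truth so pipeline output can be scored without external data.

Every random choice flows from one integer seed; a fixed seed gives
byte-identical FASTA and manifest output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import discovery, seqcore
from .maturation import PQ_CONTEXT, mature_segment
from .seqcore import Transcript, write_fasta

#: Signal-like leader: initiator M, 14-residue hydrophobic h-region, 3 polar.
DEFAULT_LEADER = "M" + "LALLFVALIVALMA" + "SES"

#: Dibasic junction separating the leader/propeptide from the first unit.
DEFAULT_JUNCTION = "KR"

#: Acidic tail after the last unit, before the stop codon.
DEFAULT_TAIL = "SDDEAN"


@dataclass(frozen=True)
class PeptideUnit:
    core: str
    flank: str | None  # single residue preceding the core, or None
    motif: str = "GKR"  # amidating motif terminating the unit


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    units: tuple[PeptideUnit, ...]
    leader: str = DEFAULT_LEADER
    junction: str = DEFAULT_JUNCTION
    tail: str = DEFAULT_TAIL
    spacer: str = ""  # between units; repeats are contiguous in vivo


def _units(core_flank_motif: list[tuple[str, str | None, str]]) -> tuple[PeptideUnit, ...]:
    return tuple(PeptideUnit(c, f, m) for c, f, m in core_flank_motif)


_RFAMIDE_FLANKS = ["E", "D", "E", "E", "D", "E", "E", "D", "E", "E",
                   "D", "E", "E", "D", "E", "E", "D", "E", "E"]

TABLE1_SPECS: tuple[FixtureSpec, ...] = (
    FixtureSpec(
        "Tcy-RFamide",
        _units([("QWLRGRF", f, "GKR") for f in _RFAMIDE_FLANKS]
               + [("QFLRGRF", "E", "GKR")]),
    ),
    FixtureSpec(
        "Tcy-RFamide-II",
        _units([("RF", None, "GRR")] * 6),
    ),
    FixtureSpec(
        "Tcy-VWamide",
        _units([("QPPGVW", f, "GKR") for f in ["S", "T", "A", "S", "T", "S"]]),
    ),
    FixtureSpec(
        "Tcy-LWamide",
        _units([
            ("GNPKGGSILW", None, "GKR"),
            ("LQPGMW", "E", "GKR"),
            ("SLVQPRLNMLW", None, "GKR"),
            ("AMKEESPRLGLW", None, "GKR"),
            ("REMLERPKVGLW", None, "GKR"),
            ("SSKPGKVGLW", None, "GKR"),
            ("PDRPIEGLW", None, "GKR"),
            ("KGKPGTVGLW", None, "GKR"),
        ]),
    ),
    FixtureSpec(
        "Tcy-RAamide",
        _units(
            [("QPRS", "E", "GKR")]
            + [("RPRA", None, "GKR")] * 2
            + [("QVLTRPRG", "R", "GKR")]
            + [("RPRA", None, "GKR")] * 5
            + [("QPRS", "E", "GKR")]
            + [("RPRA", None, "GKR")] * 3
            + [("QPRS", "E", "GKR")]
            + [("RPRA", None, "GKR")] * 3
        ),
    ),
    FixtureSpec(
        "Tcy-RYamide",
        _units([
            ("TPPWVKGRY", None, "GKR"),
            ("QMWHRQRY", "E", "GKR"),
            ("APGWHHGRY", None, "GKR"),
            ("TPLWAKGRY", None, "GKR"),
        ]),
    ),
    FixtureSpec(
        "Tcy-FRamide",
        _units([
            ("CTGQMCWFR", None, "GKR"),
            ("CKGQMCWFR", None, "GKR"),
            ("CTGQMCWFR", None, "GKR"),
            ("CTGQMCWFR", None, "GKR"),
            ("CVGQMCWFR", None, "GKR"),
            ("CKGQMCWFR", None, "GKR"),
            ("CTGQMCWFR", None, "GKR"),
        ]),
    ),
)


def expected_display(unit: PeptideUnit, aminopeptidase_l_rule: bool = True) -> str:
    """Ground-truth mature display string for one encoded unit."""
    seg = (unit.flank or "") + unit.core
    context = PQ_CONTEXT | {"L"} if aminopeptidase_l_rule else PQ_CONTEXT
    for i, ch in enumerate(seg):
        if ch == "Q" and (i == 0 or seg[i - 1] in context):
            return "pQ" + seg[i + 1 :] + "amide"
    return seg + "amide"


@dataclass
class GroundTruth:
    name: str
    transcript_id: str
    strand: str
    cds_start: int  # forward-strand nt coords of leader..tail (excl. stop)
    cds_end: int
    protein: str
    peptides: list[dict] = field(default_factory=list)  # position, display

    @property
    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {}
        for p in self.peptides:
            c[p["display"]] = c.get(p["display"], 0) + 1
        return c


def build_precursor(spec: FixtureSpec) -> tuple[str, list[dict]]:
    """Assemble the precursor protein and its per-unit ground truth."""
    parts = [spec.leader, spec.junction]
    truth: list[dict] = []
    for i, unit in enumerate(spec.units):
        parts.append((unit.flank or "") + unit.core + unit.motif)
        if i < len(spec.units) - 1:
            parts.append(spec.spacer)
        truth.append({"position": i + 1, "display": expected_display(unit)})
    parts.append(spec.tail)
    return "".join(parts), truth


_CODONS_BY_AA: dict[str, list[str]] = {}
_table = CodonTable.unambiguous_dna_by_id[1]
for _codon, _aa in _table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
STOP_CODONS = tuple(sorted(_table.stop_codons))


def reverse_translate(aa: str, rng: np.random.Generator) -> str:
    """Encode a protein with uniformly random synonymous codons."""
    try:
        return "".join(
            _CODONS_BY_AA[ch][rng.integers(len(_CODONS_BY_AA[ch]))] for ch in aa
        )
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate residue {exc}") from None


def _random_utr(rng: np.random.Generator, lo: int = 30, hi: int = 120) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _passed_candidates(transcript: Transcript) -> list[discovery.PrecursorCandidate]:
    orfs = seqcore.extract_orfs(transcript, min_aa_len=50)
    cands = [discovery.discover(o) for o in orfs]
    return [c for c in discovery.curate_candidates(cands) if c.passed]


def _embed(protein: str, rng: np.random.Generator, tid: str) -> tuple[Transcript, str, int, int]:
    """Place a coding sequence between UTRs on a random strand."""
    utr5, utr3 = _random_utr(rng), _random_utr(rng)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    cds = reverse_translate(protein, rng)
    # in-frame stop before the ATG so the ORF segment starts at the leader M
    fwd = utr5 + "TAA" + cds + stop + utr3
    cds_start = len(utr5) + 3
    cds_end = cds_start + len(cds)
    strand = "+" if rng.integers(2) == 0 else "-"
    if strand == "-":
        fwd_rc = str(Seq(fwd).reverse_complement())
        cds_start, cds_end = len(fwd) - cds_end, len(fwd) - cds_start
        fwd = fwd_rc
    return Transcript(tid, fwd), strand, cds_start, cds_end


def _build_one(
    spec: FixtureSpec, rng: np.random.Generator, max_attempts: int = 20
) -> tuple[GroundTruth, Transcript]:
    """Embed one precursor; regenerate codons until the transcript screens
    cleanly (exactly one passed candidate reproducing the encoded units)."""
    protein, truth = build_precursor(spec)
    tid = "fx_" + spec.name.lower().replace("-", "_")
    for _ in range(max_attempts):
        transcript, strand, cds_start, cds_end = _embed(protein, rng, tid)
        passed = _passed_candidates(transcript)
        if len(passed) != 1 or passed[0].orf.strand != strand:
            continue
        cand = passed[0]
        displays = [
            mature_segment(s, aminopeptidase_l_rule=True).display
            for s in cand.segments
        ]
        if displays == [t["display"] for t in truth]:
            return GroundTruth(
                spec.name, tid, strand, cds_start, cds_end, protein, truth
            ), transcript
        # fall through: re-roll codons
    raise RuntimeError(f"could not build a clean fixture for {spec.name}")


def _build_decoy(
    proteins: list[str], i: int, rng: np.random.Generator, max_attempts: int = 100
) -> Transcript:
    """A composition-preserving shuffle of a precursor, screened so the
    shuffle did not accidentally recreate a precursor-like repeat."""
    base = proteins[i % len(proteins)]
    tid = f"decoy_{i:03d}"
    for _ in range(max_attempts):
        shuffled = "".join(np.array(list(base))[rng.permutation(len(base))])
        transcript, _, _, _ = _embed(shuffled, rng, tid)
        if not _passed_candidates(transcript):
            return transcript
    raise RuntimeError(f"could not build a motif-free decoy for {tid}")


def build_transcriptome(
    specs: tuple[FixtureSpec, ...] = TABLE1_SPECS,
    n_decoys: int = 100,
    seed: int = 17,
    out_fasta: str | Path | None = None,
    out_manifest: str | Path | None = None,
) -> tuple[list[Transcript], dict]:
    """Generate the synthetic transcriptome and its ground-truth manifest."""
    rng = np.random.default_rng(seed)
    records: list[Transcript] = []
    truths: list[GroundTruth] = []
    for spec in specs:
        truth, transcript = _build_one(spec, rng)
        truths.append(truth)
        records.append(transcript)
    proteins = [t.protein for t in truths]
    for i in range(n_decoys):
        records.append(_build_decoy(proteins, i, rng))
    manifest = {
        "seed": seed,
        "n_decoys": n_decoys,
        "aminopeptidase_l_rule": True,
        "coordinates": "0-based half-open, forward strand",
        "precursors": [
            {
                "name": t.name,
                "transcript_id": t.transcript_id,
                "strand": t.strand,
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
                "protein": t.protein,
                "peptides": t.peptides,
                "counts": t.counts,
            }
            for t in truths
        ],
        "decoy_ids": [r.id for r in records[len(truths):]],
    }
    if out_fasta is not None:
        write_fasta(((r.id, r.seq) for r in records), out_fasta)
    if out_manifest is not None:
        Path(out_manifest).write_text(json.dumps(manifest, indent=1) + "\n")
    return records, manifest
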