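"""Prohormone processing rules: from peptide segments to mature peptides.

C-terminus.  A segment that ends at an amidating motif (G + basic residues)
loses the glycine and basic residues to convertase cleavage and carboxy-
peptidase trimming; the glycine leaves behind a C-terminal amide group
(peptidylglycine alpha-amidating monooxygenase).  Segments ending at a
plain dibasic site are liberated un-amidated; they are reported flagged but
excluded from copy tallies, since the secreted products of these precursors
are the amidated peptides.

N-terminus.  Cnidarian precursors are processed at unconventional
N-terminal sites.  A glutamine immediately downstream of an acidic (D/E),
basic (K/R) or small polar (S/T/A) residue -- or sitting directly at a
cleavage boundary -- is taken as the mature N-terminus and cyclized to
pyroglutamate (pQ), which protects the peptide from aminopeptidases.  The
most N-terminal eligible Q wins.  Leucine is *not* an eligible context by
default: cleavage C-terminal of L requires a hypothetical aminopeptidase,
and enabling ``aminopeptidase_l_rule`` opts into it explicitly (it turns
e.g. ...ELQPGMW-G-KR into pQPGMWamide).  When no eligible Q exists the full
segment is reported; if its second residue is a proline the N-terminus is
considered protected by the imide bond (confidence ``certain``), otherwise
the N-terminus is flagged ``uncertain``.

Peptides whose core starts and has a second cysteine at position 6 are
flagged cyclic (intrachain Cys1-Cys6 cystine bridge).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .discovery import PeptideSegment
from .seqcore import Orf

#: Default residues accepted immediately N-terminal of a pyroglutamate Q.
PQ_CONTEXT = frozenset("DEKRSTA")

#: Strongly hydrophobic residues used by the signal-peptide heuristic.
HYDROPHOBIC = frozenset("AILMFVWC")


@dataclass(frozen=True)
class MaturePeptide:
    core: str  # predicted secreted sequence, no G / basic motif residues
    c_term_amide: bool
    n_term_mod: str  # 'pyroglutamate' or 'free'
    n_term_protection: str  # 'pQ', 'proline_imide', or 'none'
    n_term_confidence: str  # 'certain' or 'uncertain'
    cyclic: bool = False
    segment: PeptideSegment | None = None
    flags: tuple[str, ...] = ()

    @property
    def display(self) -> str:
        body = "pQ" + self.core[1:] if self.n_term_mod == "pyroglutamate" else self.core
        return body + ("amide" if self.c_term_amide else "")

    @property
    def family(self) -> str:
        """C-terminal signature family, e.g. RFamide, LWamide."""
        if not self.c_term_amide or len(self.core) < 2:
            return "unamidated"
        return self.core[-2:] + "amide"


@dataclass
class TalliedPeptide:
    position: int  # 1-based, N- to C-terminus
    peptide: MaturePeptide
    subfamily: str = "unassigned"


@dataclass
class PeptideTally:
    precursor_id: str
    peptides: list[TalliedPeptide] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c: Counter[str] = Counter(tp.peptide.display for tp in self.peptides)
        return dict(c)

    @property
    def families(self) -> dict[str, str]:
        return {tp.peptide.display: tp.peptide.family for tp in self.peptides}


@dataclass(frozen=True)
class GphSkeleton:
    sequence_id: str
    cys_positions: tuple[int, ...]
    n_cys: int
    skeleton_ok: bool


def mature_segment(
    seg: PeptideSegment,
    pq_context: frozenset[str] = PQ_CONTEXT,
    aminopeptidase_l_rule: bool = False,
) -> MaturePeptide:
    """Apply N- and C-terminal processing rules to one segment."""
    if not seg.raw_seq:
        raise ValueError("cannot mature an empty segment")
    amide = seg.right_motif.startswith("G")
    flags: list[str] = list(seg.flags)
    if not amide:
        flags.append("no_amide_donor")
    context = pq_context | {"L"} if aminopeptidase_l_rule else pq_context
    raw = seg.raw_seq
    q_at = -1
    for i, ch in enumerate(raw):
        if ch == "Q" and (i == 0 or raw[i - 1] in context):
            q_at = i
            break
    if q_at >= 0:
        pep = MaturePeptide(
            core=raw[q_at:],
            c_term_amide=amide,
            n_term_mod="pyroglutamate",
            n_term_protection="pQ",
            n_term_confidence="certain",
            segment=seg,
            flags=tuple(flags),
        )
    elif len(raw) >= 2 and raw[1] == "P":
        pep = MaturePeptide(
            core=raw,
            c_term_amide=amide,
            n_term_mod="free",
            n_term_protection="proline_imide",
            n_term_confidence="certain",
            segment=seg,
            flags=tuple(flags),
        )
    else:
        pep = MaturePeptide(
            core=raw,
            c_term_amide=amide,
            n_term_mod="free",
            n_term_protection="none",
            n_term_confidence="uncertain",
            segment=seg,
            flags=tuple(flags),
        )
    return detect_cyclic(pep)


def detect_cyclic(pep: MaturePeptide) -> MaturePeptide:
    """Flag an intrachain Cys1-Cys6 cystine bridge (cyclic peptide)."""
    cyclic = len(pep.core) >= 6 and pep.core[0] == "C" and pep.core[5] == "C"
    return replace(pep, cyclic=cyclic)


def tally_and_classify(
    peptides: list[MaturePeptide],
    precursor_id: str,
    include_unamidated: bool = False,
) -> PeptideTally:
    """Order peptides N->C, index positions, and merge duplicate displays.

    Copy counts are exposed via :attr:`PeptideTally.counts`; positions are
    1-based ordinal indices over the retained (amidated) peptides, used for
    cross-species positional subfamily comparison.
    """
    retained = [p for p in peptides if p.c_term_amide or include_unamidated]
    return PeptideTally(
        precursor_id,
        [TalliedPeptide(i + 1, p) for i, p in enumerate(retained)],
    )


def load_subfamily_signatures(path: str | Path | None = None) -> list[dict]:
    """Load the positional subfamily signature table (editable JSON)."""
    if path is None:
        text = (
            resources.files("prepromine") / "data" / "subfamily_signatures.json"
        ).read_text()
    else:
        text = Path(path).read_text()
    return json.loads(text)["signatures"]


def assign_positional_subfamilies(
    tally: PeptideTally, signatures: list[dict] | None = None
) -> PeptideTally:
    """Assign each peptide the subfamily whose position + pattern it matches.

    Orthologous cnidarian precursors carry their peptide variants in a
    conserved N->C order; a subfamily signature is therefore a pair of
    (ordinal position, C-terminal sequence pattern).  Peptides matching no
    signature stay ``unassigned``.
    """
    if signatures is None:
        signatures = load_subfamily_signatures()
    for tp in tally.peptides:
        stem = tp.peptide.display.removesuffix("amide")
        for sig in signatures:
            if tp.position in sig["positions"] and re.search(sig["pattern"], stem):
                tp.subfamily = sig["subfamily"]
                break
    return tally


def signal_peptide_heuristic(
    orf: Orf, window: int = 12, min_hydrophobic: int = 8, search_span: int = 40
) -> tuple[str, float]:
    """Crude signal-peptide presence check: ('complete'|'partial', score).

    An ORF is called ``complete`` when it starts with the initiator M and a
    hydrophobic stretch (>= ``min_hydrophobic`` of ``window`` residues in
    {A,I,L,M,F,V,W,C}) occurs within its first ``search_span`` residues --
    the signature of a signal peptide's h-region.  The score is the best
    window's hydrophobic fraction.  This is a deliberately simple heuristic
    for triaging candidates, not a cleavage-site predictor.
    """
    head = orf.aa_seq[:search_span]
    best = 0
    for i in range(max(1, len(head) - window + 1)):
        best = max(best, sum(1 for ch in head[i : i + window] if ch in HYDROPHOBIC))
    score = best / window
    complete = orf.complete_start and best >= min_hydrophobic
    return ("complete" if complete else "partial"), score


def gph_skeleton_check(
    aa_seq: str, sequence_id: str = "", min_cys: int = 11, window: int = 160
) -> GphSkeleton:
    """Check the cysteine skeleton expected of a glycoprotein hormone subunit.

    GPH subunits carry ten bridge-forming cysteines (five intramolecular
    cystines) plus one free cysteine for the intersubunit bridge, all within
    the compact cystine-knot domain; ``skeleton_ok`` requires ``min_cys``
    cysteines inside some ``window``-residue stretch.
    """
    if len(aa_seq) < 60:
        raise ValueError("sequence too short to contain a cystine-knot domain")
    pos = tuple(i for i, ch in enumerate(aa_seq) if ch == "C")
    ok = False
    for k in range(len(pos)):
        j = k + min_cys - 1
        if j < len(pos) and pos[j] - pos[k] < window:
            ok = True
            break
    return GphSkeleton(sequence_id, pos, len(pos), ok)
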