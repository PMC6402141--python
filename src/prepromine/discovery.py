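"""The preprohormone screening algorithm.

A candidate precursor is an ORF carrying at least three *primary* processing
sites -- the amidation/cleavage motifs GKR, GKK, GR and GR(R) recognized by
prohormone convertases (PC 1/3, PC 2), where the glycine is the substrate of
peptidylglycine alpha-amidating monooxygenase -- whose liberated peptide
segments form a mutually similar repeat cluster.  Dibasic KR/KK sites
without a preceding glycine are *secondary*: they delimit segments (e.g. the
junction between a signal/propeptide region and the first peptide) but do
not count towards the threshold and do not yield amidated products.

Monobasic sites (GR, GRR) are accepted only when the residue that follows
the motif is not strongly hydrophobic ({F,Y,W,L,I,M,V}): single-arginine
convertase cleavage is context dependent, and the GR dipeptide occurs
*inside* many mature cnidarian peptides (e.g. the ...GRFamide and
...GRYamide cores) where it is demonstrably not cleaved.  Rejected matches
are still reported, flagged ``context_ok=False``, and ignored downstream.

Scanning is left-to-right with longest-match priority at each position
(GKR > GKK > GRR > GR > KR > KK) and non-overlapping consumption: one
junction is one cleavage event.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace

import networkx as nx
from Bio import Align

from .seqcore import Orf

#: Longest-match priority order at a scan position.
MOTIF_PRIORITY = ("GKR", "GKK", "GRR", "GR", "KR", "KK")
PRIMARY_MOTIFS = frozenset({"GKR", "GKK", "GRR", "GR"})

#: Residues disallowed immediately after a monobasic (single-Arg) site.
P1PRIME_EXCLUDED = frozenset("FYWLIMV")
MONOBASIC = frozenset({"GR", "GRR"})


@dataclass(frozen=True)
class CleavageSite:
    orf_pos: int  # 0-based index of the first motif residue
    motif: str
    amidating: bool  # motif begins with the amide-donor G
    scan_class: str  # 'primary' or 'secondary'
    context_ok: bool = True  # False: monobasic site with hydrophobic P1'

    @property
    def end(self) -> int:
        return self.orf_pos + len(self.motif)


@dataclass(frozen=True)
class PeptideSegment:
    start: int  # 0-based half-open within aa_seq; motif residues excluded
    end: int
    raw_seq: str
    left_flank: str  # residue preceding start; '^' at ORF start
    right_motif: str
    flags: tuple[str, ...] = ()


@dataclass
class SimilarityResult:
    mean_identity: float
    passed: bool
    cluster: tuple[int, ...]  # indices into the segment list


@dataclass
class PrecursorCandidate:
    orf: Orf
    sites: list[CleavageSite]
    segments: list[PeptideSegment]
    n_primary_sites: int
    mean_pairwise_identity: float
    passed: bool
    cluster: tuple[int, ...] = ()
    curation_flags: list[str] = field(default_factory=list)


def scan_motifs(aa_seq: str, include_lone_arg: bool = False) -> list[CleavageSite]:
    """Locate processing motifs left-to-right, longest match first.

    ``include_lone_arg`` additionally reports single R residues as secondary
    sites; this is the explicit poly-arginine (RRR) segmentation mode and is
    off by default.
    """
    motifs = MOTIF_PRIORITY + (("R",) if include_lone_arg else ())
    sites: list[CleavageSite] = []
    i, n = 0, len(aa_seq)
    while i < n:
        for m in motifs:
            if aa_seq.startswith(m, i):
                primary = m in PRIMARY_MOTIFS
                if m in MONOBASIC:
                    j = i + len(m)
                    ok = j >= n or aa_seq[j] not in P1PRIME_EXCLUDED
                else:
                    ok = True
                sites.append(
                    CleavageSite(
                        orf_pos=i,
                        motif=m,
                        amidating=m.startswith("G"),
                        scan_class="primary" if primary else "secondary",
                        context_ok=ok,
                    )
                )
                i += len(m)
                break
        else:
            i += 1
    return sites


def count_primary_sites(sites: list[CleavageSite]) -> int:
    return sum(1 for s in sites if s.scan_class == "primary" and s.context_ok)


def apply_site_threshold(sites: list[CleavageSite], min_sites: int = 3) -> bool:
    """The core screening rule: at least ``min_sites`` primary sites."""
    return count_primary_sites(sites) >= min_sites


def segment_candidates(
    orf: Orf, sites: list[CleavageSite], max_peptide_len: int = 30
) -> list[PeptideSegment]:
    """Cut the ORF at accepted sites; keep segments ending at amidating ones.

    Each retained segment spans from the end of the previous accepted site
    (or the ORF start) to the first residue of its terminating motif.
    Unknown residues (X) at the segment edges are trimmed -- they arise from
    Ns in the assembly and cannot be part of a real peptide.  Segments
    longer than ``max_peptide_len`` are truncated to their C-terminal window
    and flagged ``long_nterm``.
    """
    aa = orf.aa_seq
    segments: list[PeptideSegment] = []
    prev_end = 0
    for site in sites:
        if not site.context_ok:
            continue
        if site.amidating:
            start, end = prev_end, site.orf_pos
            flags: list[str] = []
            raw = aa[start:end]
            stripped = raw.lstrip("X")
            if len(stripped) != len(raw):
                flags.append("x_trimmed")
                start += len(raw) - len(stripped)
            raw = stripped.rstrip("X")
            end = start + len(raw)
            if len(raw) > max_peptide_len:
                flags.append("long_nterm")
                start = end - max_peptide_len
                raw = aa[start:end]
            if raw:
                segments.append(
                    PeptideSegment(
                        start=start,
                        end=end,
                        raw_seq=raw,
                        left_flank=aa[start - 1] if start > 0 else "^",
                        right_motif=site.motif,
                        flags=tuple(flags),
                    )
                )
        prev_end = site.end
    return segments


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, normalized by the shorter sequence.

    Short neuropeptide repeats differ mostly by N-terminal extensions, so
    matches over the shorter peptide is the natural yardstick; a plain
    alignment-length denominator would punish a 4-residue peptide aligned
    against a 9-residue sibling for length alone.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    return aln.counts().identities / min(len(a), len(b))


def similarity_filter(
    segments: list[PeptideSegment],
    min_cluster: int = 3,
    min_identity: float = 0.5,
    cterm_window: int = 12,
) -> SimilarityResult:
    """Find the largest segment cluster in which every pair is similar.

    Similarity is pairwise global identity over the C-terminal
    ``cterm_window`` residues of each segment (the family-defining end of a
    cnidarian neuropeptide).  The candidate passes when some cluster of at
    least ``min_cluster`` segments has every pair >= ``min_identity``.
    """
    n = len(segments)
    if n < 2:
        return SimilarityResult(0.0, False, ())
    tails = [s.raw_seq[-cterm_window:] for s in segments]
    ident: dict[tuple[int, int], float] = {}
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        ident[(i, j)] = pairwise_identity(tails[i], tails[j])
        if ident[(i, j)] >= min_identity:
            g.add_edge(i, j)
    best: tuple[int, ...] = ()
    for clique in nx.find_cliques(g):
        clique = tuple(sorted(clique))
        if (len(clique), [-c for c in clique]) > (len(best), [-c for c in best]):
            best = clique
    if len(best) < 2:
        return SimilarityResult(0.0, False, ())
    pairs = list(itertools.combinations(best, 2))
    mean = sum(ident[p] for p in pairs) / len(pairs)
    return SimilarityResult(mean, len(best) >= min_cluster, best)


def low_complexity(seq: str, max_fraction: float = 0.8) -> bool:
    """True when a single residue accounts for >= ``max_fraction`` of seq."""
    if not seq:
        return True
    return Counter(seq).most_common(1)[0][1] / len(seq) >= max_fraction


def discover(
    orf: Orf,
    min_sites: int = 3,
    min_cluster: int = 3,
    min_identity: float = 0.5,
    max_peptide_len: int = 30,
    include_lone_arg: bool = False,
) -> PrecursorCandidate:
    """Run the full screen on one ORF: scan, threshold, segment, cluster."""
    sites = scan_motifs(orf.aa_seq, include_lone_arg=include_lone_arg)
    n_primary = count_primary_sites(sites)
    flags: list[str] = []
    if not apply_site_threshold(sites, min_sites):
        flags.append("below_site_threshold")
        return PrecursorCandidate(
            orf, sites, [], n_primary, 0.0, False, (), flags
        )
    segments = segment_candidates(orf, sites, max_peptide_len)
    sim = similarity_filter(segments, min_cluster, min_identity)
    if not sim.passed:
        flags.append("low_similarity")
    return PrecursorCandidate(
        orf,
        sites,
        segments,
        n_primary,
        sim.mean_identity,
        sim.passed,
        sim.cluster,
        flags,
    )


def curate_candidates(
    candidates: list[PrecursorCandidate], max_peptide_len: int = 30
) -> list[PrecursorCandidate]:
    """Deterministic stand-in for the final manual rejection step.

    Candidates whose similarity cluster is dominated by low-complexity
    segments (single-residue runs; e.g. poly-K stretches that happen to be
    rich in KK/KR matches), or whose cluster peptides exceed the plausible
    length ceiling, are rejected with an explanatory flag.  This encodes the
    two unambiguous reasons a human curator discards a screen hit; judgment
    calls beyond them are out of scope.
    """
    curated: list[PrecursorCandidate] = []
    for cand in candidates:
        if not cand.passed:
            curated.append(cand)
            continue
        flags = list(cand.curation_flags)
        cluster_segs = [cand.segments[i] for i in cand.cluster]
        n_low = sum(1 for s in cluster_segs if low_complexity(s.raw_seq))
        if cluster_segs and n_low / len(cluster_segs) >= 0.5:
            flags.append("low_complexity")
        if any(len(s.raw_seq) > max_peptide_len or "long_nterm" in s.flags for s in cluster_segs):
            flags.append("overlong_peptide")
        rejected = len(flags) > len(cand.curation_flags)
        curated.append(
            replace(cand, passed=cand.passed and not rejected, curation_flags=flags)
        )
    return curated
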