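"""End-to-end precursor mining pipeline and manifest scoring.

``run_pipeline`` chains sequence reading, six-frame ORF extraction, the
motif/similarity screen, curation and maturation, and renders candidate and
peptide tables plus an annotated plain-text view of each passed precursor.
All outputs are deterministic functions of the input FASTA and the
configuration; the configuration (seed included) is echoed in every output
header so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import discovery, maturation, seqcore

logger = logging.getLogger("prepromine")

COORD_NOTE = "coordinates: 0-based half-open, forward strand"


@dataclass
class RunConfig:
    input_fasta: str = ""
    min_sites: int = 3
    min_identity: float = 0.5
    min_cluster: int = 3
    min_aa_len: int = 50
    max_peptide_len: int = 30
    require_start: bool = False
    aminopeptidase_l_rule: bool = False
    include_lone_arg: bool = False
    seed: int = 17
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("min_sites", "min_identity", "min_cluster", "min_aa_len", "max_peptide_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    config: RunConfig
    candidates: list[discovery.PrecursorCandidate]
    tallies: dict[str, maturation.PeptideTally]  # orf_id -> tally (passed only)
    summary: dict
    candidate_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    peptide_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _candidate_table(cands: list[discovery.PrecursorCandidate]) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append(
            {
                "transcript_id": c.orf.transcript_id,
                "orf_id": c.orf.orf_id,
                "strand": c.orf.strand,
                "frame": c.orf.frame,
                "aa_len": len(c.orf.aa_seq),
                "n_primary_sites": c.n_primary_sites,
                "n_segments": len(c.segments),
                "mean_identity": round(c.mean_pairwise_identity, 4),
                "passed": c.passed,
                "flags": ";".join(c.curation_flags) or ".",
            }
        )
    cols = ["transcript_id", "orf_id", "strand", "frame", "aa_len",
            "n_primary_sites", "n_segments", "mean_identity", "passed", "flags"]
    return pd.DataFrame(rows, columns=cols)


def _peptide_table(tallies: dict[str, maturation.PeptideTally]) -> pd.DataFrame:
    rows = []
    for orf_id, tally in tallies.items():
        counts = tally.counts
        for tp in tally.peptides:
            p = tp.peptide
            rows.append(
                {
                    "precursor_id": orf_id,
                    "transcript_id": orf_id.split("|")[0],
                    "position": tp.position,
                    "display": p.display,
                    "copies_of_display": counts[p.display],
                    "core": p.core,
                    "amide": p.c_term_amide,
                    "n_term_mod": p.n_term_mod,
                    "protection": p.n_term_protection,
                    "confidence": p.n_term_confidence,
                    "cyclic": p.cyclic,
                    "family": p.family,
                    "subfamily": tp.subfamily,
                }
            )
    cols = ["precursor_id", "transcript_id", "position", "display",
            "copies_of_display", "core", "amide", "n_term_mod", "protection",
            "confidence", "cyclic", "family", "subfamily"]
    return pd.DataFrame(rows, columns=cols)


def render_precursor(cand: discovery.PrecursorCandidate,
                     tally: maturation.PeptideTally) -> str:
    """Annotated plain-text rendering of one precursor.

    Peptide segments are wrapped in ``{...}`` and processing motifs in
    ``[...]``; a legend line lists the mature products.  This is the
    machine-checkable counterpart of a color-highlighted precursor figure.
    """
    aa = cand.orf.aa_seq
    marks: list[tuple[int, int, str]] = []
    for seg in cand.segments:
        marks.append((seg.start, seg.end, "{}"))
    for site in cand.sites:
        if site.context_ok:
            marks.append((site.orf_pos, site.end, "[]"))
    marks.sort()
    out, prev = [], 0
    for start, end, kind in marks:
        if start < prev:
            continue
        out.append(aa[prev:start])
        out.append(kind[0] + aa[start:end] + kind[1])
        prev = end
    out.append(aa[prev:])
    sig, score = maturation.signal_peptide_heuristic(cand.orf)
    lines = [
        f"# precursor {cand.orf.orf_id}",
        f"# signal_peptide={sig} (hydrophobic fraction {score:.2f})",
        f"# n_primary_sites={cand.n_primary_sites} mean_identity={cand.mean_pairwise_identity:.3f}",
        "".join(out),
        "# mature peptides: "
        + ", ".join(f"{d} x{n}" for d, n in tally.counts.items()),
        "",
    ]
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full screen and (optionally) write the report bundle."""
    transcripts = seqcore.read_fasta(config.input_fasta)
    logger.info("read %d transcripts from %s", len(transcripts), config.input_fasta)
    candidates: list[discovery.PrecursorCandidate] = []
    n_orfs = 0
    for t in transcripts:
        orfs = seqcore.extract_orfs(
            t, min_aa_len=config.min_aa_len, require_start=config.require_start
        )
        n_orfs += len(orfs)
        for orf in orfs:
            candidates.append(
                discovery.discover(
                    orf,
                    min_sites=config.min_sites,
                    min_cluster=config.min_cluster,
                    min_identity=config.min_identity,
                    max_peptide_len=config.max_peptide_len,
                    include_lone_arg=config.include_lone_arg,
                )
            )
    candidates = discovery.curate_candidates(candidates, config.max_peptide_len)
    signatures = maturation.load_subfamily_signatures()
    tallies: dict[str, maturation.PeptideTally] = {}
    for cand in candidates:
        if not cand.passed:
            continue
        peptides = [
            maturation.mature_segment(
                seg, aminopeptidase_l_rule=config.aminopeptidase_l_rule
            )
            for seg in cand.segments
        ]
        tally = maturation.tally_and_classify(peptides, cand.orf.orf_id)
        maturation.assign_positional_subfamilies(tally, signatures)
        tallies[cand.orf.orf_id] = tally
        logger.info(
            "passed candidate %s: %d primary sites, %d peptides [%s]",
            cand.orf.orf_id, cand.n_primary_sites, len(tally.peptides),
            ";".join(cand.curation_flags) or "-",
        )
    summary = {
        "n_transcripts": len(transcripts),
        "n_orfs_scanned": n_orfs,
        "n_candidates": sum(1 for c in candidates if c.n_primary_sites >= config.min_sites),
        "n_passed": len(tallies),
        "config": config.to_dict(),
    }
    result = RunResult(
        config,
        candidates,
        tallies,
        summary,
        _candidate_table(candidates),
        _peptide_table(tallies),
    )
    if config.out_dir is not None:
        _write_bundle(result)
    return result


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# prepromine config: {json.dumps(config.to_dict())}\n")
        fh.write(f"# {COORD_NOTE}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_bundle(result: RunResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.candidate_table, out / "candidates.tsv", result.config)
    _write_tsv(result.peptide_table, out / "peptides.tsv", result.config)
    with open(out / "precursors.txt", "w") as fh:
        fh.write(f"# prepromine config: {json.dumps(result.config.to_dict())}\n")
        fh.write(f"# {COORD_NOTE}\n")
        for cand in result.candidates:
            if cand.passed:
                fh.write(render_precursor(cand, result.tallies[cand.orf.orf_id]))
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1) + "\n")


def score_against_manifest(result: RunResult, manifest: dict) -> dict:
    """Precision/recall of precursor detection plus exact peptide matching.

    Detection is scored at the transcript level (a transcript counts as
    detected when it carries a passed candidate).  For each ground-truth
    precursor, the passed candidate with the most primary sites on its
    transcript is compared peptide-by-peptide: display strings and copy
    counts must match the manifest exactly.
    """
    truth_ids = {p["transcript_id"] for p in manifest["precursors"]}
    detected = {c.orf.transcript_id for c in result.candidates if c.passed}
    tp = len(truth_ids & detected)
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(truth_ids) if truth_ids else 0.0
    mismatches: list[dict] = []
    n_exact = 0
    for prec in manifest["precursors"]:
        tid = prec["transcript_id"]
        cands = [
            c for c in result.candidates
            if c.passed and c.orf.transcript_id == tid
        ]
        if not cands:
            mismatches.append({"precursor": prec["name"], "error": "not detected"})
            continue
        best = max(cands, key=lambda c: c.n_primary_sites)
        observed = result.tallies[best.orf.orf_id].counts
        if observed == prec["counts"]:
            n_exact += 1
        else:
            mismatches.append(
                {
                    "precursor": prec["name"],
                    "expected": prec["counts"],
                    "observed": observed,
                }
            )
    return {
        "precision": precision,
        "recall": recall,
        "n_truth": len(truth_ids),
        "n_detected": len(detected),
        "n_exact_peptide_sets": n_exact,
        "mismatches": mismatches,
    }
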