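"""Motif scanning, the >=3-site rule, segmentation and similarity filtering."""

import itertools

import numpy as np
import pytest

from prepromine.discovery import (
    MOTIF_PRIORITY,
    P1PRIME_EXCLUDED,
    apply_site_threshold,
    count_primary_sites,
    curate_candidates,
    discover,
    pairwise_identity,
    scan_motifs,
    segment_candidates,
    similarity_filter,
)
from prepromine.seqcore import Orf


def _orf(aa: str, tid: str = "t") -> Orf:
    return Orf(tid, "+", 1, aa, 0, 3 * len(aa), aa.startswith("M"), False)


def oracle_scan(aa: str, include_lone_arg: bool = False):
    """Independent position-by-position matcher mirroring the scan contract:
    longest-match priority, non-overlapping consumption, P1' context check
    on monobasic sites."""
    motifs = list(MOTIF_PRIORITY) + (["R"] if include_lone_arg else [])
    out = []
    i = 0
    while i < len(aa):
        hit = None
        for m in motifs:
            if aa[i : i + len(m)] == m:
                hit = m
                break
        if hit is None:
            i += 1
            continue
        if hit in ("GR", "GRR"):
            nxt = aa[i + len(hit)] if i + len(hit) < len(aa) else None
            ok = nxt is None or nxt not in P1PRIME_EXCLUDED
        else:
            ok = True
        out.append((i, hit, ok))
        i += len(hit)
    return out


def _random_aa(rng, n):
    # motif residues enriched so sites are actually exercised
    alphabet = "GKRGKRAEDSTQWLFPNYVCX"
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


class TestScanMotifs:
    def test_single_exact_motif(self):
        sites = scan_motifs("AAGKRAA")
        assert len(sites) == 1
        s = sites[0]
        assert (s.orf_pos, s.motif, s.amidating, s.scan_class) == (2, "GKR", True, "primary")

    def test_rfamide_repeat_yields_one_primary_site_per_unit(self):
        # the internal ..GRF.. dipeptide of the core must not be cleaved:
        # a monobasic site followed by an aromatic residue is rejected
        aa = "EQWLRGRFGKR" * 5
        sites = scan_motifs(aa)
        assert count_primary_sites(sites) == 5
        rejected = [s for s in sites if not s.context_ok]
        assert all(s.motif == "GR" for s in rejected) and len(rejected) == 5

    @pytest.mark.parametrize("aa, expected", [
        ("AGRRA", [("GRR", True)]),            # GRR outranks GR
        ("AGKKA", [("GKK", True)]),
        ("AKRKK", [("KR", True), ("KK", True)]),
        ("AGKRR", [("GKR", True)]),            # consumption: trailing R alone
        ("AGRF", [("GR", False)]),             # hydrophobic P1' -> rejected
    ])
    def test_priority_and_context(self, aa, expected):
        got = [(s.motif, s.context_ok) for s in scan_motifs(aa)]
        assert got == expected

    def test_lone_arg_only_in_polyarg_mode(self):
        assert scan_motifs("ARA") == []
        sites = scan_motifs("ARA", include_lone_arg=True)
        assert [(s.motif, s.scan_class, s.amidating) for s in sites] == [
            ("R", "secondary", False)
        ]

    def test_matches_bruteforce_oracle_over_1e5_positions(self):
        rng = np.random.default_rng(23)
        total = 0
        for _ in range(120):
            aa = _random_aa(rng, 1000)
            total += len(aa)
            got = [(s.orf_pos, s.motif, s.context_ok) for s in scan_motifs(aa)]
            assert got == oracle_scan(aa)
        assert total >= 100_000


class TestSiteThreshold:
    def test_boundary(self):
        two = scan_motifs("AGKRAAGKRA")
        three = scan_motifs("AGKRAAGKRAAGKRA")
        assert count_primary_sites(two) == 2
        assert not apply_site_threshold(two)
        assert apply_site_threshold(three)

    def test_equivalence_with_naive_recount(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            aa = _random_aa(rng, 300)
            sites = scan_motifs(aa)
            naive = sum(
                1 for s in sites
                if s.motif in ("GKR", "GKK", "GRR", "GR") and s.context_ok
            )
            assert apply_site_threshold(sites) == (naive >= 3)


class TestSegmentation:
    def test_segment_definition(self):
        orf = _orf("XXEQWLRGRFGKRYY")
        segs = segment_candidates(orf, scan_motifs(orf.aa_seq))
        assert [s.raw_seq for s in segs] == ["EQWLRGRF"]
        assert segs[0].right_motif == "GKR"
        assert segs[0].end == 10  # motif start

    def test_concatemer_yields_identical_segments(self):
        orf = _orf("EQWLRGRFGKR" * 19)
        segs = segment_candidates(orf, scan_motifs(orf.aa_seq))
        assert len(segs) == 19
        assert set(s.raw_seq for s in segs) == {"EQWLRGRF"}

    def test_secondary_site_delimits_but_does_not_emit(self):
        # the KR junction cuts off the leader; only amidating sites yield segments
        orf = _orf("MLLLLKRTPPAGKRTPPAGKR")
        segs = segment_candidates(orf, scan_motifs(orf.aa_seq))
        assert [s.raw_seq for s in segs] == ["TPPA", "TPPA"]

    def test_long_segment_truncated_and_flagged(self):
        orf = _orf("A" * 40 + "TPPA" + "GKR")
        segs = segment_candidates(orf, scan_motifs(orf.aa_seq), max_peptide_len=10)
        assert len(segs[0].raw_seq) == 10
        assert "long_nterm" in segs[0].flags

    def test_segments_never_overlap_motif_residues(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            aa = _random_aa(rng, 400)
            orf = _orf(aa)
            sites = scan_motifs(aa)
            spans = [(s.orf_pos, s.end) for s in sites if s.context_ok]
            for seg in segment_candidates(orf, sites):
                assert seg.raw_seq == aa[seg.start : seg.end]
                for lo, hi in spans:
                    assert seg.end <= lo or seg.start >= hi


def nw_identity_oracle(a: str, b: str) -> float:
    """Independent Needleman-Wunsch (match 2, mismatch -1, gap open -2,
    extend -0.5) with traceback, counting identities over the shorter
    sequence.  Affine gaps via the standard three-state DP."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -2 - 0.5 * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -2 - 0.5 * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 2 if a[i - 1] == b[j - 1] else -1
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - 2, X[i - 1][j] - 0.5, Y[i - 1][j] - 2)
            Y[i][j] = max(M[i][j - 1] - 2, Y[i][j - 1] - 0.5, X[i][j - 1] - 2)
    # traceback for identities along one optimal path
    state = max(("M", "X", "Y"), key=lambda k: {"M": M, "X": X, "Y": Y}[k][n][m])
    i, j, ident = n, m, 0
    while i > 0 or j > 0:
        if state == "M":
            s = 2 if a[i - 1] == b[j - 1] else -1
            ident += a[i - 1] == b[j - 1]
            prev = max(("M", "X", "Y"),
                       key=lambda k: {"M": M, "X": X, "Y": Y}[k][i - 1][j - 1])
            i, j, state = i - 1, j - 1, prev
            if i == 0 and j == 0:
                break
        elif state == "X":
            tgt = X[i][j]
            if abs(M[i - 1][j] - 2 - tgt) < 1e-9:
                state = "M"
            elif abs(X[i - 1][j] - 0.5 - tgt) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            tgt = Y[i][j]
            if abs(M[i][j - 1] - 2 - tgt) < 1e-9:
                state = "M"
            elif abs(Y[i][j - 1] - 0.5 - tgt) < 1e-9:
                state = "Y"
            else:
                state = "X"
            j -= 1
    return ident / min(n, m)


class TestSimilarity:
    def test_identical_repeats(self):
        orf = _orf("EQWLRGRFGKR" * 19)
        segs = segment_candidates(orf, scan_motifs(orf.aa_seq))
        res = similarity_filter(segs)
        assert res.passed and res.mean_identity == 1.0
        assert len(res.cluster) == 19

    def test_lwamide_family_clusters(self, pipeline_result):
        """Eight related LWamide-family peptides with diverse N-termini must
        still pass: their shared C-terminal ..GLWamide signature is the
        loosest real repeat family the screen has to keep."""
        cands = [c for c in pipeline_result.candidates
                 if c.passed and c.orf.transcript_id == "fx_tcy_lwamide"]
        assert len(cands) == 1
        assert len(cands[0].cluster) >= 3

    def test_single_segment_fails_with_zero_identity(self):
        orf = _orf("EQWLRGRFGKR")
        segs = segment_candidates(orf, scan_motifs(orf.aa_seq))
        res = similarity_filter(segs)
        assert (res.mean_identity, res.passed) == (0.0, False)

    def test_identity_agrees_with_needleman_wunsch_oracle(self):
        rng = np.random.default_rng(37)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        pairs = [("EQWLRGRF", "EQFLRGRF"), ("RPRA", "RQVLTRPRG")]
        for _ in range(60):
            a = "".join(alphabet[i] for i in rng.integers(20, size=rng.integers(2, 13)))
            b = "".join(alphabet[i] for i in rng.integers(20, size=rng.integers(2, 13)))
            pairs.append((a, b))
        for a, b in pairs:
            assert pairwise_identity(a, b) == pytest.approx(
                nw_identity_oracle(a, b), abs=1e-9
            )

    def test_screened_shuffle_decoys_never_pass(self):
        """Composition-preserving shuffles can recreate motif clusters by
        chance (the precursors are G/K/R-rich), so the generator screens and
        re-shuffles; the resulting decoy set must yield zero passed ORFs."""
        from prepromine.fixtures import (
            TABLE1_SPECS,
            _build_decoy,
            _passed_candidates,
            build_precursor,
        )

        rng = np.random.default_rng(41)
        proteins = [build_precursor(s)[0] for s in TABLE1_SPECS]
        for k in range(30):
            decoy = _build_decoy(proteins, k, rng)
            assert _passed_candidates(decoy) == []


class TestCuration:
    def test_low_complexity_rejected(self):
        orf = _orf("KKKKKKKGKR" * 4 + "SDD")
        cand = discover(orf)
        assert cand.passed  # identical single-residue repeats do cluster
        curated = curate_candidates([cand])[0]
        assert not curated.passed
        assert "low_complexity" in curated.curation_flags

    def test_fixture_precursors_retained(self, pipeline_result, fixture_bundle):
        truth_ids = {p["transcript_id"] for p in fixture_bundle["manifest"]["precursors"]}
        kept = {c.orf.transcript_id for c in pipeline_result.candidates if c.passed}
        assert truth_ids <= kept

    def test_failed_candidates_always_carry_a_reason(self, pipeline_result):
        for c in pipeline_result.candidates:
            if not c.passed:
                assert c.curation_flags


class TestMonotonicity:
    def test_relaxing_thresholds_never_loses_candidates(self, fixture_bundle):
        from prepromine import seqcore

        orfs = []
        for rec in fixture_bundle["records"][:30]:
            orfs.extend(seqcore.extract_orfs(rec, min_aa_len=50))
        for strict, loose in [
            (dict(min_sites=4), dict(min_sites=3)),
            (dict(min_identity=0.8), dict(min_identity=0.5)),
            (dict(min_cluster=5), dict(min_cluster=3)),
        ]:
            passed_strict = {o.orf_id for o in orfs if discover(o, **strict).passed}
            passed_loose = {o.orf_id for o in orfs if discover(o, **loose).passed}
            assert passed_strict <= passed_loose
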