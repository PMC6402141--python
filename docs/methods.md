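# Methods

## The screening model

Cnidarian neuropeptide genes encode preprohormones: a signal peptide
followed by many immature peptide copies, each flanked by processing
signals. At the C-terminal side of each copy sits a glycine followed by
basic residues — GKR, GKK or GR(R) — where prohormone convertases (PC 1/3,
PC 2) cleave at the basic residues and peptidylglycine α-amidating
monooxygenase converts the exposed glycine into a C-terminal amide. This
anatomy gives a screen that needs no homology information: translate every
transcript in all six reading frames, split each frame at stop codons into
ORFs, and keep ORFs that carry **at least three** amidation-competent
processing sites whose liberated segments form a mutually similar repeat
cluster.

`prepromine` implements that screen as a deterministic pipeline:

1. **seqcore** — FASTA input (Biopython), six-frame translation under the
   standard genetic code (codons containing N → `X`), stop-to-stop ORF
   extraction with 0-based half-open forward-strand coordinates. ORFs are
   stop-to-stop rather than ATG-anchored because assembled transcripts are
   frequently 5′-truncated; an M-anchored mode exists (`require_start`).
2. **discovery** — motif scan, site threshold, segmentation, similarity
   clustering, deterministic curation.
3. **maturation** — N/C-terminal processing rules, copy tallies, peptide
   families and positional subfamilies, plus two auxiliary classifiers
   (signal-peptide heuristic, glycoprotein-hormone cysteine skeleton).

## Motif scanning

Scanning is left-to-right with longest-match priority
(GKR ≻ GKK ≻ GRR ≻ GR ≻ KR ≻ KK) and non-overlapping consumption: one
junction is one cleavage event. GKR/GKK/GRR/GR are *primary* (amidating,
counted toward the threshold); KR/KK are *secondary* (segment delimiters
only — they cut off the signal/propeptide region but never yield amidated
products). Lone arginines are reported only in the explicit poly-Arg mode
(`include_lone_arg`), which models precursors whose copies are separated by
RRR runs where the exact cleavage register is unknowable.

Monobasic sites (GR, GRR) are accepted only when the residue following the
motif is not strongly hydrophobic ({F,Y,W,L,I,M,V}). Single-arginine
convertase cleavage is strongly context-dependent, and the GR dipeptide
occurs *inside* many mature cnidarian peptides (…GRFamide, …GRYamide
cores) where it is demonstrably not processed; without this rule every
RFamide repeat would be cut in half. Rejected matches are still reported
(`context_ok=False`) for audit.

## Segmentation and similarity

For each accepted amidating site, the candidate peptide segment runs from
the end of the previous accepted site (or the ORF start) to the first motif
residue. Unknown residues (X) at segment edges are trimmed; segments longer
than `max_peptide_len` (default 30 aa — the longest known mature peptide in
this clade is 12 aa, the margin admits novel families) are truncated to
their C-terminal window and flagged `long_nterm`.

Similarity is judged on the C-terminal 12 residues of each segment — the
family-defining end of a cnidarian neuropeptide. Pairs are globally aligned
(match 2, mismatch −1, gap open −2, extend −0.5) and identity is counted as
matches over the **shorter** sequence: these repeats differ mostly by
N-terminal extensions, and an alignment-length denominator would punish a
4-residue copy aligned against a 9-residue sibling for length alone. The
candidate passes when some cluster of ≥ `min_cluster` (default 3) segments
has every pair ≥ `min_identity` (default 0.5); the cluster is the maximum
clique of the pairwise-similarity graph (exact, via clique enumeration —
candidate ORFs have at most a few dozen segments). The defaults are set so
the loosest real repeat family (the eight-peptide LWamide precursor, pairs
down to ≈0.5 identity) passes while composition-preserving shuffles do not.

Curation replaces the human rejection step with two deterministic rules,
each recorded in `curation_flags`: clusters dominated (≥ half) by
low-complexity segments (one residue ≥ 80% of the segment), and clusters
containing peptides over the length ceiling. Human judgment beyond these
rules is out of scope.

**Tallies cover all amidated segments of a passed precursor**, not only the
cluster members: real precursors carry occasional odd peptides (e.g. a
single pQVLTRPRGamide among thirteen RPRAamide copies) that belong in the
repertoire even though they do not cluster.

## Maturation rules

* **C-terminus** — a segment ending at an amidating motif is amidated; a
  segment ending at a plain dibasic site is liberated un-amidated, flagged
  `no_amide_donor`, and excluded from tallies (the secreted products of
  these precursors are the amidated peptides).
* **Pyroglutamate** — the most N-terminal glutamine that either sits at a
  cleavage boundary or follows a residue in {D,E,K,R,S,T,A} becomes the
  mature N-terminus and cyclizes to pQ (confidence `certain`). N, L and V
  are *not* eligible by default: published repertoires leave V-preceded
  glutamines uncyclized, and cleavage after L requires a hypothetical
  aminopeptidase — enabling `aminopeptidase_l_rule` adds L explicitly
  (…ELQPGMW-GKR → pQPGMWamide).
* **Proline imide** — with no eligible Q, a proline at position 2 protects
  the N-terminus (imide bond; `certain`); otherwise the full segment is
  reported with confidence `uncertain`.
* **Cyclic peptides** — cores with cysteines at positions 1 and 6 are
  flagged cyclic (intrachain Cys1–Cys6 cystine bridge).
* **Families and subfamilies** — family = last two core residues + "amide"
  (RFamide, LWamide, …). Positional subfamilies (orthologous precursors
  carry their peptide variants in a conserved N→C order) are assigned from
  an editable JSON table of (ordinal position, C-terminal regex) signatures
  shipped with the package, seeded with the LWamide (positions 1–6) and
  RYamide (positions 1–4) reference sets.

The signal-peptide heuristic (initiator M plus a ≥8/12 hydrophobic window
in the first 40 residues) is a triage rule for complete vs. fragmentary
precursors, not a cleavage-site predictor. The GPH check asks whether ≥11
cysteines fall inside a 160-residue window — ten bridge-forming plus one
intersubunit cysteine of a glycoprotein-hormone cystine knot.

## Synthetic transcriptome

The generator emits seven precursor transcripts reproducing the known
*Tripedalia cystophora* repertoire — an RFamide (19× pQWLRGRFamide + 1×
pQFLRGRFamide), a short poly-Arg RFamide (6× RFamide), a VWamide (6×
pQPPGVWamide), an LWamide (8 distinct peptides), an RAamide (13 + 3 + 1), an
RYamide (4 distinct) and a cyclic FRamide (4 + 2 + 1) — with the flank
conventions of the real genes (acidic flanks before RFamide copies; S/T/A
before VWamide copies; contiguous repeats where the published N-termini are
uncertain). Each protein is leader + KR junction + units + acidic tail,
reverse-translated with uniformly random synonymous codons, framed by an
in-frame upstream stop and random UTRs, and embedded on a random strand.
Decoys are composition-preserving residue shuffles of the precursors.

Two generation-time screens keep the ground-truth manifest sufficient for
scoring at any seed: precursor transcripts are re-screened (exactly one
passed candidate reproducing the encoded units; codons re-rolled otherwise,
bounded at 20 attempts), and decoys that accidentally recreate a
precursor-like motif cluster — raw shuffles of these G/K/R-rich proteins do
so ~20% of the time — are re-shuffled (bounded at 100 attempts). All
randomness flows from one integer seed; a fixed seed gives byte-identical
FASTA and manifest.

What the fixtures do *not* emulate: sequencing error, fragmentary
assemblies, alternative isoforms, UTR composition bias, and realistic
inter-unit linker sequences beyond the documented flank conventions.
Passing the round-trip therefore demonstrates correctness of the screen and
the processing rules on well-formed precursors, not robustness to assembly
artifacts.

## Numerical and degenerate-input choices

Ties in clique selection break toward the lexicographically smallest
segment-index set; identical display strings merge in first-appearance
order; a single segment scores identity 0 and fails; empty FASTA, duplicate
ids and non-nucleotide characters are hard errors naming the record; an
all-N transcript yields all-X ORFs in which no motif can match (X never
matches a motif residue). Scores are exact rationals in floating point
(multiples of 0.5), so threshold comparisons are stable.

## Problem sizes

The bundled test suite and the acceptance script run the full pipeline on a
107-transcript synthetic transcriptome (seven precursors + 100 decoys,
~100 kb of nucleotide), scan ≥10⁵ random residues against a brute-force
motif oracle, and property-test 1000 random segments; the whole suite
completes in a few seconds on one CPU.

## Known limitations

The curation proxy cannot reproduce expert judgment; the similarity
thresholds are tuned to one clade's repeat families; the pQ and monobasic
context rules are heuristics over a small set of biochemically verified
cases; detection of precursors whose copies lack amidation entirely (plain
KR-flanked peptides) is out of scope by design.
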