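# prepromine

Mining transcriptome assemblies for neuropeptide preprohormones — and
predicting the mature peptides they release.

Cnidarian nervous systems run largely on neuropeptides, and the genes
encoding them have a tell-tale anatomy: a signal peptide followed by many
near-identical immature peptide copies, each ending in an
amidation/cleavage signal (**GKR**, **GKK** or **GR(R)** — the basic
residues are cut by prohormone convertases, the glycine becomes a
C-terminal amide). Because the peptides themselves are short and fast
evolving, BLAST-style homology searches miss them; the repeat-plus-motif
anatomy does not. `prepromine` is for anyone annotating neuropeptide
repertoires in transcriptomes of cnidarians or other early-branching
animals: it finds candidate precursor ORFs, applies the prohormone
processing rules, and reports each precursor's mature peptides with
modifications and copy numbers.

## The screen

For every transcript, all six reading frames are split at stop codons into
ORFs. An ORF becomes a candidate precursor when

* it carries **≥ 3 primary processing sites** (GKR/GKK/GR(R); dibasic
  KR/KK count only as segment boundaries, and monobasic GR sites followed
  by a hydrophobic residue are rejected — that context occurs inside
  mature …GRFamide/…GRYamide cores, not at real junctions), and
* the liberated peptide segments contain a cluster of **≥ 3 mutually
  similar** copies (global-alignment identity ≥ 0.5 over the C-terminal
  12 residues, every pair in the cluster).

Passed candidates are matured: segments ending at G+basic motifs get a
C-terminal amide; a glutamine at a cleavage boundary or after a
D/E/K/R/S/T/A residue cyclizes to N-terminal pyroglutamate (**pQ**);
position-2 prolines protect otherwise-free N-termini; Cys1/Cys6 pairs mark
cyclic peptides. Identical products are tallied into copy numbers and
labelled by family (RFamide, LWamide, …) and by positional subfamily
(orthologous precursors keep their peptide variants in a conserved N→C
order). See `docs/methods.md` for every rule and default.

## Worked example

The package ships a generator that writes a synthetic transcriptome
containing seven realistic precursors (the known *Tripedalia cystophora*
repertoire re-encoded with random synonymous codons, random strands and
UTRs) plus 100 shuffled decoy transcripts, together with a ground-truth
manifest:

```
$ prepromine fixtures --out-dir fx --seed 17 --n-decoys 100
$ prepromine mine fx/transcriptome.fasta --out-dir run --aminopeptidase-l-rule
{
 "n_transcripts": 107,
 "n_orfs_scanned": 581,
 "n_candidates": 60,
 "n_passed": 7,
 ...
}
```

107 transcripts yield 581 ORFs; 60 clear the ≥3-site threshold but only
the seven real precursors survive the similarity filter and curation. The
run directory contains `candidates.tsv` (one row per scanned ORF),
`peptides.tsv` (one row per predicted peptide), `summary.json`, and
`precursors.txt`, an annotated rendering of each passed precursor with
segments in `{...}` and processing motifs in `[...]`:

```
# precursor fx_tcy_rfamide|-2|37-775
# signal_peptide=complete (hydrophobic fraction 1.00)
# n_primary_sites=20 mean_identity=0.932
MLALLFVALIVALMASES[KR]{EQWLRGRF}[GKR]{DQWLRGRF}[GKR]{EQWLRGRF}[GKR]...
# mature peptides: pQWLRGRFamide x19, pQFLRGRFamide x1
```

Reading: after the signal-like leader and a dibasic KR junction, the ORF
carries 20 repeats, each an acidic flank (E/D) + core + GKR junction. The
acidic context licenses pyroglutamate formation, so the precursor releases
19 copies of pQWLRGRFamide and one of pQFLRGRFamide — amidated,
pQ-protected peptides, exactly the repertoire the transcript encodes.
`prepromine score` checks a whole run against the generator's manifest:

```
$ prepromine score fx/transcriptome.fasta fx/manifest.json
{
 "precision": 1.0,
 "recall": 1.0,
 "n_exact_peptide_sets": 7,
 "mismatches": []
}
```

All seven precursors are detected with no false positives among the 100
decoys, and all seven predicted peptide sets match the ground truth
exactly.

The `--aminopeptidase-l-rule` flag opts into pQ formation after a leucine
context (a hypothesized aminopeptidase); it is off by default so the
conservative prediction is never silently overridden.

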