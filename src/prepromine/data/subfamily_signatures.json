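{
  "comment": "Positional peptide subfamily signatures. Each entry matches a peptide by its ordinal position on the precursor (N- to C-terminus) and a regex applied to the display string with the trailing 'amide' removed. Edit or extend freely; load with maturation.load_subfamily_signatures(path).",
  "signatures": [
    {"group": "LWamide", "subfamily": "peptide-1", "positions": [1], "pattern": "ILW$"},
    {"group": "LWamide", "subfamily": "peptide-2", "positions": [2], "pattern": "^(pQ|.{0,2}Q)PGMW$"},
    {"group": "LWamide", "subfamily": "peptide-3", "positions": [3], "pattern": "P[RKQ]L[DN][LM]LW$"},
    {"group": "LWamide", "subfamily": "peptide-4/5", "positions": [4, 5], "pattern": "P[RKQ][LMVA]GLW$"},
    {"group": "LWamide", "subfamily": "peptide-6", "positions": [6], "pattern": "PGKVGLW$"},
    {"group": "RYamide", "subfamily": "peptide-1", "positions": [1], "pattern": "PPW[VI]KGRY$"},
    {"group": "RYamide", "subfamily": "peptide-2", "positions": [2], "pattern": "^pQ.W.[KR][QG]?RYA?$"},
    {"group": "RYamide", "subfamily": "peptide-3", "positions": [3], "pattern": "^APGWHHGRY$"},
    {"group": "RYamide", "subfamily": "peptide-4", "positions": [4], "pattern": ".P.W[AF]KGRYA?$"}
  ]
}
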