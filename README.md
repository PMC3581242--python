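# hbrscout

Discover member-unique peptide segments in a protein family and nominate
cationic windows within them as putative heparin-binding regions (HBRs).

Given a FASTA family, the pipeline:

1. **uniqseg** — indexes every fixed-length *primary pattern* (default 3
   residues) to the set of members carrying it, flags pattern starts carried
   by at most *m* members (default 1 = member-unique), and merges maximal
   runs of flagged starts bottom-up into unique segments.
2. **hbrscreen** — scans each unique segment (extended by a small flank) with
   a fixed-width window (default 5) and reports windows containing at least
   3 basic residues (Arg/Lys by default) that overlap the segment; per
   segment, one representative window (max basic count, leftmost tie-break)
   or, verbosely, every qualifying window.
3. **identity** — positional (Hamming) identity between pre-aligned motif
   strings (gap = mismatch, full-length denominator), motif-subwindow
   identity, and whole-protein percent identity from a Needleman–Wunsch
   global alignment (Gotoh affine gaps, BLOSUM62, gap open 10 / extend 0.2).
4. **synth** — seeded synthetic families: one scaffold, per-member
   substitution noise, planted member-unique segments (rejection-sampled so
   every internal k-mer is absent from all other members) and planted
   cationic windows, plus span-level precision/recall scoring.

Packaged reference data (`hbrscout/data/`) includes the mature human RNase3
(ECP) chain, its eleven published unique segments, the three HBR windows
(RWRCK 34–38, RSRFR 73–77, RPGRR 101–105), and two published 10-residue
motif comparison tables for the human RNaseA superfamily and primate
RNase2/RNase3 orthologs, addressable from the CLI as `builtin:table4` /
`builtin:table5`.

## CLI

```sh
hbr-scout unique-segments --fasta family.fa --length 3 --level 1 --out segments.tsv
hbr-scout screen-hbr --fasta family.fa --window 5 --min-basic 3 --flank 2 --out hbr.tsv
hbr-scout motif-identity --table builtin:table5 --reference RNase3
hbr-scout motif-identity --table builtin:table5 --reference RNase3 --subwindow-offset 3
hbr-scout protein-identity --fasta family.fa --reference P12724
hbr-scout synth --config cfg.yaml --seed 1 --out-fasta fam.fa --out-truth truth.tsv
hbr-scout full-run --fasta family.fa --out-dir reports/
```

Reports are TSV (1-based inclusive coordinates) with `#` provenance header
lines (tool version, parameters, input SHA-256); reruns are byte-identical
unless `--timestamp` is passed. Invalid input exits with status 2 and names
the offending record.

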