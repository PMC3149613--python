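# strainscan

Gene-by-gene comparison of two bacterial strains at the protein level:
given a reference genome with gene annotation (e.g. *E. coli* K-12 MG1655),
a target genome (e.g. the expression strain BL21(DE3)), and a list of
candidate genes, `strainscan` decides for every candidate whether its
product exists in the target **identical**, **substituted** (with every
amino-acid exchange enumerated in `R51L` notation), **truncated** by a
premature stop codon, or **missing** altogether.

This is the classic question behind phenotype differences between closely
related strains — e.g. why a B-lineage expression strain is defective in
anaerobic hydrogen metabolism while K-12 is not — answered purely from
sequence, with no functional-effect prediction.

## Method

For each reference protein `q` (length `n`, annotation-derived, genetic
code table 11), the target genome is translated exhaustively: every
start-to-stop stretch on both strands in all three frames (start codons
ATG/GTG/TTG, stop codons TAA/TAG/TGA, nested internal starts included) is
a *potential ORF*. Each ORF's translation `t` is aligned globally
(Needleman–Wunsch) under an identity scoring scheme calibrated so that

```
score(q, t) = n · match   ⟺   t = q        (match=+1, mismatch=−1, gap=−1)
```

The maximal similarity score over all ORFs is taken. A perfect score
proves the gene product exists unchanged; otherwise the best alignment is
examined: mismatch columns become amino-acid exchanges (silent DNA changes
are invisible by construction), a premature stop codon in the reference
reading frame marks a nonsense mutation (amber/ochre/opal, with the causal
base change when it is a single substitution, e.g. C→T turning CAG into
TAG), and a best score below half the perfect score calls the gene
missing. Scores are integers throughout, so the exact-match test is exact;
a k-mer prefilter and an exact branch-and-bound length bound accelerate
the all-vs-all scan without changing any result.

Because real strain pairs require downloads, the package ships a
synthetic-data generator that builds an annotated ancestor genome and a
mutant carrying planted missense, silent and nonsense substitutions,
single-codon indels, and whole-gene deletions — each recorded in a truth
table that the scan output is diffed against.

## Worked example

```
strainscan fixtures --outdir fx --which smoke
strainscan scan --reference fx/smoke_ancestor.fasta \
                --annotation fx/smoke_ancestor.gff3 \
                --target fx/smoke_mutant.fasta \
                --genes fx/smoke_genes.txt \
                --report smoke_report.tsv --summary smoke_summary.json
```

The log ends with:

```
scan complete: 12 queries -> 5 identical, 5 substituted (5 exchanges), 1 truncated, 1 missing; 0 unresolved
```

and `smoke_report.tsv` contains one row per candidate, e.g.:

```
gene   query_length  status       n_exchanges  exchanges  indels  best_score  identity  coverage  orf_coordinates  truncation_codon  stop_class
g0004  92            substituted  2            S13C;L66T  .       88          0.9783    1.0000    1302..1580(+)    .                 .
g0007  96            substituted  0            .          Q95del  94          0.9896    0.9896    2324..2611(-)    .                 .
g0008  90            truncated    0            .          .       -12         0.4333    0.4333    2646..2765(-)    40                ochre
g0011  93            missing      0            .          .       -42         0.3118    0.6989    470..688(+)      .                 .
```

Reading the rows: g0004 carries two amino-acid exchanges (Ser13→Cys,
Leu66→Thr; score 88 = 92 − 2·2); g0007 lost one residue in frame
(Gln95 deleted — an indel, deliberately not counted as an exchange);
g0008 hit an ochre stop at codon 40, so only its 39-residue N-terminal
fragment survives; g0011 was deleted outright, and its best remaining
alignment anywhere in the genome scores far below the missing threshold.
`smoke_summary.json` echoes the six summary counts and the full resolved
configuration, which alone suffices to rerun the scan identically.

The same `scan` command accepts real genome records (FASTA + GFF3 or
GenBank) for a full-scale strain comparison; exact counts there depend on
how the candidate list is reconstructed and on the mismatch/gap penalties,
which are a reasoned reconstruction (see `docs/methods.md`).

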