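# chimorf

Detection and scoring of cytoplasmic-male-sterility (CMS) candidate
chimeric ORFs in plant mitochondrial genomes.

CMS — the maternally inherited inability to make functional pollen — is the
backbone of hybrid seed production in many crops and is usually caused by
*chimeric open reading frames*: novel genes stitched together by
mitochondrial genome rearrangement from fragments of real genes.  Given a
finished (circular) mitochondrial reference from a male-sterile line,
its gene annotation, and sequencing data from a fertile comparator line,
`chimorf` finds the genomic territory that differs between the lines and
screens the ORFs there for the classic CMS hallmarks.  It is written for
plant mitochondrial genomicists and breeders comparing sterile/maintainer
line pairs.

The pipeline:

1. **No-coverage regions** — maximal runs of comparator depth ≤ 1 that are
   strictly longer than 1 kb (sequence absent or diverged in the
   comparator).
2. **Rearrangement breakpoints** — unique 21-mer anchors chained between
   comparator scaffolds and the reference; discontinuities (inversion,
   translocation, unanchored junctions) become breakpoints, optionally
   confirmed by read-level discordance with a strict >60% support rule.
3. **ORF discovery** — six-frame scan for maximal ATG→stop frames of
   > 100 codons (codon counts include the stop), restricted to ORFs
   overlapping a no-coverage region or within 5 kb of a breakpoint, with
   known annotated genes excluded.
4. **Chimera scoring** — affine-gap Smith–Waterman (+2/−3/−5/−2) of each
   candidate against the whole genome; non-self hits with identity ≥ 95%
   over ≥ 16 bp mark copied fragments.  Candidates score one point each
   for carrying parts of other genes/ORFs, proximity (≤ 1 kb) to a gene, a
   hydrophobic (Kyte–Doolittle window-19 > 1.6) domain, and a bonus for
   carrying part of an *atp* gene; **total ≥ 3 retains the ORF** as a CMS
   candidate.
5. **Gene-order clusters** — maximal runs of genes adjacent in two
   annotated genomes (shared-gene restriction, forward or reversed),
   for cross-species synteny comparison.

A fully specified synthetic-data module generates circular reference
genomes with annotated genes, planted chimeric ORFs among rubric-negative
decoys, Poisson ~23× coverage with planted zero regions, rearranged
derivative genomes and error-free reads — with machine-readable truth
tables, so every stage is testable end to end without any external data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a small fixture (60 kb genome, 12 genes, 3 planted chimeric ORFs
among 6 decoys) and run the pipeline on it:

```sh
chimorf fixtures make --seed 7 --outdir fx --length 60000 --n-genes 12 \
    --n-chimeras 3 --n-decoys 6
cat > config.yaml <<EOF
reference: fx/reference.fasta
annotation: fx/annotation.gff3
coverage: {maintainer: fx/coverage.bedgraph}
outdir: out
EOF
chimorf run --config config.yaml
```

which prints:

```
chimorf.pipeline: regions[maintainer]: 9 regions, 10260 bp
chimorf.pipeline: orfs: 22 scanned, 11 in vicinity, 9 after known-gene exclusion
chimorf.pipeline: candidates: 9 scored, 3 retained (score >= 3)
breakpoints=0 no_coverage_regions=9 orfs_candidate=9 orfs_scanned=22 retained=3
```

Nine regions of the reference have ~zero comparator coverage; the 22 ORFs
of > 100 codons reduce to 9 candidates in that territory; 3 reach score
≥ 3 — exactly the planted chimeras.  `out/candidate_report.tsv` holds one
row per retained ORF–hit pair:

```
orf_start  orf_stop  orf_length  nearest_gene  subject_start  subject_stop  chimera_length  identity  subject_features  tm_helices
1402       1710      308         atp1          5558           5608          51              100       atp9              1
6322       6645      323         atp9          829             870           42              100       atp1              1
11730      12047     317         cox3          21248          21295         48              100       nad5              1
```

Row 1 reads: the ORF spanning 1,402–1,710 (printed length = stop − start =
308; 103 codons inclusive) sits next to *atp1*, carries an exact 51 bp
copy of *atp9* sequence (identity 100%, subject 5,558–5,608), and encodes
one predicted transmembrane helix — parts-of-other + proximity +
hydrophobic + atp bonus = score 4, retained.  A reverse-strand hit would
print subject_start > subject_stop.

Library use mirrors the CLI: `chimorf.pipeline.analyze(genome, features,
tracks)` runs the same stages in memory, and each stage
(`find_no_coverage_regions`, `call_breakpoints`, `scan_orfs`,
`find_self_homology`, `score_candidate`, `shared_gene_clusters`, …) is
importable on its own.

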