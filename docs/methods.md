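# Methods

`chimorf` implements a comparative-genomics screen for cytoplasmic-male-
sterility (CMS) candidates in plant mitochondrial genomes.  The biological
premise: CMS is usually caused by *chimeric ORFs* — novel reading frames
assembled by mitochondrial genome rearrangement from fragments of real
genes — which tend to (i) carry parts of other mitochondrial genes, often
*atp* subunits, (ii) sit close to functional genes, and (iii) encode
hydrophobic, membrane-associated segments.  Given a finished reference
mitochondrial genome from a male-sterile line and sequencing data from a
fertile comparator (maintainer) line, the pipeline locates the genomic
territory that differs between the lines and scores the ORFs found there
against these hallmarks.

## Stages and models

### No-coverage regions

The comparator's per-base depth on the reference is segmented into maximal
runs of depth ≤ `max_region_depth` (default 1 — "approximately zero", so a
stray mismapped read does not split a region).  Runs longer than 1 kb
(strictly: `min_region_length` = 1001 bp) are reported; a run touching both
ends of a circular reference merges across the origin.  A single covered
base splits a run — no gap tolerance by default.  These regions mark
sequence present in the sterile line but absent (or highly diverged) in
the comparator: prime CMS territory.

### Rearrangement breakpoints

Commercial read mappers used for this kind of comparison are closed source;
the module reinterprets the comparison as **unique k-mer anchor chaining**.
The reference is indexed by k-mers (k = 21, odd so no reverse-complement
palindromes) occurring exactly once counting both strands — uniqueness
across both strands is deliberately stricter than forward-strand uniqueness
so that the large recombinationally active repeats typical of plant
mitochondrial genomes cannot seed phantom junctions.  Comparator scaffolds
are anchored through the index and greedily chained under colinearity
(same orientation, monotone reference progress, gaps ≤ `max_gap` = 500 bp
on both sequences; chains under 3 anchors discarded).  For each discordant
adjacent chain pair (orientation flip → inversion junction; reference jump
→ translocation junction; long unanchored query stretch → unanchored
junction) both junction-flanking anchored reference coordinates are
recorded; calls within k bp are merged keeping the lowest coordinate, which
yields one call per true junction to within k−1 bp on planted events.

When comparator reads are supplied, each breakpoint must be confirmed by
read-level discordance: a read whose single chain covers the junction with
≥ k bp margin on both sides votes *concordant*; a read whose chain walks up
to the junction from the low-coordinate side and stops there while the read
continues ≥ k bp past it votes *discordant* (split alignment).  Only the
low-side approach is counted so that each junction collects votes from
exactly one comparator locus and a 50/50 read mixture measures ≈ 0.5
(empirically the split test is marginally more sensitive than the span test
at window edges, biasing mixtures a few points above 0.5).  Breakpoints are
retained iff discordant/(concordant+discordant) **exceeds** 0.6 — the
support threshold is strict, so an even mixture is rejected.  Breakpoints
with no informative reads are dropped with a warning.

### ORF discovery

Six-frame scan for maximal ATG-initiated, stop-terminated frames, standard
genetic code (plant mitochondria use the standard table; the start-codon
requirement is a choice — the sources leave it unstated).  Codon counts
include the terminal stop, so ">100 codons" becomes `min_codons` = 101
(303 nt inclusive).  Per stop codon and frame only the longest ORF (first
ATG after the previous stop) is reported; circular genomes are scanned
across the origin by doubling the sequence and deduplicating by circular
stop position.  Candidate ORFs must overlap a no-coverage region by ≥ 1 bp
or lie within `flank` = 5 kb (circular distance) of a retained breakpoint —
"vicinity" is unquantified in the sources, 5 kb is this package's default.
ORFs that overlap an annotated gene over ≥ 50% of their length are removed
as re-discoveries of known genes (the exclusion rule is likewise
unquantified; 0.5 is the default).

### Self-homology (chimeric structure)

Each candidate is aligned against both strands of the full genome with
affine-gap Smith–Waterman (match +2, mismatch −3, gap open −5, gap extend
−2 — common nucleotide-search defaults; a length-g gap costs
open + (g−1)·extend; N never matches).  Alignment is seeded from exact
shared 11-mers (the classic nucleotide-search word size), so hits lacking
an exact 11 bp run are not found — the same property as word-seeded search
tools; at the 95%-identity retention bar this costs nothing in practice.
Within each seeded window the best alignment is taken, its subject interval
masked, and the search repeated, enumerating co-homologous copies.  Hits
overlapping the ORF's own genomic interval are removed — the "first hit"
is the ORF's original location.  Retained hits need integer identity
(rounded half-up) ≥ 95 over a subject span ≥ 16 bp; "sequence coverage of
≥ 16 bp" is read as subject match length, consistent with a 20 bp hit
passing in the source material.  Reverse-strand hits are reported with
subject_start > subject_stop.

One numerical subtlety: the *score-optimal* local alignment can extend a
clean copied fragment through noisy flanks (a small gap plus chance
matches) and drag overall identity below 95%.  When that happens the
qualifying core is recovered by scanning the alignment's column path for
the maximal-score contiguous window that satisfies the identity and length
thresholds (ties: shortest, then lowest subject start).  Without this, a
perfect 50 bp gene fragment can be silently lost to a 94%-identity
extension.  Hit boundaries may therefore drift a base or two beyond a
copied fragment where the flanks genuinely align at ≥ 95%.

Smith–Waterman end-cell ties break to the lowest subject position, then
lowest query position, with a diagonal-preferring traceback — deterministic
across runs and platforms.

### Transmembrane stand-in

Licensed HMM topology predictors cannot be redistributed or re-derived, so
hydrophobic domains are called with the standard Kyte–Doolittle heuristic:
19-residue windows whose mean hydropathy exceeds 1.6 are marked and
overlapping/adjacent windows merge into segments.  Helix counts on real
proteins will differ from HMM-based predictors; within this package the
component only feeds the binary "has a hydrophobic domain" score, for which
the heuristic is adequate.

### Candidate score

One point each for: ≥ 1 retained self-homology hit (hits landing in
unannotated but ORF-bearing loci count — the hallmark is "parts of other
genes *or ORFs*"); an annotated gene within 1 kb (circular interval
distance); ≥ 1 hydrophobic segment; and a bonus point if any hit lands in
a gene whose name starts with "atp".  Total ≥ 3 retains the ORF as a CMS
candidate.  The report prints, per retained ORF–hit pair: ORF start/stop,
ORF length as **stop − start** (the printed-table convention; the inclusive
span, one larger, is always divisible by 3), nearest gene, subject
start/stop, chimera length as |Δ|+1, integer identity, subject feature and
helix count.

### Gene-order clusters

Two annotated genomes are compared by restricting both circular gene orders
to their shared gene names (duplicated genes get `_2`, `_3` suffixes) and
reporting maximal runs of ≥ 2 genes consecutive in both restricted orders,
forward or reversed.  Strand agreement is recorded as orientation but not
required.  Identical restricted orders yield a single full-circle cluster
anchored at the first shared gene.

## Synthetic data

The generator emulates the study design at reduced scale — a sequenced
sterile-line reference vs a maintainer-line comparator:

- **Reference**: 100 kb circular genome (the real genome is ~5× larger),
  background composition mildly AT-rich (A .30, C .21, G .21, T .28;
  GC 0.42, within the plant-mitochondrial band), 20 genes with real
  mitochondrial names (atp1, atp9, cox3, nad4, …), each a valid ORF of
  101–160 codons (scaled down so the genome stays ≥ 10× total gene span).
- **Chimeric ORFs** (default 5): ATG-initiated, ≥ 101 codons, an exact
  30–60 bp in-frame fragment copied from a donor gene — the default donor
  rotation (atp9, atp1, nad5, rps4, nad4) mirrors the gene families known
  to donate fragments to CMS ORFs — plus a 25–30-residue Leu/Ile/Val/Phe
  stretch, placed 150–600 bp from an annotated gene.  Expected score 4 for
  atp donors, else 3.  An in-frame TAA is written immediately upstream of
  each planted ATG so the scanner recovers the planted coordinates exactly,
  and the copied fragment is fenced by 12 positionwise-mismatching bases on
  each side so the self-homology hit ends at the fragment boundary (up to
  rare flank micro-homology).
- **Decoys** (default 20): hydrophilic-only ORFs ≥ 1.5 kb from any gene.
  Their codon text interleaves a 9-codon guard block that plants a stop
  codon in every non-native reading frame, so no "shadow" ORF in another
  frame or strand can live inside a decoy cassette (shadow ORFs over
  chimera cassettes are instead eliminated by deterministic re-planting).
  A decoy can still pick up one chance ≥ 16 bp repeat somewhere in a
  random 100 kb genome (expected ≈ 0.3 per fixture), contributing at most
  the parts-of-other point — never retention.
- **Coverage**: independent per-base Poisson(23) — matching the study's
  ~23× depth — zeroed over each planted ORF ± 400 bp (every zero region
  therefore > 1 kb).  Real coverage is autocorrelated along reads; the
  Poisson model is adequate because region calling only thresholds depth.
- **Rearranged derivatives**: inversions and translocations applied to
  non-overlapping intervals, truth breakpoints recorded in reference
  coordinates; error-free 400 bp reads with uniform circular starts
  (substitution rate configurable up to 1%).

Everything is byte-deterministic per seed.  What passing tests on these
fixtures do **not** show: robustness to sequencing error and chimeric
reads, repeat-mediated recombination isomers, RNA editing, or the
real-data behaviour of the TM heuristic versus HMM predictors.

## Verification

Independent oracles back every nontrivial stage: a plain-Python Gotoh DP
for Smith–Waterman scores; a position-by-position six-frame enumerator for
the ORF scanner; brute-force run enumeration for synteny clusters; direct
window-mean computation for the TM heuristic; hypothesis-driven maximality
and disjointness properties for region segmentation.  End-to-end recovery
(precision = recall = 1.0 for the planted candidates among decoys) is
checked over ten fixed seeds, and `scripts/acceptance.py` recomputes the
same quantities from scratch for any seed.  The problem sizes used there —
100 kb genomes, ten fixtures, 40 kb rearrangement fixtures at 23× reads —
keep a full run in the low minutes on one CPU while leaving every rule
(strict >1 kb, strict >60%, ≥ 95%/≥ 16 bp, score ≥ 3) exercised at its
boundary.

## Known limitations

- Origin-crossing self-homology hits on circular genomes are not searched;
  a ≥ 16 bp duplication straddling the arbitrary origin is vanishingly
  unlikely but would be missed.
- Breakpoint coordinates are resolved to within k−1 bp, not to the base.
- The read-support denominator is this package's contract (the original
  mapper's "frequency" is undefined in public sources); its mixtures run a
  few points above the nominal fraction (see above).
- Gene-order clusters treat duplicated genes by suffix-renaming; a
  different duplicate pairing between two genomes can split a cluster.
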