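"""Synthetic mitochondrial-genome fixtures with machine-readable truth.

Emulates the study design of a CMS sequencing comparison at reduced scale:
a circular reference genome with annotated genes, a comparator line whose
read depth (~23x Poisson, matching the study's sequencing depth) drops to
zero over regions absent from that line, derivative genomes carrying
inversions/translocations, and planted chimeric ORFs built to satisfy the
candidate rubric — an exact fragment of a donor gene (some from the atp
family), a strongly hydrophobic stretch, and placement next to an annotated
gene.  Decoy ORFs satisfy none of the rubric components.

Everything is deterministic per seed, down to the emitted file bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coverage import NoCoverageRegion
from .orfs import OrfRecord
from .rearrange import Breakpoint
from .seqio import (CoverageTrack, GeneFeature, GenomeSequence, revcomp,
                    translate_orf, write_annotation, write_bedgraph,
                    write_fasta)

# Real plant mitochondrial gene names; the leading block guarantees atp
# donors and the six-cluster synteny genes are always present at n_genes=20.
GENE_CATALOG = [
    "atp1", "atp9", "cox3", "nad4", "nad5", "nad7", "rps4", "mttB", "ccmFc",
    "nad1", "nad6", "ccmB", "rpl5", "rps14", "cob", "rps3", "rpl16", "rps12",
    "nad3", "ccmC", "atp4", "atp6", "atp8", "nad2", "nad4L", "nad9", "cox1",
    "ccmFn", "rps10", "rpl2", "rps1", "rps7", "matR", "rrn18", "rrn26",
    "rrn5", "trnM", "trnC", "trnK", "trnW",
]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
# codons for strongly hydrophobic residues (L, I, V, F)
_HYDROPHOBIC_CODONS = ["CTT", "CTC", "CTG", "ATT", "ATC", "GTT", "GTC",
                       "GTG", "TTT", "TTC"]
# codons for hydrophilic/neutral residues only (D, E, K, N, Q, R, S, T, G, H)
_HYDROPHILIC_CODONS = ["GAT", "GAA", "AAA", "AAT", "CAA", "CGT", "AGT",
                       "ACT", "GGA", "CAT", "GAC", "GAG", "AAG", "AAC"]
# Hydrophilic 9-codon guard (peptide DNMNDHTKS) whose nucleotide text puts a
# stop codon in every non-native reading frame: GAT|AAT -> TAA (+2),
# ATG|AAT -> TGA (+1), and the reverse-frame stop precursors TCA (codon),
# GAT|CAT -> TCA, ACT|AAA -> CTA at the three remaining offsets.  Interleaved
# into decoy ORFs so no "shadow" ORF in another frame/strand can live
# inside a decoy cassette.
_DECOY_GUARD = "GAT" "AAT" "ATG" "AAT" "GAT" "CAT" "ACT" "AAA" "TCA"

# background base composition: mildly AT-rich, like plant mt intergenic DNA
_BG_BASES = np.array(list("ACGT"))
_BG_PROBS = np.array([0.30, 0.21, 0.21, 0.28])


@dataclass
class TruthTable:
    """Ground truth for one synthetic fixture."""

    seed: int
    planted_genes: list[GeneFeature] = field(default_factory=list)
    # (orf, donor gene name, donor genomic interval, expected score)
    planted_orfs: list[tuple[OrfRecord, str, tuple[int, int], int]] = \
        field(default_factory=list)
    planted_decoys: list[OrfRecord] = field(default_factory=list)
    planted_zero_regions: list[NoCoverageRegion] = field(default_factory=list)
    planted_breakpoints: list[Breakpoint] = field(default_factory=list)


def _random_codons(rng: np.random.Generator, n: int, pool: list[str]) -> str:
    return "".join(rng.choice(pool) for _ in range(n))


def _mismatch_codons(rng: np.random.Generator, target: str) -> str:
    """Sense codons whose bases each differ positionwise from ``target``.

    Used to fence a copied fragment: a local alignment extending past the
    fragment must first cross ``len(target)`` guaranteed mismatches (or an
    equally costly gap shift), which the scoring scheme cannot recover from
    in unrelated sequence.  ``target`` length must be a multiple of 3.
    """
    while True:
        bases = [str(rng.choice([b for b in "ACGT" if b != t]))
                 for t in target]
        codons = ["".join(bases[i:i + 3]) for i in range(0, len(bases), 3)]
        if not any(c in _STOPS for c in codons):
            return "".join(codons)


def _gene_sequence(rng: np.random.Generator, codons: int) -> str:
    body = _random_codons(rng, codons - 2, _SENSE_CODONS)
    stop = str(rng.choice(list(_STOPS)))
    return "ATG" + body + stop


def generate_reference(seed: int, length: int = 100_000,
                       n_genes: int = 20) -> tuple[GenomeSequence,
                                                   list[GeneFeature]]:
    """A circular random genome with non-overlapping planted genes.

    Gene lengths are scaled down (101-160 codons) so the default 20-gene
    fixture respects ``length >= 10 x total gene length``.  Every gene is a
    valid ORF on its own strand; tRNA/rRNA-named genes follow the same
    construction at this scale.
    """
    rng = np.random.default_rng(seed)
    names = GENE_CATALOG[:n_genes] if n_genes <= len(GENE_CATALOG) else None
    if names is None:
        raise ValueError(f"at most {len(GENE_CATALOG)} genes supported")
    gene_codons = rng.integers(101, 161, size=n_genes)
    if int(gene_codons.sum()) * 3 * 10 > length:
        raise ValueError("infeasible packing: genome must be >= 10x gene span")
    seq = rng.choice(_BG_BASES, size=length, p=_BG_PROBS)
    slot = length // n_genes
    features = []
    for i, (name, codons) in enumerate(zip(names, gene_codons)):
        gene_nt = _gene_sequence(rng, int(codons))
        start0 = i * slot + int(rng.integers(0, slot // 4))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = gene_nt if strand == "+" else revcomp(gene_nt)
        seq[start0:start0 + len(insert)] = list(insert)
        ftype = ("tRNA" if name.startswith("trn")
                 else "rRNA" if name.startswith("rrn") else "protein")
        features.append(GeneFeature(name, ftype, start0 + 1,
                                    start0 + len(insert), strand))
    genome = GenomeSequence("synthetic_mt", "".join(seq), circular=True)
    return genome, features


# default donor rotation: the genes the study found copied into candidates
DEFAULT_DONORS = ("atp9", "atp1", "nad5", "rps4", "nad4")


def _free_gaps(features: list[GeneFeature], occupied: list[tuple[int, int]],
               length: int) -> list[tuple[int, int]]:
    """Linear (non-wrapping) intervals free of genes and prior plantings."""
    taken = sorted([(f.start, f.stop) for f in features] + occupied)
    gaps = []
    prev_end = 0
    for s, e in taken:
        if s - 1 > prev_end + 1:
            gaps.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    if prev_end < length:
        gaps.append((prev_end + 1, length))
    return gaps


def plant_chimeric_orfs(genome: GenomeSequence, features: list[GeneFeature],
                        seed: int, n: int = 5, n_decoys: int = 20,
                        donors: tuple[str, ...] = DEFAULT_DONORS,
                        region_margin: int = 400,
                        ) -> tuple[GenomeSequence, TruthTable]:
    """Plant chimeric candidate ORFs and rubric-negative decoys.

    Each chimeric ORF is ATG-initiated, >= 101 codons, carries an exact
    in-frame >= 30 bp fragment of its donor gene, encodes a >= 25-residue
    hydrophobic stretch and sits within 1 kb of an annotated gene (expected
    score 4 for atp donors, 3 otherwise).  Decoys are hydrophilic-only ORFs
    placed >= 1.5 kb from any gene.  An in-frame stop codon is written
    immediately upstream of every planted ATG so the scanner's
    first-ATG-after-stop rule recovers the planted coordinates exactly.

    The truth table also records the zero-coverage regions (ORF +/-
    ``region_margin`` bp, each > 1 kb) that a comparator lacking these loci
    would show; feed them to :func:`simulate_coverage`.

    A random chimera cassette occasionally lacks stop codons in another
    frame or strand, creating a "shadow" ORF that overlaps the cassette and
    inherits its donor fragment — a legitimate extra candidate that would
    break the one-candidate-per-cassette truth table.  Planting is retried
    (deterministically) until no shadow ORF overlaps any chimera cassette.
    """
    for attempt in range(50):
        rng = np.random.default_rng([seed, attempt])
        out, truth = _plant_once(rng, genome, features, seed, n, n_decoys,
                                 donors, region_margin)
        from .orfs import scan_orfs
        planted = {(o.start, o.stop, o.strand)
                   for o, _, _, _ in truth.planted_orfs}
        cassettes = [(o.start - 3, o.stop) for o, _, _, _ in truth.planted_orfs]
        shadows = [o for o in scan_orfs(out, 101)
                   if (o.start, o.stop, o.strand) not in planted
                   and any(not (o.stop < cs or o.start > ce)
                           for cs, ce in cassettes)]
        if not shadows:
            return out, truth
    raise ValueError("packing failure: could not avoid shadow ORFs")


def _plant_once(rng: np.random.Generator, genome: GenomeSequence,
                features: list[GeneFeature], seed: int, n: int,
                n_decoys: int, donors: tuple[str, ...],
                region_margin: int) -> tuple[GenomeSequence, TruthTable]:
    L = genome.length
    seq = list(genome.seq)
    truth = TruthTable(seed=seed, planted_genes=list(features))
    gene_by_name = {f.name: f for f in features}
    occupied: list[tuple[int, int]] = []

    def build_chimera(donor: GeneFeature) -> tuple[str, int, tuple[int, int]]:
        """Return (orf nt, donor fragment offset in nt, donor genomic iv)."""
        donor_sense = genome.slice(donor.start, donor.stop, donor.strand)
        donor_codons = len(donor_sense) // 3
        m = int(rng.integers(10, 21))           # fragment codons: 30-60 bp
        off = int(rng.integers(1, donor_codons - m - 1))
        frag = donor_sense[3 * off:3 * (off + m)]
        if donor.strand == "+":
            donor_iv = (donor.start + 3 * off, donor.start + 3 * (off + m) - 1)
        else:
            donor_iv = (donor.stop - 3 * (off + m) + 1, donor.stop - 3 * off)
        # fence the fragment with 12 guaranteed-mismatch bases on each side
        # so the self-homology hit ends exactly at the fragment boundary
        pad = "ACACACACACAC"
        donor_prev = (pad + donor_sense[max(0, 3 * off - 12):3 * off])[-12:]
        donor_next = (donor_sense[3 * (off + m):3 * (off + m) + 12] + pad)[:12]
        pre = (_random_codons(rng, int(rng.integers(3, 14)), _SENSE_CODONS)
               + _mismatch_codons(rng, donor_prev))
        mid = (_mismatch_codons(rng, donor_next)
               + _random_codons(rng, int(rng.integers(1, 7)), _SENSE_CODONS))
        hydro = _random_codons(rng, int(rng.integers(25, 31)),
                               _HYDROPHOBIC_CODONS)
        core = "ATG" + pre + frag + mid + hydro
        pad = max(0, 101 - len(core) // 3 - 1) + int(rng.integers(0, 8))
        core += _random_codons(rng, pad, _SENSE_CODONS)
        nt = core + str(rng.choice(list(_STOPS)))
        frag_off = 3 + len(pre)
        return nt, frag_off, donor_iv

    def place(nt: str, pos0: int) -> OrfRecord:
        """Write 'TAA' + nt at 0-based pos0; return the truth OrfRecord."""
        cassette = "TAA" + nt
        seq[pos0:pos0 + len(cassette)] = list(cassette)
        start = pos0 + 3 + 1
        stop = start + len(nt) - 1
        occupied.append((start - region_margin, stop + region_margin))
        return OrfRecord(f"orf_{start}_{stop}_fwd", start, stop, "+",
                         (start - 1) % 3, len(nt), translate_orf(nt))

    # --- chimeric candidates: next to a gene, one gap per gene
    donor_cycle = [d for d in donors if d in gene_by_name]
    if not donor_cycle:
        raise ValueError("no donor genes present in the annotation")
    used_genes: set[str] = set()
    for i in range(n):
        donor = gene_by_name[donor_cycle[i % len(donor_cycle)]]
        nt, _, donor_iv = build_chimera(donor)
        placed = False
        for host in features:  # deterministic order; skip used neighbourhoods
            if host.name in used_genes:
                continue
            offset = int(rng.integers(150, 601))
            p0 = host.stop + offset  # 0-based == 1-based stop + offset - 1 + 1
            if p0 + len(nt) + 3 + region_margin + 60 >= L:
                continue
            iv = (p0 - region_margin, p0 + len(nt) + 3 + region_margin)
            clash = any(not (iv[1] < s or iv[0] > e)
                        for s, e in occupied)
            clash = clash or any(not (iv[1] < f.start or iv[0] > f.stop)
                                 for f in features if f.name != host.name)
            if clash:
                continue
            orf = place(nt, p0)
            expected = 4 if donor.name.startswith("atp") else 3
            truth.planted_orfs.append((orf, donor.name, donor_iv, expected))
            used_genes.add(host.name)
            placed = True
            break
        if not placed:
            raise ValueError("packing failure: no room for chimeric ORF")

    # --- decoys: hydrophilic-only ORFs far from genes
    decoys_left = n_decoys
    for gs, ge in sorted(_free_gaps(features, occupied, L),
                         key=lambda g: g[0] - g[1]):
        p0 = gs - 1 + 1500
        while decoys_left > 0:
            codons = int(rng.integers(101, 131))
            body = ""
            while len(body) < 3 * (codons - 2):
                body += _random_codons(rng, int(rng.integers(6, 11)),
                                       _HYDROPHILIC_CODONS) + _DECOY_GUARD
            nt = ("ATG" + body[:3 * (codons - 2)]
                  + str(rng.choice(list(_STOPS))))
            end0 = p0 + 3 + len(nt)
            if end0 + 1500 > ge or end0 + region_margin + 60 >= L:
                break
            truth.planted_decoys.append(place(nt, p0))
            decoys_left -= 1
            p0 = end0 + 2 * region_margin + 120
        if decoys_left == 0:
            break
    if decoys_left > 0:
        raise ValueError("packing failure: no room for decoy ORFs")

    # --- zero-coverage truth regions around every planted ORF
    for orf in [t[0] for t in truth.planted_orfs] + truth.planted_decoys:
        s = max(1, orf.start - region_margin)
        e = min(L, orf.stop + region_margin)
        truth.planted_zero_regions.append(
            NoCoverageRegion(s, e, e - s + 1, 0.0))
    truth.planted_zero_regions.sort(key=lambda r: r.start)
    return GenomeSequence(genome.id, "".join(seq), genome.circular), truth


def simulate_coverage(genome: GenomeSequence, seed: int,
                      mean_depth: float = 23.0,
                      zero_regions: list[tuple[int, int]] | None = None,
                      ) -> CoverageTrack:
    """Poisson per-base depth with planted zero-depth regions.

    ``zero_regions`` are (1-based start, length) pairs; they must lie within
    the genome and not overlap.
    """
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, genome.length).astype(np.int64)
    seen = np.zeros(genome.length, dtype=bool)
    for start, length in zero_regions or ():
        if start < 1 or start + length - 1 > genome.length:
            raise ValueError(f"zero region ({start},{length}) outside genome")
        sl = slice(start - 1, start - 1 + length)
        if seen[sl].any():
            raise ValueError("overlapping zero regions")
        seen[sl] = True
        depth[sl] = 0
    return CoverageTrack(genome.id, depth)


def derive_rearranged(genome: GenomeSequence, seed: int,
                      events: list[dict]) -> tuple[GenomeSequence, TruthTable]:
    """Apply inversion/translocation events; truth on REFERENCE coordinates.

    Event specs: ``{"kind": "inversion", "start": s, "stop": e}`` or
    ``{"kind": "translocation", "start": s, "stop": e, "insert_after": p}``
    (all 1-based inclusive, non-wrapping, mutually non-overlapping; the
    insertion point must lie outside every event interval).
    """
    truth = TruthTable(seed=seed)
    ivs = sorted((ev["start"], ev["stop"]) for ev in events)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError("overlapping rearrangement events")
    seq = genome.seq
    # token stream over reference coordinates: ("fwd"|"inv", start, stop)
    tokens: list[tuple[str, int, int]] = []
    inserts: list[tuple[int, int, int]] = []  # (insert_after, start, stop)
    cursor = 1
    for ev in sorted(events, key=lambda e: e["start"]):
        s, e = ev["start"], ev["stop"]
        if cursor < s:
            tokens.append(("fwd", cursor, s - 1))
        if ev["kind"] == "inversion":
            tokens.append(("inv", s, e))
            truth.planted_breakpoints += [
                Breakpoint(s, "inversion_junction", 1.0, "truth"),
                Breakpoint(e, "inversion_junction", 1.0, "truth")]
        elif ev["kind"] == "translocation":
            p = ev["insert_after"]
            if any(s2 <= p <= e2 for s2, e2 in ivs):
                raise ValueError("insertion point inside an event interval")
            inserts.append((p, s, e))
            truth.planted_breakpoints += [
                Breakpoint(s, "translocation_junction", 1.0, "truth"),
                Breakpoint(e, "translocation_junction", 1.0, "truth"),
                Breakpoint(p, "translocation_junction", 1.0, "truth")]
        else:
            raise ValueError(f"unknown event kind {ev['kind']!r}")
        cursor = e + 1
    if cursor <= genome.length:
        tokens.append(("fwd", cursor, genome.length))
    for p, bs, be in inserts:
        for i, (kind, s, e) in enumerate(tokens):
            if kind == "fwd" and s <= p <= e:
                repl = [t for t in [("fwd", s, p), ("fwd", bs, be),
                                    ("fwd", p + 1, e)] if t[1] <= t[2]]
                tokens[i:i + 1] = repl
                break
        else:
            raise ValueError(f"insertion point {p} not in retained sequence")
    derived = "".join(seq[s - 1:e] if kind == "fwd"
                      else revcomp(seq[s - 1:e]) for kind, s, e in tokens)
    truth.planted_breakpoints.sort(key=lambda b: b.ref_pos)
    return (GenomeSequence(genome.id + "_derived", derived, genome.circular),
            truth)


def simulate_reads(genome: GenomeSequence, seed: int, n_reads: int,
                   read_length: int = 400,
                   sub_rate: float = 0.0) -> list[GenomeSequence]:
    """Error-free (or low-substitution) reads with uniform circular starts."""
    if sub_rate > 0.01:
        raise ValueError("substitution rate capped at 1%")
    rng = np.random.default_rng(seed)
    ext = genome.seq + genome.seq[:read_length] if genome.circular \
        else genome.seq
    max_start = genome.length if genome.circular \
        else genome.length - read_length + 1
    reads = []
    for i in range(n_reads):
        s0 = int(rng.integers(0, max_start))
        r = ext[s0:s0 + read_length]
        if sub_rate > 0:
            r = list(r)
            for j in range(len(r)):
                if rng.random() < sub_rate:
                    r[j] = str(rng.choice(_BG_BASES))
            r = "".join(r)
        if rng.random() < 0.5:
            r = revcomp(r)
        reads.append(GenomeSequence(f"read_{i}", r, circular=False))
    return reads


def write_fixture(outdir: str | Path, genome: GenomeSequence,
                  features: list[GeneFeature], track: CoverageTrack,
                  truth: TruthTable) -> None:
    """Emit FASTA + GFF3 + bedGraph + truth tables into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([genome], outdir / "reference.fasta")
    write_annotation(features, outdir / "annotation.gff3", genome.id, "gff3")
    write_bedgraph(track, outdir / "coverage.bedgraph")
    rows = []
    for orf, donor, donor_iv, score in truth.planted_orfs:
        rows.append({"orf_id": orf.orf_id, "start": orf.start,
                     "stop": orf.stop, "donor": donor,
                     "donor_start": donor_iv[0], "donor_stop": donor_iv[1],
                     "expected_score": score})
    for orf in truth.planted_decoys:
        rows.append({"orf_id": orf.orf_id, "start": orf.start,
                     "stop": orf.stop, "donor": "", "donor_start": 0,
                     "donor_stop": 0, "expected_score": 0})
    import pandas as pd

    from .seqio import write_tsv
    write_tsv(pd.DataFrame(rows), outdir / "truth_orfs.tsv")
    meta = {"seed": truth.seed,
            "zero_regions": [[r.start, r.stop]
                             for r in truth.planted_zero_regions],
            "breakpoints": [[b.ref_pos, b.kind]
                            for b in truth.planted_breakpoints]}
    (outdir / "truth.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
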