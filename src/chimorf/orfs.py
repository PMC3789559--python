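"""Six-frame ORF discovery and restriction to rearrangement vicinity.

An ORF is a maximal ATG-initiated, stop-terminated reading frame.  Codon
counts include the stop codon, so the ">100 codons" rule becomes
``min_codons = 101`` (303 nt inclusive).  Reported coordinates are always
1-based inclusive on the forward strand; the report column "ORF length"
follows the stop − start convention of the source tables, i.e.
``reported_length = nt_length - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coords import interval_length, interval_overlap, point_to_interval_dist
from .seqio import GeneFeature, GenomeSequence, translate_orf

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class OrfRecord:
    orf_id: str
    start: int      # 1-based inclusive, forward strand
    stop: int       # start > stop encodes an origin-spanning ORF
    strand: str
    frame: int      # 0-based frame on the scanned strand
    nt_length: int  # inclusive span, divisible by 3, includes the stop codon
    peptide: str

    @property
    def codons(self) -> int:
        return self.nt_length // 3

    @property
    def reported_length(self) -> int:
        """stop − start; the length convention of the candidate report."""
        return self.nt_length - 1

    def interval(self) -> tuple[int, int]:
        return (self.start, self.stop)


def _scan_strand(seq: str, L: int, circular: bool, min_codons: int,
                 strand: str) -> list[OrfRecord]:
    """Scan one strand; ``seq`` is the strand's own 5'->3' sequence."""
    ext = seq + seq if circular else seq
    found: dict[tuple[int, int], OrfRecord] = {}
    for frame in range(3):
        atg = None
        for pos in range(frame, len(ext) - 2, 3):
            codon = ext[pos:pos + 3]
            if codon in _STOPS:
                if atg is not None and atg < L:
                    nt_len = pos + 3 - atg
                    if nt_len <= L and nt_len // 3 >= min_codons:
                        rec = _to_record(atg, pos + 2, nt_len, ext, L, strand)
                        key = (rec.strand, rec.stop if rec.strand == "+" else rec.start)
                        prev = found.get(key)
                        # one ORF per stop codon: keep the longest (first ATG)
                        if prev is None or rec.nt_length > prev.nt_length:
                            found[key] = rec
                atg = None
            elif codon == "ATG" and atg is None:
                atg = pos
    return list(found.values())


def _to_record(start0: int, stop0: int, nt_len: int, ext: str, L: int,
               strand: str) -> OrfRecord:
    nt = ext[start0:stop0 + 1]
    pep = translate_orf(nt)
    if strand == "+":
        s = start0 % L + 1
        e = stop0 % L + 1
    else:
        # map strand-local 0-based positions back to forward coordinates
        s = L - 1 - (stop0 % L) + 1
        e = L - 1 - (start0 % L) + 1
    orf_id = f"orf_{s}_{e}_{'fwd' if strand == '+' else 'rev'}"
    return OrfRecord(orf_id, s, e, strand, start0 % 3, nt_len, pep)


def scan_orfs(genome: GenomeSequence, min_codons: int = 101) -> list[OrfRecord]:
    """All maximal ATG..stop ORFs with >= min_codons codons, both strands.

    Circular genomes are scanned across the origin.  Within one frame only
    the longest ORF per stop codon (the first ATG after the previous stop)
    is reported.  Output is sorted by (start, stop, strand).
    """
    L = genome.length
    recs = _scan_strand(genome.seq, L, genome.circular, min_codons, "+")
    recs += _scan_strand(genome.revcomp(), L, genome.circular, min_codons, "-")
    recs.sort(key=lambda r: (r.start, r.stop, r.strand))
    return recs


def filter_candidate_orfs(orfs: list[OrfRecord], regions, breakpoints,
                          genome_length: int, flank: int = 5000,
                          circular: bool = True) -> list[OrfRecord]:
    """ORFs overlapping a no-coverage region or within ``flank`` of a breakpoint."""
    kept = []
    for orf in orfs:
        iv = orf.interval()
        hit = any(interval_overlap(iv, (r.start, r.stop), genome_length, circular) > 0
                  for r in regions)
        if not hit:
            hit = any(point_to_interval_dist(b.ref_pos, iv, genome_length,
                                             circular) <= flank
                      for b in breakpoints)
        if hit:
            kept.append(orf)
    kept.sort(key=lambda r: (r.start, r.stop, r.strand))
    return kept


def exclude_known_genes(orfs: list[OrfRecord], features: list[GeneFeature],
                        genome_length: int, min_overlap_fraction: float = 0.5,
                        circular: bool = True) -> list[OrfRecord]:
    """Drop ORFs that mostly re-code an annotated gene.

    An ORF is removed when an annotated protein/tRNA/rRNA feature overlaps
    at least ``min_overlap_fraction`` of the ORF's own length.
    """
    annotated = [f for f in features if f.ftype != "ORF"]
    kept = []
    for orf in orfs:
        olen = interval_length(orf.start, orf.stop, genome_length)
        drop = any(
            interval_overlap(orf.interval(), (f.start, f.stop), genome_length,
                             circular) >= min_overlap_fraction * olen
            for f in annotated)
        if not drop:
            kept.append(orf)
    return kept


def orfs_to_frame(orfs: list[OrfRecord]) -> pd.DataFrame:
    rows = [{"orf_id": o.orf_id, "start": o.start, "stop": o.stop,
             "strand": o.strand, "reported_length": o.reported_length,
             "codons": o.codons} for o in orfs]
    return pd.DataFrame(rows, columns=["orf_id", "start", "stop", "strand",
                                       "reported_length", "codons"])
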