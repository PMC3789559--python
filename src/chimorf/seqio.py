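"""Sequence, annotation and coverage I/O plus core sequence utilities.

The pipeline works in 1-based inclusive forward-strand coordinates
internally; conversions to the 0-based half-open conventions of BED and
bedGraph happen only here, at the file boundary.

Formats handled: FASTA (via Biopython), GFF3 (via gffutils' line parser),
BED, bedGraph / two-column per-base TSV, and TSV reports (via pandas).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .coords import interval_length

_VALID_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature classes accepted in annotations; "ORF" marks unannotated ORF loci.
FEATURE_TYPES = ("protein", "tRNA", "rRNA", "ORF")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class GenomeSequence:
    """A (possibly circular) nucleotide sequence with an identifier."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def revcomp(self) -> str:
        return self.seq.translate(_COMPLEMENT)[::-1]

    def slice(self, start: int, stop: int, strand: str = "+") -> str:
        """Extract [start, stop] (1-based inclusive, wrap-aware).

        For strand '-', returns the reverse complement (the sense sequence of
        a minus-strand feature).
        """
        if start <= stop:
            s = self.seq[start - 1:stop]
        else:
            if not self.circular:
                raise ValueError("wrapping slice on a linear sequence")
            s = self.seq[start - 1:] + self.seq[:stop]
        if strand == "-":
            s = s.translate(_COMPLEMENT)[::-1]
        return s


@dataclass
class GeneFeature:
    """An annotated gene in 1-based inclusive forward-strand coordinates.

    ``start > stop`` encodes a feature spanning the circular origin.
    """

    name: str
    ftype: str
    start: int
    stop: int
    strand: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("feature with empty name")
        if self.ftype not in FEATURE_TYPES:
            raise FormatError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.name}")

    def length(self, genome_length: int) -> int:
        return interval_length(self.start, self.stop, genome_length)


@dataclass
class CoverageTrack:
    """Per-base read depth; ``depth[i]`` is the depth at base ``i+1``."""

    seq_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise FormatError("coverage track must be a non-empty 1-D array")
        if (self.depth < 0).any():
            raise FormatError("coverage track contains negative depths")

    @property
    def length(self) -> int:
        return int(self.depth.size)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeSequence]:
    """Read FASTA records; sequences are uppercased and U is mapped to T.

    Circularity is not expressible in FASTA, so it is set from the
    ``circular`` flag for every record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            records.append(GenomeSequence(rec.id, seq, circular=circular))
        except FormatError as exc:
            raise FormatError(f"record {rec.id!r}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(genomes: list[GenomeSequence] | dict[str, str], path: str | Path,
                width: int = 70) -> None:
    if isinstance(genomes, dict):
        recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genomes.items()]
    else:
        recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Annotations

_GFF_TYPE_MAP = {"tRNA": "tRNA", "rRNA": "rRNA", "ORF": "ORF"}


def _ftype_from_name(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "protein"


def read_annotation(path: str | Path, fmt: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or BED into 1-based inclusive coordinates.

    GFF3 names come from the ``Name`` (or ``gene``) attribute; BED names from
    column 4.  BED's 0-based half-open intervals are converted on the way in.
    """
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    feats: list[GeneFeature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        if fmt == "gff3":
            f = feature_from_line(line)
            if f.end < f.start:
                raise FormatError(f"{path}:{lineno}: stop < start in GFF3")
            name = (f.attributes.get("Name") or f.attributes.get("gene") or [None])[0]
            if not name:
                raise FormatError(f"{path}:{lineno}: missing Name/gene attribute")
            ftype = _GFF_TYPE_MAP.get(f.featuretype, "protein")
            feats.append(GeneFeature(name, ftype, int(f.start), int(f.end),
                                     f.strand if f.strand in "+-" else "+"))
        else:
            cols = line.split("\t")
            if len(cols) < 4 or not cols[3]:
                raise FormatError(f"{path}:{lineno}: BED line lacks a name field")
            start0, end0 = int(cols[1]), int(cols[2])
            strand = cols[5] if len(cols) > 5 else "+"
            feats.append(GeneFeature(cols[3], _ftype_from_name(cols[3]),
                                     start0 + 1, end0, strand))
    return feats


def write_annotation(features: list[GeneFeature], path: str | Path,
                     seq_id: str, fmt: str = "gff3") -> None:
    lines = []
    if fmt == "gff3":
        lines.append("##gff-version 3")
        for f in features:
            ftype = {"protein": "gene"}.get(f.ftype, f.ftype)
            lines.append("\t".join([
                seq_id, "chimorf", ftype, str(f.start), str(f.stop),
                ".", f.strand, ".", f"Name={f.name}"]))
    elif fmt == "bed":
        for f in features:
            lines.append("\t".join([seq_id, str(f.start - 1), str(f.stop),
                                    f.name, "0", f.strand]))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coverage


def read_coverage(path: str | Path, genome_length: int,
                  seq_id: str | None = None) -> CoverageTrack:
    """Read a depth track from bedGraph or two-column (pos, depth) TSV.

    Positions absent from the file get depth 0.  Overlapping bedGraph
    intervals and positions beyond the genome length are errors.
    """
    text = Path(path).read_text()
    depth = np.zeros(genome_length, dtype=np.int64)
    rows = [ln.split("\t") for ln in text.splitlines()
            if ln.strip() and not ln.startswith(("#", "track"))]
    if not rows:
        return CoverageTrack(seq_id or "unknown", depth)
    ncol = len(rows[0])
    seen = np.zeros(genome_length, dtype=bool)
    if ncol >= 4:  # bedGraph: chrom, start0, end0, value
        sid = rows[0][0]
        for cols in rows:
            start0, end0, value = int(cols[1]), int(cols[2]), int(float(cols[3]))
            if end0 > genome_length or start0 < 0:
                raise FormatError(
                    f"{path}: interval [{start0},{end0}) beyond genome length {genome_length}")
            if seen[start0:end0].any():
                raise FormatError(f"{path}: overlapping bedGraph intervals at {start0}")
            seen[start0:end0] = True
            depth[start0:end0] = value
    elif ncol == 2:  # per-base TSV: 1-based pos, depth
        sid = seq_id or "unknown"
        for cols in rows:
            pos, value = int(cols[0]), int(float(cols[1]))
            if not 1 <= pos <= genome_length:
                raise FormatError(f"{path}: position {pos} beyond genome length")
            depth[pos - 1] = value
    else:
        raise FormatError(f"{path}: expected bedGraph or 2-column TSV")
    return CoverageTrack(seq_id or sid, depth)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a run-length-encoded bedGraph (0-based half-open)."""
    d = track.depth
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [d.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.seq_id}\t{s}\t{e}\t{int(d[s])}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV: fixed column order, '\\n' endings, no index."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Sequence utilities

_STOPS = {"TAA", "TAG", "TGA"}


def translate_orf(nt: str) -> str:
    """Translate an ORF with the standard genetic code.

    Plant mitochondria use the standard table.  A trailing stop codon is
    dropped from the peptide; an internal stop codon is an error, as is a
    length not divisible by 3.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"ORF length {len(nt)} not divisible by 3")
    pep = str(Seq(nt).translate(table=1))
    if pep.endswith("*"):
        pep = pep[:-1]
    if "*" in pep:
        raise ValueError(f"internal stop codon at codon {pep.index('*') + 1}")
    return pep


def gc_profile(genome: GenomeSequence, window: int, step: int) -> list[tuple[int, float]]:
    """Sliding-window GC fraction, (1-based window start, GC fraction).

    Circular genomes wrap the final windows; for linear genomes only fully
    contained windows are reported.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = genome.length
    if window > L and not genome.circular:
        raise ValueError(f"window {window} exceeds linear genome length {L}")
    seq = genome.seq + genome.seq[:window - 1] if genome.circular else genome.seq
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    out = []
    last_start = L if genome.circular else L - window + 1
    for s0 in range(0, last_start, step):
        gc = int(csum[s0 + window] - csum[s0])
        out.append((s0 + 1, gc / window))
    return out
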