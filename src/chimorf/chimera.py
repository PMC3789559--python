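"""Chimeric-structure detection and the 0-4 candidate score.

Each candidate ORF is locally aligned against both strands of the reference
genome (affine-gap Smith-Waterman, scoring +2/-3/-5/-2, BLASTN-like
defaults).  After removing the ORF's own locus ("the original location"),
hits with integer identity >= 95% over >= 16 bp of subject sequence are
retained as evidence that the ORF carries a copied fragment.  Hydrophobic
(candidate transmembrane) segments are called with a Kyte-Doolittle
window-19 mean-hydropathy > 1.6 heuristic.  The score awards one point each
for: carrying parts of other genes/ORFs, proximity (<= 1 kb) to an annotated
gene, a hydrophobic domain, and a bonus for carrying part of an atp gene;
ORFs scoring >= 3 are retained as CMS candidates.

Coordinate conventions in the report follow the source tables: a
reverse-strand hit is encoded as subject_start > subject_stop, "chimera
length" is |subject_stop - subject_start| + 1, and "ORF length" is
stop - start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd
from numba import njit

from .coords import interval_gap, interval_overlap
from .orfs import OrfRecord
from .seqio import GeneFeature, GenomeSequence, revcomp

# ---------------------------------------------------------------------------
# Smith-Waterman (affine gaps, full traceback)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i  # N and anything else -> 4, never matches


@dataclass
class LocalAlignment:
    query_start: int     # 1-based inclusive on the query
    query_stop: int
    subject_start: int   # 1-based inclusive on the subject string
    subject_stop: int
    score: int
    matches: int
    columns: int         # aligned columns including gaps
    #: per-column (query_pos, subject_pos, column score); 0 marks a gap
    path: list[tuple[int, int, int]] = field(default=None, repr=False)

    @property
    def identity_pct(self) -> int:
        """Integer identity, rounded half up."""
        return int(floor(100 * self.matches / self.columns + 0.5))

    @property
    def match_length(self) -> int:
        return abs(self.subject_stop - self.subject_start) + 1


@njit(cache=False)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = a.size, b.size
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)   # 0 stop, 1 diag, 2 E, 3 F
    extE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    extF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                extE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                extF[i, j] = 1
            else:
                F[i, j] = f_open
            s = match if (ai == b[j - 1] and ai != 4) else mismatch
            diag = H[i - 1, j - 1] + s
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if E[i, j] > h:
                h, p = E[i, j], 2
            if F[i, j] > h:
                h, p = F[i, j], 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best or (h == best and (j < bj or (j == bj and i < bi))):
                best, bi, bj = h, i, j
    return H, ptrH, extE, extF, best, bi, bj


def smith_waterman(a: str, b: str, match: int = 2, mismatch: int = -3,
                   gap_open: int = -5,
                   gap_extend: int = -2) -> LocalAlignment | None:
    """Optimal local alignment of ``a`` vs ``b`` under affine gap costs.

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``.  N never
    matches.  Ties between co-optimal end cells break to the lowest subject
    position, then the lowest query position; traceback prefers diagonal
    moves.  Returns None when no positive-scoring alignment exists.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    ea = _ENCODE[np.frombuffer(a.encode(), dtype=np.uint8)]
    eb = _ENCODE[np.frombuffer(b.encode(), dtype=np.uint8)]
    H, ptrH, extE, extF, best, bi, bj = _sw_fill(
        ea, eb, match, mismatch, gap_open, gap_extend)
    if best <= 0:
        return None
    i, j = bi, bj
    matches = columns = 0
    path: list[tuple[int, int, int]] = []
    while H[i, j] > 0:
        p = ptrH[i, j]
        if p == 1:
            hit = ea[i - 1] == eb[j - 1] and ea[i - 1] != 4
            matches += int(hit)
            columns += 1
            path.append((i, j, match if hit else mismatch))
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                ext = extE[i, j]
                columns += 1
                path.append((0, j, gap_extend))
                j -= 1
                if not ext:
                    break
            path[-1] = (0, path[-1][1], gap_open)  # leftmost column opens
        elif p == 3:
            while True:
                ext = extF[i, j]
                columns += 1
                path.append((i, 0, gap_extend))
                i -= 1
                if not ext:
                    break
            path[-1] = (path[-1][0], 0, gap_open)
        else:
            break
    path.reverse()
    return LocalAlignment(i + 1, bi, j + 1, bj, int(best), matches, columns,
                          path)


# ---------------------------------------------------------------------------
# Self-homology search

@dataclass
class ChimeraHit:
    """A retained non-self hit of an ORF elsewhere in the genome.

    ``subject_start > subject_stop`` encodes a reverse-strand hit.
    """

    orf_id: str
    subject_start: int
    subject_stop: int
    identity_pct: int
    score: int
    subject_feature: str = "—"

    @property
    def match_length(self) -> int:
        return abs(self.subject_stop - self.subject_start) + 1

    def interval(self) -> tuple[int, int]:
        return (min(self.subject_start, self.subject_stop),
                max(self.subject_start, self.subject_stop))


class SelfHomologySearcher:
    """Word index over both genome strands, reused across ORF queries.

    Alignment is seeded from exact shared words (default 11, the classic
    nucleotide-search word size), so a hit must contain an exact >= word_size
    run to be found — the same seeding property as word-based search tools.
    Origin-crossing subject hits on circular genomes are not searched; with
    mitochondrial-scale genomes the probability that a >= 16 bp duplication
    straddles the arbitrary origin is negligible.
    """

    def __init__(self, genome: GenomeSequence, word_size: int = 11):
        self.genome = genome
        self.word_size = word_size
        self.subjects = {"+": genome.seq, "-": revcomp(genome.seq)}
        self.words: dict[str, dict[str, list[int]]] = {}
        for strand, seq in self.subjects.items():
            d: dict[str, list[int]] = {}
            for i in range(len(seq) - word_size + 1):
                d.setdefault(seq[i:i + word_size], []).append(i)
            self.words[strand] = d

    def seed_windows(self, q: str, strand: str) -> list[tuple[int, int]]:
        """Merged 0-based [start, end) subject windows sharing a word with q."""
        w = self.word_size
        d = self.words[strand]
        positions = sorted({p for i in range(len(q) - w + 1)
                            for p in d.get(q[i:i + w], ())})
        if not positions:
            return []
        pad = len(q) + 50
        merged: list[list[int]] = []
        for p in positions:
            if merged and p - merged[-1][1] <= len(q):
                merged[-1][1] = p + w
            else:
                merged.append([p, p + w])
        n = len(self.subjects[strand])
        windows = [(max(0, s - pad), min(n, e + pad)) for s, e in merged]
        out = [list(windows[0])]
        for s, e in windows[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]


def _trim_to_clean_core(aln: LocalAlignment, min_identity: int,
                        min_length: int) -> tuple[int, int, int, int] | None:
    """Best-scoring sub-alignment meeting the identity/length thresholds.

    An optimal local alignment may extend a clean copied fragment through
    noisy flanks (small gaps plus chance matches), dragging overall identity
    below the retention bar.  This recovers the qualifying core: the
    contiguous column window of maximal score whose match fraction and
    subject span satisfy the thresholds.  Returns (subject_start,
    subject_stop, matches, columns, score) or None.
    """
    path = aln.path
    n = len(path)
    best_key, best_val = None, None
    for i in range(n):
        if path[i][0] == 0 or path[i][2] < 0:
            continue  # windows start on a match column
        score = matches = 0
        s_start = path[i][1]
        for j in range(i, n):
            q, s, col_score = path[j]
            score += col_score
            matches += int(col_score > 0)
            if q == 0 or col_score < 0:
                continue  # windows end on a match column
            cols = j - i + 1
            span = s - s_start + 1
            identity = int(floor(100 * matches / cols + 0.5))
            if span >= min_length and identity >= min_identity:
                key = (score, -span, -s_start)  # max score, then shortest
                if best_key is None or key > best_key:
                    best_key = key
                    best_val = (s_start, s, matches, cols, score)
    return best_val


def find_self_homology(orf: OrfRecord, genome: GenomeSequence,
                       min_identity: int = 95, min_length: int = 16,
                       max_hits: int = 10,
                       searcher: SelfHomologySearcher | None = None
                       ) -> list[ChimeraHit]:
    """Non-self local-alignment hits of an ORF against the whole genome.

    The ORF sequence is repeatedly aligned against each strand with already
    found subject intervals masked out, until no alignment that could pass
    the identity/length thresholds remains.  Hits overlapping the ORF's own
    genomic interval (the original location) are removed; survivors must
    satisfy identity >= ``min_identity`` and subject span >= ``min_length``.
    """
    if searcher is None:
        searcher = SelfHomologySearcher(genome)
    L = genome.length
    q = genome.slice(orf.start, orf.stop, orf.strand)
    own = orf.interval()
    accepted: list[ChimeraHit] = []
    min_score = 2 * min_length  # an exact min_length match; weaker cannot pass
    for strand in "+-":
        subject = searcher.subjects[strand]
        for ws, we in searcher.seed_windows(q, strand):
            win = list(subject[ws:we])
            for _ in range(max_hits + 10):
                aln = smith_waterman(q, "".join(win))
                if aln is None or aln.score < min_score:
                    break
                # mask this subject interval before the next round
                for p in range(aln.subject_start - 1, aln.subject_stop):
                    win[p] = "N"
                if (aln.identity_pct >= min_identity
                        and aln.match_length >= min_length):
                    core = (aln.subject_start, aln.subject_stop,
                            aln.matches, aln.columns, aln.score)
                else:
                    # a noisy extension can drag a clean copied fragment
                    # below the identity bar; recover the qualifying core
                    core = _trim_to_clean_core(aln, min_identity, min_length)
                    if core is None:
                        continue
                s_win, e_win, matches, columns, score = core
                s_ext = ws + s_win  # 1-based on the strand string
                e_ext = ws + e_win
                if strand == "+":
                    sub_start, sub_stop = s_ext, e_ext
                else:
                    sub_start, sub_stop = L - s_ext + 1, L - e_ext + 1
                iv = (min(sub_start, sub_stop), max(sub_start, sub_stop))
                if interval_overlap(iv, own, L, genome.circular) > 0:
                    continue  # self locus
                identity = int(floor(100 * matches / columns + 0.5))
                accepted.append(ChimeraHit(orf.orf_id, sub_start, sub_stop,
                                           identity, score))
    accepted.sort(key=lambda h: (-h.score, h.interval()))
    accepted = accepted[:max_hits]
    accepted.sort(key=lambda h: h.interval())
    return accepted


def annotate_hit_feature(hit: ChimeraHit, features: list[GeneFeature],
                         genome_length: int, orf_loci: list[OrfRecord] = (),
                         circular: bool = True) -> ChimeraHit:
    """Label a hit with the annotated gene it lands in, or "ORF", or an em dash.

    The gene with the largest overlap wins (ties to the lowest start); a hit
    in unannotated sequence that overlaps a discovered ORF locus is labelled
    "ORF".
    """
    iv = hit.interval()
    best_name, best_ov, best_start = None, 0, None
    for f in features:
        if f.ftype == "ORF":
            continue
        ov = interval_overlap(iv, (f.start, f.stop), genome_length, circular)
        if ov > best_ov or (ov == best_ov and ov > 0 and f.start < best_start):
            best_name, best_ov, best_start = f.name, ov, f.start
    if best_name is not None:
        hit.subject_feature = best_name
        return hit
    for o in orf_loci:
        if o.orf_id == hit.orf_id:
            continue
        if interval_overlap(iv, o.interval(), genome_length, circular) > 0:
            hit.subject_feature = "ORF"
            return hit
    hit.subject_feature = "—"
    return hit


# ---------------------------------------------------------------------------
# Transmembrane-helix stand-in (Kyte-Doolittle sliding window)

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass
class TMPrediction:
    helix_count: int
    segments: list[tuple[int, int]]  # 1-based inclusive residue intervals


def predict_tm_helices(peptide: str, window: int = 19,
                       threshold: float = 1.6) -> TMPrediction:
    """Hydrophobic segments by windowed mean Kyte-Doolittle hydropathy.

    Windows whose mean hydropathy exceeds ``threshold`` are marked;
    overlapping or adjacent marked windows merge into one segment.  This is
    a transparent heuristic stand-in for an HMM topology predictor: helix
    counts on real proteins will differ from TMHMM-style predictors.
    """
    for pos, aa in enumerate(peptide, 1):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
    if len(peptide) < window:
        return TMPrediction(0, [])
    vals = np.array([KYTE_DOOLITTLE[aa] for aa in peptide])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    marked = np.flatnonzero(means > threshold)
    segments: list[list[int]] = []
    for i in marked:
        start, end = int(i) + 1, int(i) + window
        if segments and start <= segments[-1][1] + 1:
            segments[-1][1] = end
        else:
            segments.append([start, end])
    return TMPrediction(len(segments), [tuple(s) for s in segments])


# ---------------------------------------------------------------------------
# Proximity, scoring, report

def nearest_gene(orf: OrfRecord, features: list[GeneFeature],
                 genome_length: int, max_distance: int = 1000,
                 circular: bool = True) -> tuple[str, int] | None:
    """Closest annotated gene by circular interval distance, if within range."""
    best = None
    for f in features:
        if f.ftype == "ORF":
            continue
        d = interval_gap(orf.interval(), (f.start, f.stop), genome_length,
                         circular)
        key = (d, f.start)
        if best is None or key < best[0]:
            best = (key, f.name)
    if best is None or best[0][0] > max_distance:
        return None
    return best[1], best[0][0]


@dataclass
class CandidateScore:
    orf_id: str
    parts_of_other: int
    proximity: int
    hydrophobic: int
    atp_bonus: int
    nearest_gene: str = "—"

    @property
    def total(self) -> int:
        return self.parts_of_other + self.proximity + self.hydrophobic + self.atp_bonus

    @property
    def retained(self) -> bool:
        return self.total >= 3


def score_candidate(orf: OrfRecord, hits: list[ChimeraHit], tm: TMPrediction,
                    near: tuple[str, int] | None) -> CandidateScore:
    """Apply the 0-4 rubric: parts-of-other, proximity, hydrophobic, atp bonus."""
    parts = int(bool(hits))
    atp = int(any(h.subject_feature.startswith("atp") for h in hits))
    prox = int(near is not None)
    hydro = int(tm.helix_count >= 1)
    return CandidateScore(orf.orf_id, parts, prox, hydro, atp,
                          near[0] if near else "—")


REPORT_COLUMNS = ["orf_start", "orf_stop", "orf_length", "nearest_gene",
                  "subject_start", "subject_stop", "chimera_length",
                  "identity", "subject_features", "tm_helices"]


def build_candidate_report(scores: list[CandidateScore],
                           orfs: list[OrfRecord],
                           hits_by_orf: dict[str, list[ChimeraHit]],
                           tm_by_orf: dict[str, TMPrediction]) -> pd.DataFrame:
    """One row per retained ORF-hit pair, in the candidate-table layout."""
    orf_by_id = {o.orf_id: o for o in orfs}
    rows = []
    for sc in scores:
        if not sc.retained:
            continue
        o = orf_by_id[sc.orf_id]
        for h in hits_by_orf.get(sc.orf_id, []):
            rows.append({
                "orf_start": o.start, "orf_stop": o.stop,
                "orf_length": o.reported_length,
                "nearest_gene": sc.nearest_gene,
                "subject_start": h.subject_start,
                "subject_stop": h.subject_stop,
                "chimera_length": h.match_length,
                "identity": h.identity_pct,
                "subject_features": h.subject_feature,
                "tm_helices": tm_by_orf[sc.orf_id].helix_count,
            })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(["orf_start", "orf_stop", "subject_start"],
                            kind="mergesort").reset_index(drop=True)
    return df
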