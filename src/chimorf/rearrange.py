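"""Rearrangement breakpoint calling by unique k-mer anchoring and chaining.

The reference genome is indexed by k-mers that occur exactly once (counting
both strands); a comparator sequence (scaffold or read) is anchored through
this index and anchors are greedily chained under a colinearity contract.
Discontinuities between adjacent chains — orientation flips, long reference
jumps, unanchored query segments — become breakpoints.  When comparator
reads are available, each breakpoint is kept only if more than ``min_fraction``
(default 0.6, strict) of the reads spanning the junction are discordant.

Plant mitochondrial genomes carry large recombinationally active repeats;
restricting anchors to two-strand-unique k-mers avoids repeat-induced
phantom junctions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .coords import circ_point_dist
from .seqio import GenomeSequence, revcomp

logger = logging.getLogger(__name__)

BREAKPOINT_KINDS = ("inversion_junction", "translocation_junction",
                    "unanchored_junction")


@dataclass
class AnchorMatch:
    query_pos: int   # 1-based start of the k-mer on the query
    ref_pos: int     # 1-based start of the (forward-strand) k-mer on the reference
    k: int
    orientation: str  # "forward" | "reverse"


@dataclass
class AlignmentChain:
    anchors: list[AnchorMatch]
    orientation: str

    @property
    def k(self) -> int:
        return self.anchors[0].k

    @property
    def query_start(self) -> int:
        return self.anchors[0].query_pos

    @property
    def query_end(self) -> int:
        return self.anchors[-1].query_pos + self.k - 1

    @property
    def ref_lo(self) -> int:
        return min(a.ref_pos for a in self.anchors)

    @property
    def ref_hi(self) -> int:
        return max(a.ref_pos for a in self.anchors) + self.k - 1

    def ref_entry(self) -> int:
        """Reference coordinate aligned to the chain's first query base."""
        a = self.anchors[0]
        return a.ref_pos if self.orientation == "forward" else a.ref_pos + self.k - 1

    def ref_exit(self) -> int:
        """Reference coordinate aligned to the chain's last query base."""
        a = self.anchors[-1]
        return a.ref_pos + self.k - 1 if self.orientation == "forward" else a.ref_pos


@dataclass
class Breakpoint:
    ref_pos: int
    kind: str
    support_fraction: float
    comparator_id: str


class AnchorIndex:
    """Unique k-mer -> 1-based reference position, circular-aware."""

    def __init__(self, ref: GenomeSequence, k: int = 21):
        if k % 2 == 0 or not 11 <= k <= 31:
            raise ValueError("k must be odd and in [11, 31]")
        if ref.length < k:
            raise ValueError("reference shorter than k")
        self.ref = ref
        self.k = k
        seq = ref.seq + ref.seq[:k - 1] if ref.circular else ref.seq
        n_kmers = ref.length if ref.circular else ref.length - k + 1
        counts: Counter[str] = Counter(seq[i:i + k] for i in range(n_kmers))
        index: dict[str, int] = {}
        for i in range(n_kmers):
            kmer = seq[i:i + k]
            if counts[kmer] + counts.get(revcomp(kmer), 0) == 1:
                index[kmer] = i + 1
        self.index = index

    def __len__(self) -> int:
        return len(self.index)


def build_anchor_index(ref: GenomeSequence, k: int = 21) -> AnchorIndex:
    return AnchorIndex(ref, k)


def _ref_step(r1: int, r2: int, L: int, circular: bool) -> int:
    """Signed reference step r2 - r1, shortest way around on a circle."""
    d = r2 - r1
    if circular:
        d %= L
        if d > L // 2:
            d -= L
    return d


def chain_anchors(query: GenomeSequence, index: AnchorIndex,
                  max_gap: int = 500, min_anchors: int = 3) -> list[AlignmentChain]:
    """Greedy colinear chaining of unique-k-mer anchors.

    Successive anchors in a chain share orientation and advance monotonically
    on the reference, with gaps <= max_gap on both sequences.  Chains with
    fewer than ``min_anchors`` anchors are discarded.
    """
    k, L = index.k, index.ref.length
    circ = index.ref.circular
    idx = index.index
    q = query.seq
    chains: list[AlignmentChain] = []
    cur: list[AnchorMatch] = []
    cur_orient = ""

    def close() -> None:
        nonlocal cur
        if len(cur) >= min_anchors:
            chains.append(AlignmentChain(cur, cur_orient))
        cur = []

    for qpos0 in range(len(q) - k + 1):
        kmer = q[qpos0:qpos0 + k]
        if kmer in idx:
            rpos, orient = idx[kmer], "forward"
        else:
            rc = revcomp(kmer)
            if rc in idx:
                rpos, orient = idx[rc], "reverse"
            else:
                continue
        a = AnchorMatch(qpos0 + 1, rpos, k, orient)
        if cur:
            dq = a.query_pos - cur[-1].query_pos
            dr = _ref_step(cur[-1].ref_pos, a.ref_pos, L, circ)
            if orient == "reverse":
                dr = -dr
            ok = (orient == cur_orient and dq <= max_gap
                  and dr >= 1 and abs(dr - dq) <= max_gap)
            if not ok:
                close()
        if not cur:
            cur_orient = orient
        cur.append(a)
    close()
    return chains


def call_breakpoints(chains: list[AlignmentChain], comparator_id: str,
                     ref_length: int, max_gap: int = 500,
                     circular: bool = True) -> list[Breakpoint]:
    """Breakpoints at reference coordinates where adjacent chains disagree.

    For each discordant adjacent chain pair (in query order) both
    junction-flanking anchored reference coordinates are recorded; calls
    within k bp of each other are then merged keeping the lowest coordinate.
    Called from scaffolds there is no read evidence, so support is 1.0.
    """
    if not chains:
        return []
    k = chains[0].k
    raw: list[tuple[int, str]] = []
    ordered = sorted(chains, key=lambda c: c.query_start)
    for c1, c2 in zip(ordered, ordered[1:]):
        dq = c2.query_start - c1.query_end
        dr = _ref_step(c1.ref_exit(), c2.ref_entry(), ref_length, circular)
        if c1.orientation == "reverse":
            dr = -dr
        if c1.orientation != c2.orientation:
            kind = "inversion_junction"
        elif dr < 1 or abs(dr - dq) > max_gap:
            kind = "translocation_junction"
        elif dq > max_gap:
            kind = "unanchored_junction"
        else:
            continue
        raw.append((c1.ref_exit(), kind))
        raw.append((c2.ref_entry(), kind))
    raw.sort()
    merged: list[Breakpoint] = []
    for pos, kind in raw:
        if merged and circ_point_dist(pos, merged[-1].ref_pos, ref_length,
                                      circular) <= k:
            continue  # keep the lowest coordinate of a junction cluster
        merged.append(Breakpoint(pos, kind, 1.0, comparator_id))
    return merged


def filter_by_read_support(breakpoints: list[Breakpoint],
                           reads: list[GenomeSequence], index: AnchorIndex,
                           min_fraction: float = 0.6,
                           max_gap: int = 500) -> list[Breakpoint]:
    """Keep breakpoints whose read-level discordance exceeds ``min_fraction``.

    A read votes on a junction when its anchor chains reach it: a single
    chain covering the junction with >= k bp margin on both sides is
    concordant; a chain that stops near the junction while the read continues
    past it is discordant (split alignment).  Breakpoints with no informative
    reads are dropped with a warning.
    """
    L = index.ref.length
    circ = index.ref.circular
    k = index.k
    read_chains = [chain_anchors(r, index, max_gap, min_anchors=2) for r in reads]
    kept: list[Breakpoint] = []
    for bp in breakpoints:
        concordant = discordant = 0
        for read, chains in zip(reads, read_chains):
            spans = split = False
            for c in chains:
                # covered reference arc, walked in the chain's direction
                # (wrap-aware: a chain may cross the circular origin)
                arc_lo = c.ref_entry() if c.orientation == "forward" else c.ref_exit()
                arc_hi = c.ref_exit() if c.orientation == "forward" else c.ref_entry()
                span = (arc_hi - arc_lo) % L if circ else arc_hi - arc_lo
                d_lo = (bp.ref_pos - arc_lo) % L if circ else bp.ref_pos - arc_lo
                if k <= d_lo <= span - k:
                    spans = True
                    break
                # split evidence: the chain walks up to the junction from the
                # low-coordinate side and stops there while the read goes on.
                # Counting only the low-side approach makes each junction
                # collect votes from exactly one derived locus, so a 50/50
                # read mixture measures ~0.5 rather than double-counting.
                if c.orientation == "forward":
                    arc_hi_q = c.query_end
                    q_margin = read.length - c.query_end
                else:
                    arc_hi_q = c.query_start
                    q_margin = c.query_start - 1
                near = circ_point_dist(arc_hi, bp.ref_pos, L, circ) <= 2 * k
                reaches = d_lo >= k and d_lo <= span + 2 * k
                if near and reaches and q_margin >= k and span >= k:
                    split = True
            if spans:
                concordant += 1
            elif split:
                discordant += 1
        total = concordant + discordant
        if total == 0:
            logger.warning("breakpoint at %d (%s): no overlapping reads, dropped",
                           bp.ref_pos, bp.comparator_id)
            continue
        frac = discordant / total
        bp.support_fraction = frac
        if frac > min_fraction:
            kept.append(bp)
    return kept


def breakpoints_to_frame(breakpoints: list[Breakpoint]):
    import pandas as pd

    rows = [{"ref_pos": b.ref_pos, "kind": b.kind,
             "support_fraction": round(b.support_fraction, 4),
             "comparator_id": b.comparator_id} for b in breakpoints]
    return pd.DataFrame(rows, columns=["ref_pos", "kind", "support_fraction",
                                       "comparator_id"])
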