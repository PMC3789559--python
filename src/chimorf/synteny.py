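"""Shared gene clusters between two annotated (circular) genomes.

Both gene orders are first restricted to the genes they share; clusters are
maximal runs of >= min_size genes that are consecutive in both restricted
circular orders, in the same or reversed direction.  Strand agreement is
recorded as the cluster orientation but not required.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import GeneFeature


@dataclass
class GeneOrder:
    genome_id: str
    genes: list[tuple[str, str]]  # (name, strand) around the circle

    def names(self) -> list[str]:
        return [g for g, _ in self.genes]


def order_from_features(genome_id: str, features: list[GeneFeature],
                        include_types: tuple[str, ...] = ("protein", "rRNA"),
                        ) -> GeneOrder:
    """Gene order by start coordinate; duplicated names get _2, _3 suffixes."""
    feats = sorted((f for f in features if f.ftype in include_types),
                   key=lambda f: (f.start, f.name))
    seen: dict[str, int] = {}
    out = []
    for f in feats:
        n = seen.get(f.name, 0) + 1
        seen[f.name] = n
        out.append((f.name if n == 1 else f"{f.name}_{n}", f.strand))
    return GeneOrder(genome_id, out)


@dataclass
class SyntenyCluster:
    genes: list[str]
    orientation: str  # "same" | "reversed"

    @property
    def size(self) -> int:
        return len(self.genes)


def _restrict(order: GeneOrder, shared: set[str]) -> list[str]:
    return [g for g in order.names() if g in shared]


def shared_gene_clusters(a: GeneOrder, b: GeneOrder,
                         min_size: int = 2) -> list[SyntenyCluster]:
    """Maximal runs of genes consecutive in both circular orders.

    Output is ordered by position in order ``a``.  If the two restricted
    orders are identical circular sequences (up to direction), a single
    cluster containing every shared gene is returned, anchored at the first
    shared gene of ``a``.
    """
    if not a.genes or not b.genes:
        raise ValueError("empty gene order")
    shared = set(a.names()) & set(b.names())
    ra, rb = _restrict(a, shared), _restrict(b, shared)
    n = len(ra)
    if n < min_size:
        return []
    pos_b = {g: i for i, g in enumerate(rb)}
    # direction of each circular adjacency of ra within rb: +1, -1 or 0
    dirs = []
    for i in range(n):
        g, h = ra[i], ra[(i + 1) % n]
        fwd = pos_b[h] == (pos_b[g] + 1) % n
        rev = pos_b[h] == (pos_b[g] - 1) % n
        dirs.append(1 if fwd else (-1 if rev else 0))
    if n == 2:
        dirs = [1, 1] if dirs[0] != 0 else [0, 0]
    clusters: list[tuple[int, SyntenyCluster]] = []

    def emit(start: int, length: int, d: int) -> None:
        if length + 1 >= min_size:
            genes = [ra[(start + j) % n] for j in range(length + 1)]
            clusters.append((start, SyntenyCluster(
                genes, "same" if d > 0 else "reversed")))

    if all(d == dirs[0] for d in dirs):
        if dirs[0] != 0:
            # restricted orders are identical circular sequences
            emit(0, n - 1, dirs[0])
    else:
        i = 0
        # start scanning at a direction change so circular runs are whole
        while dirs[i - 1] == dirs[i]:
            i += 1
        for off in range(n):
            j = (i + off) % n
            if dirs[j] == 0:
                continue
            if off > 0 and dirs[j] == dirs[(j - 1) % n]:
                continue  # continuation of a run already emitted
            length = 1
            while dirs[(j + length) % n] == dirs[j] and length < n:
                length += 1
            emit(j, length, dirs[j])
    clusters.sort(key=lambda c: c[0])
    return [c for _, c in clusters]


def cluster_size_summary(clusters: list[SyntenyCluster]) -> dict[int, int]:
    out: dict[int, int] = {}
    for c in clusters:
        out[c.size] = out.get(c.size, 0) + 1
    return dict(sorted(out.items()))


def clusters_to_frame(clusters: list[SyntenyCluster]) -> pd.DataFrame:
    rows = [{"size": c.size, "orientation": c.orientation,
             "genes": "-".join(c.genes)} for c in clusters]
    return pd.DataFrame(rows, columns=["size", "orientation", "genes"])
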