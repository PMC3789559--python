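"""No-coverage-region detection in a comparator line's depth track.

A "no-coverage region" is a maximal run of consecutive reference positions
whose depth is approximately zero (depth <= max_depth, default 1) and whose
length strictly exceeds 1 kb.  Such regions mark sequence present in the
reference line but absent (or highly diverged) in the comparator — in a
CMS study, prime territory for sterility-associated chimeric ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coords import interval_length
from .seqio import CoverageTrack


@dataclass
class NoCoverageRegion:
    """1-based inclusive region; ``start > stop`` wraps the circular origin."""

    start: int
    stop: int
    length: int
    mean_depth: float


def find_no_coverage_regions(track: CoverageTrack, min_length: int = 1001,
                             max_depth: int = 1,
                             circular: bool = True) -> list[NoCoverageRegion]:
    """Maximal low-depth runs longer than ``min_length - 1`` bp.

    ``min_length`` = 1001 realises the strict ">1 kb" rule.  A run touching
    both ends of a circular track is merged across the origin.  Runs are
    maximal: extending any region by one base would include a position with
    depth > ``max_depth``.
    """
    d = track.depth
    n = d.size
    if n == 0:
        raise ValueError("empty coverage track")
    low = d <= max_depth
    if low.all():
        return [NoCoverageRegion(1, n, n, float(d.mean()))]
    # run boundaries on the linear array
    padded = np.concatenate([[False], low, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])      # 0-based run starts
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1    # 0-based inclusive ends
    runs = [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]
    if circular and len(runs) >= 2 and runs[0][0] == 1 and runs[-1][1] == n:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])  # wrapping region
    elif circular and len(runs) == 1 and runs[0][0] == 1 and runs[0][1] == n:
        pass  # cannot happen: low.all() handled above
    out = []
    for s, e in runs:
        length = interval_length(s, e, n)
        if length < min_length:
            continue
        if s <= e:
            mean = float(d[s - 1:e].mean())
        else:
            mean = float(np.concatenate([d[s - 1:], d[:e]]).mean())
        out.append(NoCoverageRegion(s, e, length, mean))
    out.sort(key=lambda r: r.start)
    return out


def region_summary(regions: list[NoCoverageRegion]) -> dict:
    """Count/total-bp/min/max summary, mirroring the per-line region tallies."""
    if not regions:
        return {"count": 0, "total_bp": 0, "min_length": 0, "max_length": 0}
    lengths = [r.length for r in regions]
    return {"count": len(regions), "total_bp": int(sum(lengths)),
            "min_length": int(min(lengths)), "max_length": int(max(lengths))}


def regions_to_frame(regions: list[NoCoverageRegion],
                     comparator_id: str = "") -> pd.DataFrame:
    rows = [{"comparator_id": comparator_id, "start": r.start, "stop": r.stop,
             "length": r.length, "mean_depth": round(r.mean_depth, 4)}
            for r in regions]
    return pd.DataFrame(rows, columns=["comparator_id", "start", "stop",
                                       "length", "mean_depth"])


def regions_to_bed(regions: list[NoCoverageRegion], seq_id: str,
                   genome_length: int) -> str:
    """BED (0-based half-open); wrapping regions emit two lines."""
    lines = []
    for i, r in enumerate(regions):
        if r.start <= r.stop:
            lines.append(f"{seq_id}\t{r.start - 1}\t{r.stop}\tncr{i + 1}")
        else:
            lines.append(f"{seq_id}\t{r.start - 1}\t{genome_length}\tncr{i + 1}a")
            lines.append(f"{seq_id}\t0\t{r.stop}\tncr{i + 1}b")
    return "\n".join(lines) + ("\n" if lines else "")
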