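"""Joint segmentation of the bivariate (LRR, folded BAF) marker signal.

Per chromosome, candidate breakpoints are found by recursive binary
splitting of a bivariate residual-sum-of-squares cost, then pruned to a
final set by exact dynamic programming with a per-breakpoint penalty.  The
BAF channel enters folded about 0.5 (|BAF - 0.5|) and restricted to markers
inside the sample's heterozygous BAF range, so that allelic imbalance is
informative while the homozygous 0/1 bands are ignored.

Breakpoints are between-marker indices; segments are half-open [s, e) in
marker-index space.  Physical coordinates are attached only when writing
segment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SPLIT_TOL = 1e-10


@dataclass
class SegmentationParams:
    max_depth: int = 6
    min_segment_markers: int = 10
    #: cost units per breakpoint; None -> 2 * sigma^2 * log(n) with sigma the
    #: robust LRR noise scale from median absolute successive differences
    penalty: float | None = None


@dataclass
class Segmentation:
    """Half-open marker-index segments partitioning each chromosome.

    ``start``/``end`` are global row indices into the (chrom, position)-sorted
    marker track; ``chrom_start`` is each chromosome's global offset.
    """

    chrom: list[str]
    start: np.ndarray
    end: np.ndarray
    chrom_offsets: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def sizes(self) -> np.ndarray:
        return self.end - self.start

    def validate(self, n_markers_per_chrom: dict[str, int]) -> None:
        covered: dict[str, int] = {}
        for c, s, e in zip(self.chrom, self.start, self.end):
            if e <= s:
                raise ValueError("empty segment")
            covered[c] = covered.get(c, 0) + (e - s)
        if covered != dict(n_markers_per_chrom):
            raise ValueError("segments do not partition the chromosomes")


class _Cost:
    """O(1) interval costs from prefix sums over both channels."""

    def __init__(self, lrr: np.ndarray, baf: np.ndarray, het_mask: np.ndarray):
        lrr = np.asarray(lrr, dtype=float)
        fb = np.where(het_mask, np.abs(np.asarray(baf, float) - 0.5), 0.0)
        self.c1 = np.concatenate([[0.0], np.cumsum(lrr)])
        self.c2 = np.concatenate([[0.0], np.cumsum(lrr * lrr)])
        self.b1 = np.concatenate([[0.0], np.cumsum(fb)])
        self.b2 = np.concatenate([[0.0], np.cumsum(fb * fb)])
        self.hn = np.concatenate([[0], np.cumsum(het_mask.astype(np.int64))])
        self.n = len(lrr)

    def cost(self, s, e):
        """RSS(LRR) + RSS(folded het BAF) on [s, e); vectorized in s/e."""
        s = np.asarray(s)
        e = np.asarray(e)
        m = e - s
        rss_l = (self.c2[e] - self.c2[s]) - (self.c1[e] - self.c1[s]) ** 2 / m
        h = self.hn[e] - self.hn[s]
        sb = self.b1[e] - self.b1[s]
        rss_b = np.where(h > 0, (self.b2[e] - self.b2[s]) - sb**2 / np.maximum(h, 1), 0.0)
        return np.maximum(rss_l, 0.0) + np.maximum(rss_b, 0.0)


def joint_cost(lrr, baf, het_mask, interval) -> float:
    """Bivariate RSS cost of one half-open marker interval."""
    s, e = interval
    if e <= s:
        raise ValueError("interval must be non-empty")
    return float(_Cost(lrr, baf, het_mask).cost(s, e))


def _split_gains(cost: _Cost, s: int, e: int, minseg: int) -> tuple[int, float]:
    ks = np.arange(s + minseg, e - minseg + 1)
    if ks.size == 0:
        return -1, 0.0
    parent = cost.cost(s, e)
    gains = parent - cost.cost(np.full_like(ks, s), ks) - cost.cost(ks, np.full_like(ks, e))
    i = int(np.argmax(gains))
    return int(ks[i]), float(gains[i])


def candidate_breakpoints(lrr, baf, het_mask, max_depth: int = 6,
                          min_segment_markers: int = 10) -> np.ndarray:
    """Recursive binary search for candidate breakpoints on one chromosome.

    Each interval is split at the cut maximizing the cost reduction; the
    recursion stops at ``max_depth`` or when no admissible split reduces the
    cost beyond tolerance.  Returns sorted between-marker indices.
    """
    n = len(lrr)
    if n < 2 * min_segment_markers:
        return np.array([], dtype=int)
    cost = _Cost(lrr, baf, het_mask)
    out: list[int] = []

    def recurse(s: int, e: int, depth: int) -> None:
        if depth >= max_depth or e - s < 2 * min_segment_markers:
            return
        k, gain = _split_gains(cost, s, e, min_segment_markers)
        if k < 0 or gain <= _SPLIT_TOL:
            return
        out.append(k)
        recurse(s, k, depth + 1)
        recurse(k, e, depth + 1)

    recurse(0, n, 0)
    return np.array(sorted(out), dtype=int)


def default_penalty(lrr: np.ndarray) -> float:
    """BIC-like per-breakpoint penalty 2 * sigma^2 * log(n).

    sigma is estimated robustly from the median absolute successive LRR
    difference, which is insensitive to the (few) true level shifts.
    """
    lrr = np.asarray(lrr, float)
    n = len(lrr)
    if n < 2:
        return 1.0
    sigma = 1.4826 * np.median(np.abs(np.diff(lrr))) / np.sqrt(2.0)
    return float(2.0 * max(sigma, 1e-6) ** 2 * np.log(max(n, 2)))


def prune_breakpoints(lrr, baf, het_mask, candidates, penalty: float | None = None
                      ) -> np.ndarray:
    """Exact DP selection of the candidate subset minimizing cost + penalty.

    Minimizes total joint cost plus ``penalty`` per retained breakpoint over
    all subsets of the candidates; ties are broken toward retaining more
    breakpoints (so a zero penalty keeps every candidate).
    """
    n = len(lrr)
    cand = np.asarray(sorted(candidates), dtype=int)
    if cand.size == 0:
        return cand
    if penalty is None:
        penalty = default_penalty(lrr)
    cost = _Cost(lrr, baf, het_mask)
    bounds = np.concatenate([[0], cand, [n]])
    m = len(bounds)
    best = np.full(m, np.inf)
    best_nbp = np.zeros(m, dtype=int)
    back = np.zeros(m, dtype=int)
    best[0] = 0.0
    for j in range(1, m):
        prev = np.arange(j)
        vals = best[prev] + cost.cost(bounds[prev], np.full(j, bounds[j]))
        vals = vals + np.where(prev > 0, penalty, 0.0)
        lead = np.min(vals)
        tied = np.flatnonzero(vals <= lead + _SPLIT_TOL)
        i = tied[np.argmax(best_nbp[tied] + (tied > 0))]
        best[j] = vals[i]
        best_nbp[j] = best_nbp[i] + (1 if i > 0 else 0)
        back[j] = i
    kept: list[int] = []
    j = m - 1
    while j > 0:
        i = back[j]
        if i > 0:
            kept.append(int(bounds[i]))
        j = i
    return np.array(sorted(kept), dtype=int)


def segment_chromosome(lrr, baf, het_mask, params: SegmentationParams | None = None
                       ) -> np.ndarray:
    """Final breakpoints for one chromosome (candidates then DP pruning)."""
    params = params or SegmentationParams()
    cand = candidate_breakpoints(lrr, baf, het_mask, params.max_depth,
                                 params.min_segment_markers)
    return prune_breakpoints(lrr, baf, het_mask, cand, params.penalty)


def segment_track(track: pd.DataFrame, het_mask: np.ndarray,
                  params: SegmentationParams | None = None) -> Segmentation:
    """Segment every chromosome of a (chrom, position)-sorted marker track."""
    params = params or SegmentationParams()
    het_mask = np.asarray(het_mask, bool)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    offsets: dict[str, int] = {}
    for chrom, idx in track.groupby("chrom", sort=False).indices.items():
        off = int(idx[0])
        offsets[chrom] = off
        lrr = track["lrr"].values[idx]
        baf = track["baf"].values[idx]
        bps = segment_chromosome(lrr, baf, het_mask[idx], params)
        edges = np.concatenate([[0], bps, [len(idx)]])
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(chrom)
            starts.append(off + int(s))
            ends.append(off + int(e))
    return Segmentation(chrom=chroms, start=np.array(starts, dtype=int),
                        end=np.array(ends, dtype=int), chrom_offsets=offsets)


def write_segments(seg: Segmentation, track: pd.DataFrame, path) -> None:
    """BED-like table: chrom start_bp end_bp n_markers lrr_median."""
    pos = track["position"].values
    lrr = track["lrr"].values
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_markers\tlrr_median\n")
        for c, s, e in zip(seg.chrom, seg.start, seg.end):
            fh.write(f"{c}\t{pos[s] - 1}\t{pos[e - 1]}\t{e - s}\t"
                     f"{np.median(lrr[s:e]):.4f}\n")
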