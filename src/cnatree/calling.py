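"""Tree-based calling of segment copy-number states from LRR and BAF.

Each segment is assigned one of four states -- Loss, Neutral, Gain or CNLOH
(copy-neutral loss of heterozygosity) -- by a decision tree with five test
nodes:

(1)  binomial test for loss of heterozygosity: is the segment's proportion
     of heterozygous markers significantly below the genome-wide rate?
(2)  parity of the copy number for non-LOH segments: a dip test of
     unimodality of the heterozygous BAF plus a one-sided rank-sum test of
     the folded BAF against the sample-wide heterozygous background; either
     significant => odd copy number (allelic imbalance), else even.
(3)  even segments: iterative one-sided Grubbs outlier test on the segment
     LRR medians flags copy gains (two or more extra copies); the survivors
     define the copy-neutral LRR reference.
(3') odd segments: an equivalence test (two one-sided rank-sum tests with a
     log2 margin) against the neutral reference identifies CNLOH; otherwise
     the LRR median above/below the neutral median gives Gain/Loss.
(3") LOH segments: one-sided rank-sum tests against the neutral reference
     resolve Loss vs Gain; neither significant => CNLOH.

Heterozygous markers are delimited by the two local minima of a genome-wide
kernel estimate of the BAF density that lie closest to 0 and to 1.  The
family-wise error rate over all segments and nodes is controlled at level
alpha by a weighted Bonferroni correction: segment i is tested at
alpha_i = (n_i / sum_j n_j) * alpha / M with M the maximum number of tests a
segment can receive, so that M * sum_i alpha_i = alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dip import DEFAULT_CALIBRATION, DipCalibration, dip_statistic
from .segment import Segmentation, SegmentationParams, segment_track
from .simulate import STATE_CNLOH, STATE_GAIN, STATE_LOSS, STATE_NEUTRAL

#: deterministic stream for internal subsampling (independent of user seeds)
_SUBSAMPLE_SEED = 1_220_571

FALLBACK_THRESHOLDS = (0.15, 0.85)


@dataclass(frozen=True)
class HetThresholds:
    """BAF range (low, high) within which markers are called heterozygous."""

    low: float
    high: float

    def __post_init__(self):
        if not 0.0 < self.low < self.high < 1.0:
            raise ValueError("need 0 < low < high < 1")

    def mask(self, baf: np.ndarray) -> np.ndarray:
        baf = np.asarray(baf, float)
        return (baf > self.low) & (baf < self.high)


@dataclass
class CallingParams:
    alpha: float = 0.05
    #: five decision nodes -> at most five tests can touch one segment
    max_tests_per_segment: int = 5
    #: log2-ratio equivalence margin of the CNLOH test at node (3')
    equivalence_margin: float = 0.1
    kernel_bandwidth_rule: str = "silverman"
    #: genome-wide heterozygosity rate; None -> estimated from the het mask
    genome_het_rate: float | None = None
    min_het_markers: int = 10
    min_segment_markers: int = 10
    #: subsample caps keep rank tests O(1) per segment on large genomes
    dip_sample_cap: int = 500
    background_cap: int = 2000
    dip_calibration: DipCalibration = field(default_factory=lambda: DEFAULT_CALIBRATION)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.equivalence_margin <= 0:
            raise ValueError("equivalence_margin must be positive")
        if self.max_tests_per_segment < 1:
            raise ValueError("max_tests_per_segment must be >= 1")


@dataclass
class SegmentCall:
    chrom: str
    start: int                  # global marker-row indices, half-open
    end: int
    state: str
    loh_flag: bool
    parity: str                 # "odd" | "even" | "n/a"
    lrr_median: float
    het_count: int
    marker_count: int
    adjusted_alpha: float
    low_confidence: bool = False


def het_thresholds(baf_values: np.ndarray, params: CallingParams | None = None
                   ) -> HetThresholds:
    """Heterozygous BAF range from the genome-wide BAF density.

    A Gaussian kernel density on [0, 1] typically shows three modes (AA, AB,
    BB); the interior local minima closest to 0 and to 1 bracket the
    heterozygous band.  Degenerate densities (no pair of interior minima,
    e.g. an all-homozygous sample) fall back to fixed thresholds with a
    warning.
    """
    params = params or CallingParams()
    baf = np.asarray(baf_values, float)
    baf = baf[np.isfinite(baf)]
    if baf.size < 100 or np.ptp(baf) < 1e-6:
        warnings.warn("too few BAF values for density thresholds; using fallback")
        return HetThresholds(*FALLBACK_THRESHOLDS)
    if baf.size > 20_000:  # deterministic thinning: evenly spaced order stats
        srt = np.sort(baf)
        baf = srt[np.linspace(0, baf.size - 1, 20_000).astype(int)]
    kde = stats.gaussian_kde(baf, bw_method=params.kernel_bandwidth_rule)
    grid = np.linspace(0.0, 1.0, 512)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])) + 1
    minima = grid[interior]
    minima = minima[(minima > 0.02) & (minima < 0.98)]
    if minima.size < 2 or minima.max() - minima.min() < 0.1:
        warnings.warn("BAF density lacks two interior minima; using fallback "
                      "heterozygous thresholds")
        return HetThresholds(*FALLBACK_THRESHOLDS)
    return HetThresholds(float(minima.min()), float(minima.max()))


def weighted_alpha(segment_sizes, alpha: float, max_tests_per_segment: int
                   ) -> np.ndarray:
    """Per-segment weighted-Bonferroni levels alpha_i = (n_i/sum n)*alpha/M.

    The weights sum to one, so M * sum_i alpha_i = alpha and the family-wise
    error rate over at most M tests per segment is controlled at alpha.
    """
    sizes = np.asarray(segment_sizes, dtype=float)
    if sizes.size == 0:
        return sizes
    if np.any(sizes <= 0):
        raise ValueError("segment sizes must be positive")
    if max_tests_per_segment < 1:
        raise ValueError("max_tests_per_segment must be >= 1")
    return sizes / sizes.sum() * alpha / max_tests_per_segment


def test_loh(het_count: int, marker_count: int, genome_het_rate: float,
             level: float) -> bool:
    """Node (1): one-sided lower binomial tail for loss of heterozygosity."""
    if marker_count <= 0:
        raise ValueError("marker_count must be positive")
    p = float(stats.binom.cdf(het_count, marker_count, genome_het_rate))
    return p <= level


def test_parity(seg_het_baf: np.ndarray, background_het_baf: np.ndarray,
                level: float, params: CallingParams | None = None) -> str:
    """Node (2): dip test + one-sided folded-BAF rank-sum; either => odd.

    Each component runs at level/2.  Segments with fewer heterozygous
    markers than the minimum are reported even (callers flag low confidence).
    """
    params = params or CallingParams()
    x = np.asarray(seg_het_baf, float)
    if x.size < params.min_het_markers:
        return "even"
    if x.size > params.dip_sample_cap:  # evenly spaced order statistics
        srt = np.sort(x)
        xd = srt[np.linspace(0, x.size - 1, params.dip_sample_cap).astype(int)]
    else:
        xd = x
    if dip_statistic(xd) > params.dip_calibration.critical(xd.size, level / 2.0):
        return "odd"
    bg = np.asarray(background_het_baf, float)
    if bg.size:
        p = stats.mannwhitneyu(np.abs(x - 0.5), np.abs(bg - 0.5),
                               alternative="greater", method="asymptotic").pvalue
        if p <= level / 2.0:
            return "odd"
    return "even"


def _grubbs_critical(n: int, level: float) -> float:
    t = stats.t.ppf(1.0 - level / n, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def detect_even_gains(lrr_medians, levels, sizes=None, noise_scale=None) -> set[int]:
    """Node (3): iterative one-sided (maximum) Grubbs test on LRR medians.

    Flags extreme high medians as copy gains, removing one at a time until
    the largest remaining value is not significant or fewer than three
    segments remain; each round is tested at the candidate segment's own
    adjusted level.  Returns flagged indices; survivors form the neutral
    reference.

    When ``sizes`` (marker counts) and ``noise_scale`` (per-marker LRR sd)
    are given, medians are standardized by their sampling scale
    1.2533 * sd / sqrt(n_i) first: the median of a small segment is much
    noisier than that of a whole chromosome, and Grubbs' equal-variance
    normal assumption only holds on the standardized values.
    """
    med = np.asarray(lrr_medians, dtype=float)
    if sizes is not None and noise_scale is not None and noise_scale > 0:
        se = 1.2533 * noise_scale / np.sqrt(np.asarray(sizes, dtype=float))
        med = med / se
    levels = np.broadcast_to(np.asarray(levels, dtype=float), med.shape)
    active = list(range(med.size))
    flagged: set[int] = set()
    while len(active) >= 3:
        vals = med[active]
        i_loc = int(np.argmax(vals))
        sd = vals.std(ddof=1)
        if sd <= 0:
            break
        g = (vals[i_loc] - vals.mean()) / sd
        cand = active[i_loc]
        if g > _grubbs_critical(len(active), levels[cand]):
            flagged.add(cand)
            active.pop(i_loc)
        else:
            break
    return flagged


def classify_odd(seg_lrr: np.ndarray, neutral_lrr: np.ndarray,
                 equivalence_margin: float, level: float) -> str:
    """Node (3'): TOST equivalence => CNLOH, else Loss/Gain by median."""
    if len(neutral_lrr) == 0:
        raise ValueError("empty copy-neutral reference")
    seg = np.asarray(seg_lrr, float)
    ref = np.asarray(neutral_lrr, float)
    p_hi = stats.mannwhitneyu(seg, ref + equivalence_margin,
                              alternative="less", method="asymptotic").pvalue
    p_lo = stats.mannwhitneyu(seg, ref - equivalence_margin,
                              alternative="greater", method="asymptotic").pvalue
    if p_hi <= level and p_lo <= level:
        return STATE_CNLOH
    diff = np.median(seg) - np.median(ref)
    if diff > 0:
        return STATE_GAIN
    if diff < 0:
        return STATE_LOSS
    return STATE_CNLOH


def resolve_loh(seg_lrr: np.ndarray, neutral_lrr: np.ndarray, level: float) -> str:
    """Node (3"): one-sided rank-sum tests split LOH into Loss/Gain/CNLOH."""
    if len(neutral_lrr) == 0:
        raise ValueError("empty copy-neutral reference")
    seg = np.asarray(seg_lrr, float)
    ref = np.asarray(neutral_lrr, float)
    if stats.mannwhitneyu(seg, ref, alternative="less",
                          method="asymptotic").pvalue <= level:
        return STATE_LOSS
    if stats.mannwhitneyu(seg, ref, alternative="greater",
                          method="asymptotic").pvalue <= level:
        return STATE_GAIN
    return STATE_CNLOH


def _thin(values: np.ndarray, cap: int) -> np.ndarray:
    if values.size <= cap:
        return values
    idx = np.linspace(0, values.size - 1, cap).astype(int)
    return np.sort(values)[idx]


def call_sample(track: pd.DataFrame, segmentation: Segmentation,
                params: CallingParams | None = None,
                thresholds: HetThresholds | None = None) -> list[SegmentCall]:
    """Run the five-node decision tree over every segment of one sample."""
    params = params or CallingParams()
    baf = track["baf"].values
    lrr = track["lrr"].values
    thresholds = thresholds or het_thresholds(baf, params)
    het = thresholds.mask(baf)
    rate = params.genome_het_rate if params.genome_het_rate is not None else float(het.mean())
    rate = min(max(rate, 1e-6), 1.0 - 1e-6)

    n_seg = len(segmentation)
    sizes = segmentation.sizes
    alphas = weighted_alpha(sizes, params.alpha, params.max_tests_per_segment)

    seg_het_counts = np.array([int(het[s:e].sum())
                               for s, e in zip(segmentation.start, segmentation.end)])
    medians = np.array([float(np.median(lrr[s:e]))
                        for s, e in zip(segmentation.start, segmentation.end)])

    degenerate = sizes < params.min_segment_markers
    loh = np.zeros(n_seg, dtype=bool)
    for i in range(n_seg):
        if degenerate[i]:
            continue
        loh[i] = test_loh(seg_het_counts[i], int(sizes[i]), rate, alphas[i])

    parity = np.array(["n/a"] * n_seg, dtype=object)
    all_het_baf = baf[het]
    for i in range(n_seg):
        if degenerate[i] or loh[i]:
            continue
        s, e = segmentation.start[i], segmentation.end[i]
        seg_het_baf = baf[s:e][het[s:e]]
        bg_mask = het.copy()
        bg_mask[s:e] = False
        bg = _thin(baf[bg_mask], params.background_cap)
        parity[i] = test_parity(seg_het_baf, bg, alphas[i], params)

    states = np.array([STATE_NEUTRAL] * n_seg, dtype=object)
    low_conf = degenerate.copy()

    even_idx = [i for i in range(n_seg)
                if not degenerate[i] and not loh[i] and parity[i] == "even"]
    if len(even_idx) >= 3:
        sigma = 1.4826 * float(np.median(np.abs(np.diff(lrr)))) / np.sqrt(2.0)
        gains = detect_even_gains(medians[even_idx], alphas[even_idx],
                                  sizes[even_idx], sigma)
        gain_idx = {even_idx[j] for j in gains}
    else:
        gain_idx = set()
    for i in gain_idx:
        states[i] = STATE_GAIN
    neutral_idx = [i for i in even_idx if i not in gain_idx]
    if not neutral_idx:
        raise RuntimeError("no copy-neutral reference segments; calling aborted")
    neutral_lrr = _thin(np.concatenate(
        [lrr[segmentation.start[i]:segmentation.end[i]] for i in neutral_idx]),
        params.background_cap)

    for i in range(n_seg):
        if degenerate[i]:
            continue
        s, e = segmentation.start[i], segmentation.end[i]
        if loh[i]:
            states[i] = resolve_loh(lrr[s:e], neutral_lrr, alphas[i])
        elif parity[i] == "odd":
            states[i] = classify_odd(lrr[s:e], neutral_lrr,
                                     params.equivalence_margin, alphas[i])

    calls = []
    for i in range(n_seg):
        s, e = int(segmentation.start[i]), int(segmentation.end[i])
        n_het = int(seg_het_counts[i])
        calls.append(SegmentCall(
            chrom=segmentation.chrom[i], start=s, end=e, state=str(states[i]),
            loh_flag=bool(loh[i]), parity=str(parity[i]),
            lrr_median=float(medians[i]), het_count=n_het,
            marker_count=int(sizes[i]), adjusted_alpha=float(alphas[i]),
            low_confidence=bool(low_conf[i] or
                                (parity[i] == "even" and not loh[i]
                                 and n_het < params.min_het_markers)),
        ))
    return calls


@dataclass
class PipelineResult:
    thresholds: HetThresholds
    segmentation: Segmentation
    calls: list[SegmentCall]


def call_track(track: pd.DataFrame, params: CallingParams | None = None,
               seg_params: SegmentationParams | None = None) -> PipelineResult:
    """Full per-sample pipeline: thresholds -> segmentation -> calling."""
    params = params or CallingParams()
    thresholds = het_thresholds(track["baf"].values, params)
    het = thresholds.mask(track["baf"].values)
    segmentation = segment_track(track, het, seg_params)
    calls = call_sample(track, segmentation, params, thresholds)
    return PipelineResult(thresholds, segmentation, calls)


def marker_states(calls: list[SegmentCall], n_markers: int) -> np.ndarray:
    """Expand segment calls to a per-marker state array."""
    out = np.full(n_markers, STATE_NEUTRAL, dtype=object)
    for c in calls:
        out[c.start:c.end] = c.state
    return out


def write_calls(calls: list[SegmentCall], track: pd.DataFrame, path) -> None:
    """BED-like call table with the per-node audit columns."""
    pos = track["position"].values
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstate\tlrr_median\tn_markers\thet_frac"
                 "\tadjusted_alpha\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{pos[c.start] - 1}\t{pos[c.end - 1]}\t{c.state}\t"
                     f"{c.lrr_median:.4f}\t{c.marker_count}\t"
                     f"{c.het_count / c.marker_count:.4f}\t{c.adjusted_alpha:.3e}\n")
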