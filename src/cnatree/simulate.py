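"""Synthetic impure-tumor SNP-array data with known copy-number truth.

The generator emulates the statistical structure the calling procedure
assumes: per-marker log R ratio (LRR, log2 total-intensity ratio, ~0 at two
copies) and B allele frequency (BAF, ~0/0.5/1 at AA/AB/BB germline
genotypes), for a tumor of known segment states diluted by normal cells.

For a marker with ``c`` total tumor copies, ``b`` of them carrying the B
allele, in a sample of tumor purity ``p`` (germline carries 2 copies, ``g``
of them B):

    LRR = log2((p*c + (1-p)*2) / 2)
    BAF = (p*b + (1-p)*g) / (p*c + (1-p)*2)

Gaussian marker noise is added on both channels; BAF is clipped to [0, 1]
and homozygous markers get reduced noise to mimic the tight 0/1 bands of
real arrays.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STATE_LOSS = "Loss"
STATE_NEUTRAL = "Neutral"
STATE_GAIN = "Gain"
STATE_CNLOH = "CNLOH"

#: tight BAF bands of homozygous markers relative to heterozygous noise
HOM_BAF_NOISE_FRACTION = 0.25


@dataclass(frozen=True)
class TruthSegment:
    """A ground-truth tumor segment in marker-index space (half-open)."""

    chrom: str
    start_idx: int
    end_idx: int
    total_copies: int
    b_copies: int

    def __post_init__(self):
        if self.end_idx <= self.start_idx:
            raise ValueError("empty truth segment")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if not 0 <= self.b_copies <= max(self.total_copies, 0):
            raise ValueError("b_copies must lie in [0, total_copies]")

    @property
    def state(self) -> str:
        """CNA state implied at a normally heterozygous locus."""
        if self.total_copies < 2:
            return STATE_LOSS
        if self.total_copies > 2:
            return STATE_GAIN
        if self.b_copies in (0, 2):
            return STATE_CNLOH
        return STATE_NEUTRAL


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults reflect a desk-scale genome (22 autosomes, 1000 markers each)
    of an exome SNP array, a mid-range tumor purity of 0.4, a genome-wide
    heterozygosity rate of 0.3 and typical Illumina-like marker noise
    (LRR sd 0.15 log2 units, BAF sd 0.04).
    """

    n_chromosomes: int = 22
    markers_per_chromosome: int = 1000
    purity: float = 0.4
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.04
    genome_het_rate: float = 0.3
    truth_segments: Sequence[TruthSegment] = field(default_factory=tuple)
    seed: int = 0
    marker_spacing_bp: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if not 0.0 < self.genome_het_rate < 1.0:
            raise ValueError("genome_het_rate must be in (0, 1)")
        if self.lrr_noise_sd <= 0 or self.baf_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("genome dimensions must be positive")
        self.truth_segments = tuple(
            sorted(self.truth_segments, key=lambda s: (s.chrom, s.start_idx))
        )
        by_chrom: dict[str, list[TruthSegment]] = {}
        for seg in self.truth_segments:
            if seg.end_idx > self.markers_per_chromosome:
                raise ValueError(f"truth segment beyond chromosome: {seg}")
            sibs = by_chrom.setdefault(seg.chrom, [])
            if sibs and seg.start_idx < sibs[-1].end_idx:
                raise ValueError(f"overlapping truth segments on {seg.chrom}")
            sibs.append(seg)

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]


def expected_lrr(total_copies: int, purity: float) -> float:
    """Noise-free LRR of a tumor segment diluted by normal cells."""
    c = np.asarray(total_copies)
    if np.any(c < 0):
        raise ValueError("total_copies must be >= 0")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    out = np.log2((purity * c + (1.0 - purity) * 2.0) / 2.0)
    return float(out) if np.isscalar(total_copies) else out


_GENOTYPE_B_COPIES = {"AA": 0, "AB": 1, "BB": 2}


def expected_baf(total_copies: int, b_copies: int, purity: float,
                 germline_genotype: str = "AB") -> float:
    """Noise-free BAF of a diluted tumor segment at a given germline genotype."""
    if germline_genotype not in _GENOTYPE_B_COPIES:
        raise ValueError(f"unknown genotype {germline_genotype!r}")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    c = np.asarray(total_copies)
    b = np.asarray(b_copies)
    if np.any(c < 0) or np.any(b < 0) or np.any(b > c):
        raise ValueError("need 0 <= b_copies <= total_copies")
    g = _GENOTYPE_B_COPIES[germline_genotype]
    denom = purity * c + (1.0 - purity) * 2.0
    out = (purity * b + (1.0 - purity) * g) / denom
    return float(out) if np.isscalar(total_copies) else out


def simulate_sample(config: SimulationConfig) -> tuple[pd.DataFrame, list[TruthSegment]]:
    """Draw one sample's marker track.

    Returns a marker table sorted by (chromosome, position) with columns
    ``chrom, position, lrr, baf`` plus the germline-truth helper column
    ``germline`` (B-allele count 0/1/2, not part of the on-disk format), and
    the validated list of truth segments.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.markers_per_chromosome
    p = config.purity
    frames = []
    truth_by_chrom: dict[str, list[TruthSegment]] = {}
    for seg in config.truth_segments:
        truth_by_chrom.setdefault(seg.chrom, []).append(seg)

    for chrom in config.chromosomes:
        g = np.where(
            rng.random(n) < config.genome_het_rate,
            1,
            np.where(rng.random(n) < 0.5, 0, 2),
        )
        total = np.full(n, 2)
        b = g.copy()
        for seg in truth_by_chrom.get(chrom, []):
            sl = slice(seg.start_idx, seg.end_idx)
            total[sl] = seg.total_copies
            seg_b = np.where(g[sl] == 0, 0,
                             np.where(g[sl] == 2, seg.total_copies, seg.b_copies))
            # at heterozygous loci either parental haplotype may be affected
            flip = (g[sl] == 1) & (rng.random(seg.end_idx - seg.start_idx) < 0.5)
            seg_b = np.where(flip, seg.total_copies - seg_b, seg_b)
            b[sl] = seg_b

        denom = p * total + (1.0 - p) * 2.0
        lrr = np.log2(denom / 2.0) + rng.normal(0.0, config.lrr_noise_sd, n)
        baf0 = (p * b + (1.0 - p) * g) / denom
        sd = np.where(g == 1, config.baf_noise_sd,
                      config.baf_noise_sd * HOM_BAF_NOISE_FRACTION)
        baf = np.clip(baf0 + rng.normal(0.0, 1.0, n) * sd, 0.0, 1.0)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "position": config.marker_spacing_bp * (np.arange(n) + 1),
            "lrr": lrr,
            "baf": baf,
            "germline": g,
        }))
    track = pd.concat(frames, ignore_index=True)
    return track, list(config.truth_segments)


def truth_marker_states(config: SimulationConfig) -> np.ndarray:
    """Per-marker truth state array aligned with ``simulate_sample`` output."""
    n = config.markers_per_chromosome
    states = np.full(config.n_chromosomes * n, STATE_NEUTRAL, dtype=object)
    offsets = {c: i * n for i, c in enumerate(config.chromosomes)}
    for seg in config.truth_segments:
        off = offsets[seg.chrom]
        states[off + seg.start_idx:off + seg.end_idx] = seg.state
    return states


def make_cytoband_map(n_chromosomes: int, bands_per_chromosome: int,
                      chrom_length: int) -> pd.DataFrame:
    """Equal-width cytoband annotation tiling a synthetic genome.

    Bands are named p1..pK then q1..qK the way real maps order them from
    pter to qter; coordinates are 0-based half-open as in UCSC files.
    """
    if n_chromosomes < 1 or bands_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    n_p = bands_per_chromosome // 2
    rows = []
    edges = np.round(np.linspace(0, chrom_length, bands_per_chromosome + 1)).astype(int)
    for ci in range(1, n_chromosomes + 1):
        for bi in range(bands_per_chromosome):
            name = f"p{bi + 1}" if bi < n_p else f"q{bi - n_p + 1}"
            rows.append((f"chr{ci}", int(edges[bi]), int(edges[bi + 1]), name, "gneg"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])


def write_track(track: pd.DataFrame, path) -> None:
    """Write a marker track as tab-separated text (chrom position lrr baf)."""
    track[["chrom", "position", "lrr", "baf"]].to_csv(path, sep="\t", index=False)


def read_track(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "position", "lrr", "baf"} - set(track.columns)
    if missing:
        raise ValueError(f"track file lacks columns: {sorted(missing)}")
    return track.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)


def write_truth(truth: Iterable[TruthSegment], config: SimulationConfig, path) -> None:
    """Write truth segments BED-like: chrom start end total_copies b_copies state."""
    sp = config.marker_spacing_bp
    with open(path, "w") as fh:
        for seg in truth:
            start_bp = sp * seg.start_idx
            end_bp = sp * seg.end_idx
            fh.write(f"{seg.chrom}\t{start_bp}\t{end_bp}\t"
                     f"{seg.total_copies}\t{seg.b_copies}\t{seg.state}\n")


# ---------------------------------------------------------------------------
# cohort-level generators (cytoband-state matrices, no marker level)
# ---------------------------------------------------------------------------

def simulate_band_counts(class_probs: np.ndarray, n_bands: int = 768,
                         n_samples: int = 42, weights: np.ndarray | None = None,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-cytoband (loss, neutral, gain) sample counts from a class mixture.

    Each band is assigned to one of the latent propensity classes (equal
    weights by default) and its counts drawn from the trinomial with that
    class's probabilities.  Returns (counts [n_bands x 3], class labels).
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("class_probs must be (n_classes, 3)")
    k = probs.shape[0]
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    classes = rng.choice(k, size=n_bands, p=w / w.sum())
    counts = np.vstack([rng.multinomial(n_samples, probs[c]) for c in classes])
    return counts, classes


DEFAULT_CLUSTER_SIZES = (10, 20, 12)
DEFAULT_BAND_GROUPS = {"1p": 25, "3p": 25, "7p": 25}
#: cluster -> {band group: aberrant state}; emulates a cohort in which one
#: cluster shows 1p loss with 7p gain, one 1p+3p loss without 7p gain, and
#: one is mostly quiet
DEFAULT_CLUSTER_PROFILES = (
    {"1p": STATE_LOSS, "7p": STATE_GAIN},
    {"1p": STATE_LOSS, "3p": STATE_LOSS},
    {},
)


def simulate_state_cohort(cluster_sizes=DEFAULT_CLUSTER_SIZES,
                          band_groups=None, cluster_profiles=DEFAULT_CLUSTER_PROFILES,
                          n_noise_bands: int = 65, p_signal: float = 0.8,
                          p_background_aberration: float = 0.05,
                          seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Samples-by-cytobands categorical state matrix with latent clusters.

    Cluster-defining (group, state) pairs occur with probability ``p_signal``
    (remaining mass mostly Neutral); all other bands are Neutral except for
    sporadic aberrations at ``p_background_aberration`` per state.  Returns
    the matrix (values in {Loss, Neutral, Gain}) and true cluster labels.
    """
    band_groups = dict(DEFAULT_BAND_GROUPS if band_groups is None else band_groups)
    rng = np.random.default_rng(seed)
    bands = []
    group_of = []
    for gname, cnt in band_groups.items():
        for i in range(cnt):
            bands.append(f"{gname}.{i + 1}")
            group_of.append(gname)
    for i in range(n_noise_bands):
        bands.append(f"noise.{i + 1}")
        group_of.append(None)

    states = [STATE_LOSS, STATE_NEUTRAL, STATE_GAIN]
    labels = np.repeat(np.arange(len(cluster_sizes)), cluster_sizes)
    rows = []
    for lab in labels:
        profile = cluster_profiles[lab]
        row = []
        for grp in group_of:
            target = profile.get(grp) if grp is not None else None
            if target is None:
                pn = 1.0 - 2.0 * p_background_aberration
                p = {STATE_LOSS: p_background_aberration, STATE_NEUTRAL: pn,
                     STATE_GAIN: p_background_aberration}
            else:
                rest = 1.0 - p_signal
                p = {s: rest * 0.25 for s in states}
                p[STATE_NEUTRAL] = rest * 0.5
                p[target] = p[target] + p_signal
            row.append(rng.choice(states, p=[p[s] / sum(p.values()) for s in states]))
        rows.append(row)
    matrix = pd.DataFrame(rows, columns=bands,
                          index=[f"S{i + 1}" for i in range(len(labels))])
    return matrix, labels
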