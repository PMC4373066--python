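"""Cytoband annotation and majority-vote summarization of segment calls.

Cytobands (Giemsa bands, e.g. 1p36.33) are the summarization unit of the
cohort analyses: each band receives the state covering the plurality of its
markers, with each marker inheriting its segment's call.  Votes are weighted
by marker count rather than physical span because the signal lives at the
markers and exome arrays are physically very uneven.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calling import SegmentCall, marker_states
from .simulate import STATE_NEUTRAL

STATE_MISSING = "Missing"

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def read_cytoband_file(path) -> pd.DataFrame:
    """Parse a UCSC ``cytoBand.txt`` file, restricted to autosomes.

    Expects five tab-separated columns (chrom, start, end, name, stain) with
    0-based half-open coordinates.  Raises on malformed lines (with the line
    number) and on overlapping bands.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"line {lineno}: expected 5 tab-separated "
                                 f"columns, got {len(parts)}")
            chrom, start, end, name, stain = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as err:
                raise ValueError(f"line {lineno}: non-integer coordinates") from err
            if end_i <= start_i:
                raise ValueError(f"line {lineno}: empty or inverted band")
            rows.append((chrom, start_i, end_i, name, stain))
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    if bands.empty:
        warnings.warn("cytoband file contains no usable rows")
        return bands
    bands = bands[bands["chrom"].isin(AUTOSOMES)].reset_index(drop=True)
    if bands.empty:
        warnings.warn("cytoband file contains no autosomal rows")
        return bands
    for chrom, grp in bands.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
            raise ValueError(f"overlapping cytobands on {chrom}")
        if grp["name"].duplicated().any():
            raise ValueError(f"duplicate band names on {chrom}")
    return bands.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def band_ids(cytoband_map: pd.DataFrame) -> pd.Index:
    return pd.Index(cytoband_map["chrom"].astype(str) + ":" + cytoband_map["name"])


def majority_vote(calls: list[SegmentCall], track: pd.DataFrame,
                  cytoband_map: pd.DataFrame) -> pd.Series:
    """Per-cytoband state of one sample by marker-count plurality.

    Each marker inherits its segment's state; a band takes the state held by
    the plurality of its markers.  Exact ties resolve to Neutral
    (conservative) and bands without markers are Missing.
    """
    states = marker_states(calls, len(track))
    chrom_arr = track["chrom"].values
    pos = track["position"].values
    out = {}
    for (chrom,), grp in cytoband_map.groupby(["chrom"], sort=False):
        in_chrom = np.flatnonzero(chrom_arr == chrom)
        cpos = pos[in_chrom]
        for _, band in grp.iterrows():
            bid = f"{band.chrom}:{band['name']}"
            lo = np.searchsorted(cpos, band.start + 1, side="left")
            hi = np.searchsorted(cpos, band.end, side="right")
            if hi <= lo:
                out[bid] = STATE_MISSING
                continue
            vals, counts = np.unique(states[in_chrom[lo:hi]], return_counts=True)
            top = counts.max()
            winners = vals[counts == top]
            out[bid] = winners[0] if len(winners) == 1 else STATE_NEUTRAL
    ids = band_ids(cytoband_map)
    return pd.Series(out).reindex(ids)


def build_matrix(per_sample_states: dict[str, pd.Series]) -> pd.DataFrame:
    """Stack per-sample cytoband state vectors into a samples x bands matrix."""
    if not per_sample_states:
        raise ValueError("no samples")
    items = list(per_sample_states.items())
    index0 = items[0][1].index
    for name, series in items[1:]:
        if not series.index.equals(index0):
            raise ValueError(f"sample {name!r} uses a different cytoband map")
    return pd.DataFrame({name: s for name, s in items}).T


def state_frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-band state frequencies (rows sum to 1), basis of frequency plots."""
    freq = matrix.apply(lambda col: col.value_counts(normalize=True), axis=0)
    return freq.fillna(0.0).T


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Tab-separated samples x bands matrix with the {L,N,G,C,.} alphabet."""
    short = {"Loss": "L", "Neutral": "N", "Gain": "G", "CNLOH": "C",
             STATE_MISSING: "."}
    matrix.replace(short).to_csv(path, sep="\t")
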