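"""Binary-coverage and signal metagenes over scaled regions with flanks.

Each region is rescaled to a fixed number of body bins; flanks are
unscaled, fixed-width bins on either side.  Minus-strand regions are
reversed so bins always run 5'->3'.  Two modes:

* binary x 100 — a bin scores 1 when >= 50% of its bases overlap the
  investigated element set, else 0; column means x 100 give "% of
  regions covered at this position".
* signal — mean bedGraph signal per bin (the computeMatrix
  scale-regions behaviour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (GenomeLayout, GenomicInterval, SignalTrack,
                   merge_intervals, shuffle_intervals)

logger = logging.getLogger("tewave")


@dataclass
class MetageneMatrix:
    """Regions x bins matrix plus the bin layout that produced it."""

    values: np.ndarray  # regions x (flank + body + flank) floats
    region_ids: list[str]
    n_body_bins: int
    flank_bp: int
    flank_bins: int
    mode: str  # "binary" or "signal"

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.flank_bins

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0) if len(self.values) else \
            np.zeros(self.n_bins)

    def to_frame(self) -> pd.DataFrame:
        cols = ([f"up{i}" for i in range(self.flank_bins)]
                + [f"body{i}" for i in range(self.n_body_bins)]
                + [f"down{i}" for i in range(self.flank_bins)])
        return pd.DataFrame(self.values, index=self.region_ids, columns=cols)


def _bin_edges(region: GenomicInterval, n_body_bins: int, flank_bp: int,
               flank_bins: int) -> np.ndarray:
    """Reference-orientation bin edges: left flank, body, right flank.

    Body bins are integer-bp with the remainder spread over the last
    bins (in reference orientation for + regions; the caller reverses
    minus-strand vectors afterwards, which puts the remainder on the
    last 5'->3' bins either way up to reflection).  Flank bins have
    fixed width ``flank_bp / flank_bins``.
    """
    L = region.length
    base, rem = divmod(L, n_body_bins)
    if base == 0:
        logger.info("region %s shorter than %d bins; using >=1-bp bins",
                    region, n_body_bins)
        widths = np.zeros(n_body_bins, dtype=np.int64)
        widths[:L] = 1
    else:
        widths = np.full(n_body_bins, base, dtype=np.int64)
        if rem:
            widths[-rem:] += 1
    body = region.start + np.concatenate([[0], np.cumsum(widths)])
    if flank_bins == 0:
        return body
    fw, frem = divmod(flank_bp, flank_bins)
    fwidths = np.full(flank_bins, fw, dtype=np.int64)
    if frem:
        fwidths[-frem:] += 1
    left = region.start - np.cumsum(fwidths[::-1])[::-1]
    right = region.end + np.cumsum(fwidths)
    return np.concatenate([left, body, right])


def _coverage_cum(elements: Sequence[GenomicInterval]):
    """Per-chrom merged coverage as a unit-value SignalTrack."""
    merged = merge_intervals(elements)
    return SignalTrack([(iv, 1.0) for iv in merged])


def _region_bins(regions, n_body_bins, flank_bp, flank_bins, per_bin_fn):
    rows = []
    ids = []
    for i, region in enumerate(regions):
        edges = _bin_edges(region, n_body_bins, flank_bp, flank_bins)
        row = per_bin_fn(region.chrom, edges)
        if region.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(region.name or f"region{i}")
    return np.array(rows) if rows else \
        np.zeros((0, n_body_bins + 2 * flank_bins)), ids


def binary_metagene(regions: Sequence[GenomicInterval],
                    elements: Sequence[GenomicInterval],
                    n_body_bins: int = 100, flank_bp: int = 5000,
                    flank_bins: int = 50) -> MetageneMatrix:
    """Percent-covered metagene: bin = 100 when >= 50% of its bases
    overlap the element set, else 0."""
    cov = _coverage_cum(elements) if elements else SignalTrack()

    def per_bin(chrom, edges):
        clipped = np.clip(edges, 0, None)
        covered = np.diff(cov.integral_at(chrom, clipped))
        widths = np.diff(edges)  # nominal widths, off-genome bases count
        out = np.zeros(len(widths))
        nz = widths > 0
        out[nz] = (covered[nz] >= 0.5 * widths[nz]) * 100.0
        return out

    values, ids = _region_bins(regions, n_body_bins, flank_bp, flank_bins,
                               per_bin)
    return MetageneMatrix(values, ids, n_body_bins, flank_bp, flank_bins,
                          "binary")


def signal_metagene(regions: Sequence[GenomicInterval], signal: SignalTrack,
                    n_body_bins: int = 100, flank_bp: int = 5000,
                    flank_bins: int = 50) -> MetageneMatrix:
    """Mean-signal metagene (scale-regions): mean value per bin base."""

    def per_bin(chrom, edges):
        clipped = np.clip(edges, 0, None)
        integ = signal.integral_at(chrom, clipped)
        widths = np.diff(edges)
        out = np.zeros(len(widths))
        nz = widths > 0
        out[nz] = np.diff(integ)[nz] / widths[nz]
        return out

    values, ids = _region_bins(regions, n_body_bins, flank_bp, flank_bins,
                               per_bin)
    return MetageneMatrix(values, ids, n_body_bins, flank_bp, flank_bins,
                          "signal")


def shuffled_background(regions: Sequence[GenomicInterval],
                        layout: GenomeLayout, n_shuffles: int, seed: int,
                        metagene_fn, **kwargs) -> np.ndarray:
    """Mean column profile of a metagene over shuffled region sets."""
    total = None
    for i in range(n_shuffles):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)))
        shuffled = shuffle_intervals(regions, layout, rng)
        means = metagene_fn(shuffled, **kwargs).column_means()
        total = means if total is None else total + means
    return total / n_shuffles


def mask_signal_outside_peaks(signal: SignalTrack,
                              peaks: Sequence[GenomicInterval],
                              layout: GenomeLayout, pad: int = 1000
                              ) -> SignalTrack:
    """Zero the signal everywhere outside peaks extended by ``pad`` bp.

    Mirrors masking noisy embryo tracks to significant peaks: bases
    outside the union of padded peaks are set to 0, bases inside are
    unchanged.
    """
    if not peaks:
        return SignalTrack()
    padded = [GenomicInterval(p.chrom, max(0, p.start - pad),
                              min(layout.length(p.chrom), p.end + pad))
              for p in peaks]
    windows = merge_intervals(padded)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    steps = []
    for iv, value in signal.steps():
        for w in by_chrom.get(iv.chrom, ()):
            s, e = max(iv.start, w.start), min(iv.end, w.end)
            if e > s:
                steps.append((GenomicInterval(iv.chrom, s, e), value))
    return SignalTrack(steps)
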