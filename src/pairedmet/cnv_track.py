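"""Per-SNP log2 coverage-ratio CNV track: recentering, smoothing, segments.

The raw value at a matched SNP is log2 of the ratio of library-size
normalized tumor and germline coverages; the track is recentered to zero by
subtracting a genome-wide location estimate (median by default, mean
optional). Smoothing is a moving average across a fixed number of adjacent
SNPs inside each chromosome. Segment thresholds (+-0.3, 10 SNPs) are
tooling defaults, not reported values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .types import RegionSet, SnpObservation


@dataclass(frozen=True)
class CnvPoint:
    chrom: str
    pos: int
    raw_log2: float
    smoothed_log2: Optional[float] = None


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int  # 0-based half-open, BED-style
    end: int
    call: str  # deletion | amplification
    mean_smoothed_log2: float
    n_snps: int


class CnvTrack(NamedTuple):
    points: List[CnvPoint]
    n_dropped: int

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


def log2_ratio_track(
    tumor: Sequence[SnpObservation],
    germline: Sequence[SnpObservation],
    center: str = "median",
) -> CnvTrack:
    """Recentered per-SNP log2 ratio of normalized tumor/germline coverage.

    Observations are matched on (chrom, pos); positions with zero coverage
    in either sample are dropped and counted.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    t_by_pos = {(o.chrom, o.pos): o for o in tumor}
    g_by_pos = {(o.chrom, o.pos): o for o in germline}
    common = sorted(set(t_by_pos) & set(g_by_pos))
    matched = [(k, t_by_pos[k], g_by_pos[k]) for k in common]
    usable = [(k, t, g) for k, t, g in matched if t.coverage > 0 and g.coverage > 0]
    n_dropped = len(matched) - len(usable)
    if not usable:
        import warnings

        warnings.warn("no common covered positions between tumor and germline")
        return CnvTrack(points=[], n_dropped=n_dropped)
    t_total = sum(t.coverage for _, t, _ in usable)
    g_total = sum(g.coverage for _, _, g in usable)
    raw = np.array([
        math.log2((t.coverage / t_total) / (g.coverage / g_total))
        for _, t, g in usable
    ])
    offset = float(np.median(raw)) if center == "median" else float(np.mean(raw))
    points = [
        CnvPoint(chrom=k[0], pos=k[1], raw_log2=float(v - offset))
        for (k, _, _), v in zip(usable, raw)
    ]
    return CnvTrack(points=points, n_dropped=n_dropped)


def _chromosome_runs(points: Sequence[CnvPoint]) -> List[Tuple[int, int]]:
    """(start, stop) index ranges of consecutive same-chromosome points."""
    runs = []
    start = 0
    for i in range(1, len(points) + 1):
        if i == len(points) or points[i].chrom != points[start].chrom:
            runs.append((start, i))
            start = i
    return runs


def moving_average(points: Sequence[CnvPoint], window: int = 10) -> List[CnvPoint]:
    """Centered moving average of raw_log2 across adjacent SNPs.

    Windows never cross chromosome boundaries; near chromosome ends the
    available (shorter) window is used. For an even window the extra
    neighbour is taken downstream.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    points = list(points)
    out: List[CnvPoint] = [None] * len(points)  # type: ignore[list-item]
    lo_off = (window - 1) // 2
    hi_off = window // 2
    for start, stop in _chromosome_runs(points):
        vals = np.array([p.raw_log2 for p in points[start:stop]])
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        n = stop - start
        for i in range(n):
            lo = max(0, i - lo_off)
            hi = min(n, i + hi_off + 1)
            sm = (csum[hi] - csum[lo]) / (hi - lo)
            out[start + i] = replace(points[start + i], smoothed_log2=float(sm))
    return out


def call_segments(
    points: Sequence[CnvPoint],
    del_threshold: float = -0.3,
    amp_threshold: float = 0.3,
    min_snps: int = 10,
) -> List[CnvSegment]:
    """Maximal runs of SNPs beyond a smoothed-log2 threshold become segments.

    Same-call runs separated by a single below-threshold SNP are merged;
    runs shorter than ``min_snps`` qualifying SNPs (after merging) are
    discarded. Runs never cross chromosomes.
    """
    if del_threshold >= amp_threshold:
        raise ValueError("del_threshold must be below amp_threshold")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    points = list(points)
    segments: List[CnvSegment] = []
    for start, stop in _chromosome_runs(points):
        chrom_pts = points[start:stop]
        classes = []
        for p in chrom_pts:
            if p.smoothed_log2 is None:
                raise ValueError("call_segments needs smoothed values; run moving_average")
            if p.smoothed_log2 < del_threshold:
                classes.append(-1)
            elif p.smoothed_log2 > amp_threshold:
                classes.append(1)
            else:
                classes.append(0)
        # maximal runs of one class
        runs: List[Tuple[int, int, int]] = []  # (class, first, last) inclusive
        i = 0
        n = len(chrom_pts)
        while i < n:
            if classes[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and classes[j + 1] == classes[i]:
                j += 1
            runs.append((classes[i], i, j))
            i = j + 1
        # merge same-class runs separated by a gap of < 2 SNPs
        merged: List[Tuple[int, int, int]] = []
        for run in runs:
            if merged and merged[-1][0] == run[0] and run[1] - merged[-1][2] - 1 < 2:
                merged[-1] = (run[0], merged[-1][1], run[2])
            else:
                merged.append(run)
        for cls, first, last in merged:
            qualifying = [
                chrom_pts[k] for k in range(first, last + 1) if classes[k] == cls
            ]
            if len(qualifying) < min_snps:
                continue
            segments.append(CnvSegment(
                chrom=chrom_pts[first].chrom,
                start=chrom_pts[first].pos - 1,
                end=chrom_pts[last].pos,
                call="deletion" if cls < 0 else "amplification",
                mean_smoothed_log2=float(np.mean([p.smoothed_log2 for p in qualifying])),
                n_snps=len(qualifying),
            ))
    return segments


def annotate_loci(segments: Sequence[CnvSegment], loci: RegionSet) -> Dict[str, dict]:
    """Per-locus call table: deletion/amplification/neutral, or conflict."""
    table: Dict[str, dict] = {}
    for chrom, start, end, label in loci:
        key = label or f"{chrom}:{start}-{end}"
        overlapping = [
            s for s in segments
            if s.chrom == chrom and s.start < end and start < s.end
        ]
        calls = sorted({s.call for s in overlapping})
        if not calls:
            call = "neutral"
        elif len(calls) == 1:
            call = calls[0]
        else:
            call = "conflict"
        table[key] = {"call": call, "segments": overlapping}
    return table
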