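"""Rearrangement hotspot detection by piecewise-constant fitting (PCF).

Breakpoints of one SV category (short / modest / long tandem duplications,
or deletions) are genome-sorted per chromosome; log10 inter-breakpoint
distances are segmented with an exact penalized least-squares PCF
(dynamic programming), and segments whose physical breakpoint density
exceeds a fold of the whole-genome background density with support from a
minimum number of distinct samples are reported as hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .catalog_io import GenomeModel, RegionSet, SVRecord, sv_span

CATEGORIES = ("short", "modest", "long", "deletion")


def category_of(record: SVRecord) -> Optional[str]:
    """Hotspot category of a record: TD span class or deletion; None for
    records outside the four analyzed categories."""
    if record.svtype == "DEL":
        return "deletion"
    if record.svtype != "TD" or not record.intra:
        return None
    span = sv_span(record)
    if span < 1e5:
        return "short"
    if span <= 1e6:
        return "modest"
    return "long"


@dataclass
class PCFSegment:
    start: int          # inclusive index into the value sequence
    end: int            # inclusive
    mean: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    category: str
    n_breakpoints: int
    n_samples: int
    density_per_mb: float
    background_per_mb: float
    fold: float
    annotations: List[str] = field(default_factory=list)


def sorted_breakpoints(svs: Sequence[SVRecord],
                       category: Optional[str],
                       genome: GenomeModel
                       ) -> Dict[str, Tuple[np.ndarray, List[str]]]:
    """Per-chromosome sorted breakend positions with their sample tags.

    Both breakends of every qualifying record contribute.
    """
    per: Dict[str, List[Tuple[int, str]]] = {c: [] for c in genome.names}
    for r in svs:
        if category is not None and category_of(r) != category:
            continue
        for chrom, pos in ((r.chrom1, r.pos1), (r.chrom2, r.pos2)):
            if chrom in per:
                per[chrom].append((pos, r.sample_id))
    out = {}
    for chrom, items in per.items():
        items.sort()
        out[chrom] = (np.array([p for p, _ in items], dtype=np.int64),
                      [s for _, s in items])
    return out


def intermutation_log_distances(positions: np.ndarray) -> np.ndarray:
    """log10 distances between consecutive sorted positions, floored at 1 bp
    (duplicate positions map to 0.0)."""
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) < 2:
        return np.array([])
    d = np.maximum(np.diff(positions), 1)
    return np.log10(d)


def pcf(values: Sequence[float], gamma: float, kmin: int = 1
        ) -> List[PCFSegment]:
    """Exact penalized least-squares segmentation.

    Minimizes  sum_segments sum_t (v_t - mean)^2 + gamma * (#segments)
    subject to every segment containing at least ``kmin`` values, by dynamic
    programming over break positions.  Deterministic; sequences shorter than
    ``kmin`` collapse to a single segment.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return []
    if n < max(kmin, 2):
        return [PCFSegment(0, n - 1, float(v.mean()))]
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost(j, i):
        """SSE of v[j..i-1] (prefix indices)."""
        k = i - j
        return s2[i] - s2[j] - (s1[i] - s1[j]) ** 2 / k

    # dp[i] = optimal cost of v[0..i-1]; vectorized over split points
    dp = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    dp[0] = 0.0
    js = np.arange(n + 1)
    for i in range(kmin, n + 1):
        j = js[: i - kmin + 1]                # segment = v[j..i-1], len >= kmin
        k = i - j
        costs = dp[j] + (s2[i] - s2[j] - (s1[i] - s1[j]) ** 2 / k) + gamma
        best = int(np.argmin(costs))
        dp[i] = costs[best]
        prev[i] = best
    if not np.isfinite(dp[n]):               # n < kmin handled above; safety
        return [PCFSegment(0, n - 1, float(v.mean()))]
    cuts = []
    i = n
    while i > 0:
        cuts.append((prev[i], i))
        i = prev[i]
    segments = []
    for j, i in reversed(cuts):
        segments.append(PCFSegment(int(j), int(i - 1),
                                   float(v[j:i].mean())))
    return segments


def call_hotspots(svs: Sequence[SVRecord],
                  category: str,
                  genome: GenomeModel,
                  gamma: float = 25.0,
                  kmin: int = 10,
                  fold: float = 2.0,
                  min_samples: int = 6,
                  merge_gap_bp: int = 1_000) -> List[Hotspot]:
    """Call rearrangement hotspots for one SV category.

    The background density is the category's total breakpoint count over the
    genome length.  PCF segments of the per-chromosome log10 inter-breakpoint
    distances define candidate intervals [first, last breakpoint]; a
    candidate becomes a hotspot when its physical density exceeds
    ``fold`` x background and at least ``min_samples`` distinct samples
    contribute.  Adjacent qualifying intervals closer than ``merge_gap_bp``
    are merged.  Invariant to sample and chromosome ordering.
    """
    per_chrom = sorted_breakpoints(svs, category, genome)
    total_bp = sum(len(pos) for pos, _ in per_chrom.values())
    if total_bp == 0:
        return []
    background = total_bp / (genome.total_length / 1e6)
    hotspots: List[Hotspot] = []
    for chrom in genome.names:
        positions, samples = per_chrom[chrom]
        if len(positions) < 2:
            continue
        values = intermutation_log_distances(positions)
        segments = pcf(values, gamma=gamma, kmin=min(kmin, len(values)))
        candidates = []
        for seg in segments:
            # values seg.start..seg.end cover breakpoints seg.start..seg.end+1
            lo, hi = seg.start, seg.end + 1
            start, end = int(positions[lo]), int(positions[hi])
            n_bp = hi - lo + 1
            span_mb = max(end - start, 1) / 1e6
            density = n_bp / span_mb
            seg_samples = set(samples[lo:hi + 1])
            if density > fold * background and len(seg_samples) >= min_samples:
                candidates.append([start, end, lo, hi])
        # merge adjacent qualifying intervals separated by < merge_gap_bp
        merged = []
        for c in sorted(candidates):
            if merged and c[0] - merged[-1][1] < merge_gap_bp:
                merged[-1][1] = max(merged[-1][1], c[1])
                merged[-1][3] = max(merged[-1][3], c[3])
            else:
                merged.append(c)
        for start, end, lo, hi in merged:
            n_bp = hi - lo + 1
            span_mb = max(end - start, 1) / 1e6
            density = n_bp / span_mb
            hotspots.append(Hotspot(
                chrom=chrom, start=start, end=end, category=category,
                n_breakpoints=n_bp,
                n_samples=len(set(samples[lo:hi + 1])),
                density_per_mb=density,
                background_per_mb=background,
                fold=density / background))
    return hotspots


def call_all_hotspots(svs: Sequence[SVRecord], genome: GenomeModel,
                      **kwargs) -> List[Hotspot]:
    """Run hotspot calling separately per TD span category and deletions."""
    out: List[Hotspot] = []
    for category in CATEGORIES:
        out.extend(call_hotspots(svs, category, genome, **kwargs))
    return out


def annotate_hotspots(hotspots: Sequence[Hotspot],
                      region_sets: Sequence[RegionSet]) -> List[Hotspot]:
    """Attach labels of all regions overlapping each hotspot (any overlap)."""
    for h in hotspots:
        labels = []
        for rs in region_sets:
            for chrom, start, end, label in rs.intervals:
                if chrom == h.chrom and start <= h.end and end >= h.start:
                    labels.append(label)
        h.annotations = labels
    return list(hotspots)


def hotspot_table(hotspots: Sequence[Hotspot]):
    """BED-compatible hotspot table (0-based starts)."""
    import pandas as pd
    rows = [{
        "chrom": h.chrom, "start": h.start - 1, "end": h.end,
        "category": h.category, "n_breakpoints": h.n_breakpoints,
        "n_samples": h.n_samples,
        "density_per_mb": h.density_per_mb,
        "background_per_mb": h.background_per_mb,
        "fold": h.fold,
        "annotations": ",".join(h.annotations),
    } for h in hotspots]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "category", "n_breakpoints", "n_samples",
        "density_per_mb", "background_per_mb", "fold", "annotations"])
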