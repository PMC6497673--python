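"""Synthetic cancer-WGS cohort generator with planted, labelled structure.

Generates a small multi-chromosome reference genome plus per-sample somatic
SV catalogs, copy-number profiles and SNV tables in which every downstream
detector's target is planted and recorded in a truth table: tandem-duplicator
phenotype (TDP) samples with mode-specific TD span mixtures, rearrangement
hotspot loci, a chromothripsis region with oscillating copy number and random
join orientations, breakage-fusion-bridge loci (fold-back inversion +
high-level amplification + telomeric loss), kataegis SNV showers adjacent to
breakpoints, bimodal mutation burdens, and region-biased signature exposures
(a noncoding-enriched C>A process).

Scale: the default genome is four chromosomes totalling 24 Mb, sized so the
full pipeline (simulation + every detector) runs in a few minutes on one CPU.
Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .catalog_io import (CNSegment, GenomeModel, RegionSet, SampleCatalog,
                         SNVRecord, SVRecord)
from .burden_signatures import (CHANNELS, channel_context32, channel_parts,
                                SUBSTITUTIONS)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# Signature construction helpers
# ---------------------------------------------------------------------------

def make_signature(weights: Mapping[str, float]) -> np.ndarray:
    """Build a normalized 96-vector from {pattern: weight} where pattern is
    e.g. "C>T" (all 16 contexts), "T[C>T]N" / "N[C>G]G" (5'/3' restricted),
    or a full channel label "A[C>A]A"."""
    v = np.zeros(96)
    for pattern, w in weights.items():
        if "[" not in pattern:
            sub = pattern
            idx = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == sub]
        else:
            five, rest = pattern[0], pattern[2:]
            sub, three = rest[:3], rest[4]
            idx = [i for i, ch in enumerate(CHANNELS)
                   if ch[2:5] == sub
                   and (five == "N" or ch[0] == five)
                   and (three == "N" or ch[6] == three)]
        if not idx:
            raise ValueError(f"pattern {pattern!r} matches no channel")
        for i in idx:
            v[i] += w / len(idx)
    s = v.sum()
    if s <= 0:
        raise ValueError("signature has zero mass")
    return v / s


def default_signatures() -> Dict[str, np.ndarray]:
    """Three well-separated generating processes: a CpG-deamination
    aging-like C>T signature, a flat C>A signature (the noncoding-enriched
    process), and a T>C signature."""
    return {
        "aging_like": make_signature({"N[C>T]G": 0.80, "C>T": 0.20}),
        "c_to_a": make_signature({"C>A": 1.0}),
        "t_to_c": make_signature({"T>C": 1.0}),
    }


def kataegis_signature() -> np.ndarray:
    """TpC-focused C>T/C>G shower signature (APOBEC-like)."""
    return make_signature({"T[C>T]N": 0.5, "T[C>G]N": 0.5})


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class HotspotLocus:
    chrom: str
    start: int
    end: int
    category: str               # short / modest / long / deletion
    hit_prob: float = 0.5
    svs_per_hit: Tuple[int, int] = (2, 4)          # inclusive range
    span_range: Tuple[float, float] = (8e3, 6e4)   # log-uniform draw


@dataclass
class ChromothripsisSpec:
    chrom: str = "chr3"
    start: int = 400_000
    end: int = 700_000
    n_rearrangements: int = 40
    cn_states: Tuple[int, ...] = (2, 3)
    sample_fraction: float = 0.20


@dataclass
class FoldbackSpec:
    chrom: str = "chr2"
    position: int = 6_000_000
    separation: int = 5_000
    amplicon: Tuple[int, int] = (5_500_000, 6_000_000)
    amplicon_cn: int = 8
    telomere_loss: bool = True
    telomere_cn: int = 1
    sample_fraction: float = 0.24


@dataclass
class KataegisSpec:
    sample_fraction: float = 0.30
    foci_per_sample: int = 2
    shower_size: Tuple[int, int] = (8, 15)
    imd_mean_bp: float = 300.0
    breakpoint_offset_bp: int = 2_000


@dataclass
class BurdenSpec:
    regular_rate_per_mb: float = 8.0
    hyper_rate_per_mb: float = 60.0
    hyper_fraction: float = 0.08
    rate_log10_sd: float = 0.10


@dataclass
class SpanMode:
    log10_mean: float
    log10_sd: float = 0.25
    weight: float = 1.0


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults follow the observed cohort: per-sample SV counts log-uniform in
    19-696, the published SV-type mixture, TD span modes at ~11 kb and
    ~231 kb (log10 4.04 / 5.36) plus a minor >1 Mb mode, TDP prevalence
    24/168, and a bimodal mutation burden with a small hypermutated outlier
    class.
    """

    n_samples: int = 50
    seed: int = 7
    chrom_lengths: Dict[str, int] = field(default_factory=lambda: {
        "chr1": 8_000_000, "chr2": 7_000_000,
        "chr3": 5_000_000, "chr4": 4_000_000})
    sv_count_range: Tuple[int, int] = (19, 696)
    tdp_sv_count_range: Tuple[int, int] = (200, 696)
    # SV-type mixture (proportions sum to 1); the TDP mixture shifts weight
    # into TDs (paper mean TD proportion 42.4%, range 20-74%)
    sv_type_mixture: Dict[str, float] = field(default_factory=lambda: {
        "DEL": 0.42, "TD": 0.14, "ITX": 0.18, "INV": 0.13,
        "COMPLEX_DEL": 0.06, "FB_INV": 0.05, "INS": 0.02})
    tdp_sv_type_mixture: Dict[str, float] = field(default_factory=lambda: {
        "DEL": 0.30, "TD": 0.35, "ITX": 0.12, "INV": 0.10,
        "COMPLEX_DEL": 0.06, "FB_INV": 0.04, "INS": 0.03})
    tdp_fraction: float = 24 / 168
    tdp_group_probs: Dict[str, float] = field(default_factory=lambda: {
        "1": 2 / 24, "2": 16 / 24, "mix12": 6 / 24})
    td_span_modes: Dict[str, List[SpanMode]] = field(default_factory=lambda: {
        # trimodal background; group-specific unimodal / bimodal mixtures
        "background": [SpanMode(4.04, 0.25, 0.45), SpanMode(5.36, 0.25, 0.45),
                       SpanMode(6.20, 0.15, 0.10)],
        "1": [SpanMode(4.04, 0.25, 1.0)],
        "2": [SpanMode(5.36, 0.25, 1.0)],
        "mix12": [SpanMode(4.04, 0.25, 0.5), SpanMode(5.36, 0.25, 0.5)],
    })
    hotspots: List[HotspotLocus] = field(default_factory=lambda: [
        HotspotLocus("chr1", 2_000_000, 2_080_000, "short",
                     span_range=(8e3, 6e4)),
        HotspotLocus("chr2", 3_000_000, 3_100_000, "modest",
                     span_range=(1.2e5, 6e5)),
        HotspotLocus("chr4", 1_200_000, 1_280_000, "deletion",
                     span_range=(1e4, 8e4)),
    ])
    chromothripsis: ChromothripsisSpec = field(
        default_factory=ChromothripsisSpec)
    foldback: FoldbackSpec = field(default_factory=FoldbackSpec)
    kataegis: KataegisSpec = field(default_factory=KataegisSpec)
    burden: BurdenSpec = field(default_factory=BurdenSpec)
    # region-specific signature exposure weights; the C>A process is absent
    # from coding regions by construction
    coding_exposure: Dict[str, float] = field(default_factory=lambda: {
        "aging_like": 0.65, "c_to_a": 0.0, "t_to_c": 0.35})
    noncoding_exposure: Dict[str, float] = field(default_factory=lambda: {
        "aging_like": 0.40, "c_to_a": 0.35, "t_to_c": 0.25})
    # low concentration = strong inter-sample exposure heterogeneity, as in
    # real cohorts where per-sample signature contributions span 0 to >50%
    exposure_dirichlet_conc: float = 6.0
    cn_window_bp: int = 10_000
    cn_noise_sd: float = 0.08

    def validate(self) -> None:
        for name, mix in (("sv_type_mixture", self.sv_type_mixture),
                          ("tdp_sv_type_mixture", self.tdp_sv_type_mixture)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for key, modes in self.td_span_modes.items():
            if abs(sum(m.weight for m in modes) - 1.0) > 1e-9:
                raise ValueError(f"span mixture {key!r} weights must sum to 1")
        if self.burden.regular_rate_per_mb <= 0 \
                or self.burden.hyper_rate_per_mb <= 0:
            raise ValueError("burden rates must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class SampleTruth:
    sample_id: str
    is_tdp: bool = False
    tdp_group: str = "not_tdp"
    is_hypermutated: bool = False
    mutation_rate_per_mb: float = 0.0
    chromothripsis_regions: List[Tuple[str, int, int]] = field(
        default_factory=list)
    kataegis_foci: List[Tuple[str, int, int]] = field(default_factory=list)
    kataegis_phase: List[int] = field(default_factory=list)
    foldbacks: List[Tuple[str, int, int]] = field(default_factory=list)
    bfb_loci: List[Tuple[str, int, int]] = field(default_factory=list)
    hotspot_hits: List[int] = field(default_factory=list)
    true_exposures: Dict[str, Dict[str, int]] = field(default_factory=dict)
    true_exposure_weights: Dict[str, Dict[str, float]] = field(
        default_factory=dict)
    n_kataegis_foci_planned: int = 0


@dataclass
class TruthTable:
    samples: Dict[str, SampleTruth]
    hotspot_loci: List[HotspotLocus]
    signatures: Dict[str, List[float]]

    def to_json(self, path) -> None:
        payload = {
            "samples": {s: asdict(t) for s, t in self.samples.items()},
            "hotspot_loci": [asdict(h) for h in self.hotspot_loci],
            "signatures": self.signatures,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_frame(self):
        import pandas as pd
        rows = []
        for s, t in self.samples.items():
            rows.append({
                "sample_id": s, "is_tdp": t.is_tdp, "tdp_group": t.tdp_group,
                "is_hypermutated": t.is_hypermutated,
                "mutation_rate_per_mb": t.mutation_rate_per_mb,
                "n_chromothripsis": len(t.chromothripsis_regions),
                "n_kataegis": len(t.kataegis_foci),
                "n_foldbacks": len(t.foldbacks),
                "n_bfb": len(t.bfb_loci),
                "hotspot_hits": ",".join(map(str, t.hotspot_hits)),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(n_chrom: int,
                    lengths: Sequence[int],
                    gc_model: Optional[Sequence[float]] = None,
                    seed: int = 0,
                    names: Optional[Sequence[str]] = None
                    ) -> Tuple[GenomeModel, Dict[str, str]]:
    """Simulate an i.i.d. base reference genome.

    ``gc_model`` gives base probabilities for A,C,G,T (default uniform).
    Deterministic under ``seed``.
    """
    if n_chrom <= 0:
        raise ValueError("n_chrom must be positive")
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    for l in lengths:
        if l < 10_000:
            raise ValueError("chromosome lengths must be >= 10 kb")
    probs = np.asarray(gc_model if gc_model is not None else [0.25] * 4)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    names = list(names) if names else [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name, length in zip(names, lengths):
        codes = rng.choice(4, size=int(length), p=probs)
        seqs[name] = base_bytes[codes].tobytes().decode("ascii")
    model = GenomeModel(
        names=tuple(names),
        lengths={n: int(l) for n, l in zip(names, lengths)},
        centromeres={n: int(l) // 2 for n, l in zip(names, lengths)})
    return model, seqs


def default_coding_regions(genome: GenomeModel,
                           interval_bp: int = 12_500,
                           spacing_bp: int = 200_000) -> RegionSet:
    """Evenly spaced synthetic coding exon blocks (~6% genome footprint)."""
    ivs = []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        pos = 100_000
        i = 0
        while pos + interval_bp < length - 50_000:
            ivs.append((chrom, pos + 1, pos + interval_bp, f"gene_{chrom}_{i}"))
            pos += spacing_bp
            i += 1
    return RegionSet(name="coding", intervals=ivs)


def default_enhancer_regions() -> RegionSet:
    """A couple of enhancer intervals, one under the modest-TD hotspot."""
    return RegionSet(name="enhancers", intervals=[
        ("chr2", 3_020_001, 3_060_000, "super_enhancer_A"),
        ("chr1", 5_000_001, 5_030_000, "enhancer_B"),
    ])


# ---------------------------------------------------------------------------
# SV catalog
# ---------------------------------------------------------------------------

def _draw_span(modes: Sequence[SpanMode], rng: np.random.Generator) -> int:
    w = np.array([m.weight for m in modes])
    m = modes[rng.choice(len(modes), p=w / w.sum())]
    return max(2, int(round(10 ** rng.normal(m.log10_mean, m.log10_sd))))


def _choose_chrom(genome: GenomeModel, rng) -> str:
    lens = np.array([genome.lengths[n] for n in genome.names], dtype=float)
    return genome.names[rng.choice(len(lens), p=lens / lens.sum())]


def _place_span(genome: GenomeModel, chrom: str, span: int, rng,
                modes=None, max_retry: int = 100) -> Tuple[int, int, int]:
    """Place an intra-chromosomal record; resample span when it exceeds the
    chromosome (retry cap, then clamp)."""
    length = genome.lengths[chrom]
    for _ in range(max_retry):
        if span < length:
            break
        span = _draw_span(modes, rng) if modes else span // 2
    span = min(span, length - 2)
    pos1 = int(rng.integers(1, length - span))
    return pos1, pos1 + span, span


def simulate_sv_catalog(genome: GenomeModel,
                        config: CohortConfig,
                        truth: SampleTruth,
                        rng: np.random.Generator) -> List[SVRecord]:
    """Simulate one sample's SV catalog according to its truth labels."""
    sid = truth.sample_id
    records: List[SVRecord] = []

    if truth.is_tdp:
        lo, hi = config.tdp_sv_count_range
        mixture = config.tdp_sv_type_mixture
        span_modes = config.td_span_modes[truth.tdp_group]
    else:
        lo, hi = config.sv_count_range
        mixture = config.sv_type_mixture
        span_modes = config.td_span_modes["background"]
    n_sv = int(round(10 ** rng.uniform(np.log10(lo), np.log10(hi))))

    types = list(mixture)
    counts = rng.multinomial(n_sv, [mixture[t] for t in types])
    for svtype, k in zip(types, counts):
        for _ in range(k):
            chrom = _choose_chrom(genome, rng)
            if svtype == "ITX":
                others = [c for c in genome.names if c != chrom]
                chrom2 = others[rng.integers(len(others))]
                records.append(SVRecord(
                    sample_id=sid, chrom1=chrom,
                    pos1=int(rng.integers(1, genome.lengths[chrom])),
                    strand1="+-"[rng.integers(2)],
                    chrom2=chrom2,
                    pos2=int(rng.integers(1, genome.lengths[chrom2])),
                    strand2="+-"[rng.integers(2)], svtype="ITX"))
                continue
            if svtype == "TD":
                span = _draw_span(span_modes, rng)
                pos1, pos2, _ = _place_span(genome, chrom, span, rng,
                                            span_modes)
                records.append(SVRecord(sid, chrom, pos1, "-", chrom, pos2,
                                        "+", "TD"))
            elif svtype in ("DEL", "COMPLEX_DEL"):
                span = max(50, int(10 ** rng.normal(4.5, 0.4)))
                pos1, pos2, _ = _place_span(genome, chrom, span, rng)
                records.append(SVRecord(sid, chrom, pos1, "+", chrom, pos2,
                                        "-", svtype))
            elif svtype == "INV":
                span = max(100, int(10 ** rng.normal(4.7, 0.5)))
                pos1, pos2, _ = _place_span(genome, chrom, span, rng)
                s = "+" if rng.integers(2) else "-"
                records.append(SVRecord(sid, chrom, pos1, s, chrom, pos2, s,
                                        "INV", has_reciprocal_cluster=True))
            elif svtype == "FB_INV":
                span = int(rng.integers(2_000, 25_000))
                pos1, pos2, _ = _place_span(genome, chrom, span, rng)
                s = "+" if rng.integers(2) else "-"
                records.append(SVRecord(sid, chrom, pos1, s, chrom, pos2, s,
                                        "FB_INV",
                                        has_reciprocal_cluster=False))
            elif svtype == "INS":
                pos1 = int(rng.integers(1, genome.lengths[chrom] - 1))
                records.append(SVRecord(sid, chrom, pos1, "+", chrom,
                                        pos1 + 1, "-", "INS"))

    # hotspot extras: breakend 1 planted inside the locus
    for locus_id in truth.hotspot_hits:
        locus = config.hotspots[locus_id]
        k = int(rng.integers(locus.svs_per_hit[0], locus.svs_per_hit[1] + 1))
        for _ in range(k):
            pos1 = int(rng.integers(locus.start, locus.end))
            span = int(round(10 ** rng.uniform(np.log10(locus.span_range[0]),
                                               np.log10(locus.span_range[1]))))
            pos2 = min(pos1 + span, genome.lengths[locus.chrom] - 1)
            if locus.category == "deletion":
                records.append(SVRecord(sid, locus.chrom, pos1, "+",
                                        locus.chrom, pos2, "-", "DEL"))
            else:
                records.append(SVRecord(sid, locus.chrom, pos1, "-",
                                        locus.chrom, pos2, "+", "TD"))

    # chromothripsis: clustered breakpoints with uniformly random join
    # orientations; emitted as OTHER so type-based counts stay clean
    for chrom, start, end in truth.chromothripsis_regions:
        n = config.chromothripsis.n_rearrangements
        for _ in range(n):
            a, b = sorted(rng.integers(start, end, size=2).tolist())
            while b - a < 10:
                a, b = sorted(rng.integers(start, end, size=2).tolist())
            s1, s2 = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")][
                rng.integers(4)]
            records.append(SVRecord(sid, chrom, int(a), s1, chrom, int(b),
                                    s2, "OTHER",
                                    has_reciprocal_cluster=False))

    # planted fold-back inversions (BFB loci)
    for chrom, pos, sep in truth.foldbacks:
        records.append(SVRecord(sid, chrom, pos, "+", chrom, pos + sep, "+",
                                "FB_INV", has_reciprocal_cluster=False))
    return records


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

def simulate_cn_profile(genome: GenomeModel,
                        svs: Sequence[SVRecord],
                        truth: Optional[SampleTruth] = None,
                        baseline_cn: int = 2,
                        window_bp: Optional[int] = None,
                        noise_sd: float = 0.0,
                        rng: Optional[np.random.Generator] = None,
                        config: Optional[CohortConfig] = None
                        ) -> List[CNSegment]:
    """Derive a copy-number profile consistent with the SV catalog.

    TDs add +1 over their span and deletions subtract 1; planted fold-backs
    create a high-level amplicon step at the breakend with (optionally)
    telomeric loss to the chromosome end; chromothripsis regions oscillate
    between the configured states.  With ``window_bp`` the exact profile is
    resampled onto fixed windows and Gaussian noise (``noise_sd``) is added
    to log2R, emulating read-depth segmentation; integer copy number stays
    exact.  Negative CN is clamped to 0.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sid = svs[0].sample_id if svs else (truth.sample_id if truth else "sample")
    chromothripsis = truth.chromothripsis_regions if truth else []
    fb_spec = config.foldback if config else FoldbackSpec()

    segments: List[CNSegment] = []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        bounds = {1, length + 1}
        deltas: List[Tuple[int, int, int]] = []
        for r in svs:
            if not r.intra or r.chrom1 != chrom:
                continue
            if r.svtype == "TD":
                deltas.append((r.pos1, r.pos2, +1))
            elif r.svtype in ("DEL", "COMPLEX_DEL"):
                deltas.append((r.pos1, r.pos2, -1))
        for s, e, _ in deltas:
            bounds.add(s)
            bounds.add(e + 1)

        overrides: List[Tuple[int, int, int]] = []   # (start, end, cn)
        for c, rs, re_ in chromothripsis:
            if c != chrom:
                continue
            bps = sorted(p for r in svs
                         if r.svtype == "OTHER" and r.chrom1 == chrom
                         for p in (r.pos1, r.pos2) if rs <= p <= re_)
            pts = [rs] + bps + [re_]
            states = (config.chromothripsis.cn_states if config
                      else (2, 3))
            for i in range(len(pts) - 1):
                if pts[i] < pts[i + 1]:
                    overrides.append((pts[i], pts[i + 1] - 1,
                                      states[i % len(states)]))
        for c, pos, sep in (truth.foldbacks if truth else []):
            if c != chrom:
                continue
            overrides.append((fb_spec.amplicon[0], fb_spec.amplicon[1] - 1,
                              fb_spec.amplicon_cn))
            if fb_spec.telomere_loss:
                overrides.append((pos + sep, length, fb_spec.telomere_cn))
        for s, e, _ in overrides:
            bounds.add(s)
            bounds.add(e + 1)

        pts = np.array(sorted(b for b in bounds if 1 <= b <= length + 1))
        starts, ends = pts[:-1], pts[1:] - 1
        cn = np.full(len(starts), baseline_cn, dtype=float)
        for s, e, d in deltas:
            cn[(starts >= s) & (ends <= e)] += d
        for s, e, v in overrides:
            cn[(starts >= s) & (ends <= e)] = v
        n_clamped = int((cn < 0).sum())
        if n_clamped:
            cn = np.maximum(cn, 0)
        if window_bp is None:
            # merge equal-CN neighbours, exact log2R
            i = 0
            while i < len(starts):
                j = i
                while j + 1 < len(starts) and cn[j + 1] == cn[i]:
                    j += 1
                value = max(cn[i], 0.25)
                segments.append(CNSegment(
                    sample_id=sid, chrom=chrom, start=int(starts[i]),
                    end=int(ends[j]), log2r=float(np.log2(value / 2.0)),
                    copy_number=int(cn[i])))
                i = j + 1
        else:
            w_starts = np.arange(1, length + 1, window_bp)
            w_ends = np.minimum(w_starts + window_bp - 1, length)
            mids = (w_starts + w_ends) // 2
            idx = np.searchsorted(starts, mids, side="right") - 1
            w_cn = cn[idx]
            log2r = np.log2(np.maximum(w_cn, 0.25) / 2.0)
            if noise_sd > 0:
                log2r = log2r + rng.normal(0, noise_sd, size=len(log2r))
            for s, e, c_, l2 in zip(w_starts, w_ends, w_cn, log2r):
                segments.append(CNSegment(
                    sample_id=sid, chrom=chrom, start=int(s), end=int(e),
                    log2r=float(l2), copy_number=int(c_)))
    return segments


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

class ContextIndex:
    """Per-chromosome canonical trinucleotide context codes with lazy
    per-(context, region-class) position pools for rejection-free SNV
    placement."""

    def __init__(self, seqs: Mapping[str, str], coding: RegionSet):
        self._ctx: Dict[str, np.ndarray] = {}
        self._coding_mask: Dict[str, np.ndarray] = {}
        self._pools: Dict[Tuple[str, int, str], np.ndarray] = {}
        merged = coding.merged()
        for chrom, seq in seqs.items():
            codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            b = np.full(len(codes), 255, dtype=np.uint8)
            for base, v in _BASE_CODE.items():
                b[codes == ord(base)] = v
            center = b[1:-1]
            five, three = b[:-2], b[2:]
            # canonical (pyrimidine-strand) context id 0..31
            ctx = np.full(len(center), 255, dtype=np.uint8)
            is_c = center == 1
            is_t = center == 3
            ctx[is_c] = (five[is_c] * 4 + three[is_c]).astype(np.uint8)
            ctx[is_t] = (16 + five[is_t] * 4 + three[is_t]).astype(np.uint8)
            is_g = center == 2
            is_a = center == 0
            # reverse complement: center G->C, A->T; flanks swap & complement
            comp = np.array([3, 2, 1, 0], dtype=np.uint8)
            ctx[is_g] = (comp[three[is_g]] * 4 + comp[five[is_g]]).astype(
                np.uint8)
            ctx[is_a] = (16 + comp[three[is_a]] * 4
                         + comp[five[is_a]]).astype(np.uint8)
            self._ctx[chrom] = ctx      # index i -> position i+2 (1-based)
            mask = np.zeros(len(ctx), dtype=bool)
            m = merged.get(chrom)
            if m is not None:
                for s, e in m:
                    lo = max(int(s) - 2, 0)
                    hi = min(int(e) - 2, len(ctx) - 1)
                    if hi >= lo:
                        mask[lo:hi + 1] = True
            self._coding_mask[chrom] = mask

    def chroms(self) -> List[str]:
        return list(self._ctx)

    def pool(self, chrom: str, ctx32: int, region: str) -> np.ndarray:
        key = (chrom, ctx32, region)
        if key not in self._pools:
            sel = self._ctx[chrom] == ctx32
            mask = self._coding_mask[chrom]
            sel = sel & (mask if region == "coding" else ~mask)
            self._pools[key] = (np.flatnonzero(sel) + 2).astype(np.int64)
        return self._pools[key]


def _support_counts(rng) -> Dict[str, int]:
    td = 14 + int(rng.poisson(21))
    ta = int(np.clip(rng.binomial(td, 0.35), 4, td))
    nd = 10 + int(rng.poisson(25))
    na = int(min(rng.binomial(nd, 0.002), 2))
    return {"tumor_depth": td, "tumor_alt": ta,
            "normal_depth": nd, "normal_alt": na}


def _emit_snv(sid, chrom, pos, channel, seqs, rng) -> SNVRecord:
    five, c_ref, c_alt, three = channel_parts(channel)
    ref = seqs[chrom][pos - 1]
    alt = c_alt if ref in "CT" else _COMP[c_alt]
    return SNVRecord(sample_id=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     **_support_counts(rng))


def simulate_snvs(genome: GenomeModel,
                  seqs: Mapping[str, str],
                  config: CohortConfig,
                  truth: SampleTruth,
                  svs: Sequence[SVRecord],
                  signatures: Mapping[str, np.ndarray],
                  ctx_index: ContextIndex,
                  coding: RegionSet,
                  rng: np.random.Generator) -> List[SNVRecord]:
    """Simulate one sample's somatic SNVs.

    Background mutations are drawn per region class at the sample's burden
    rate from the exposure-weighted signature mixture and placed only at
    positions whose reference trinucleotide matches the drawn channel;
    kataegis showers (exponential inter-mutation spacing, C>T/C>G) are
    planted within reach of SV breakpoints.  Records mutated truth in place
    (true exposure counts, kataegis foci bounds).
    """
    sid = truth.sample_id
    rate = truth.mutation_rate_per_mb
    coding_bp = coding.footprint
    total_bp = genome.total_length
    noncoding_bp = total_bp - coding_bp
    sig_names = list(signatures)
    out: List[SNVRecord] = []
    seen = set()
    region_weights = {
        "coding": np.array([truth.true_exposure_weights["coding"][s]
                            for s in sig_names]),
        "noncoding": np.array([truth.true_exposure_weights["noncoding"][s]
                               for s in sig_names]),
    }
    truth.true_exposures = {"coding": {s: 0 for s in sig_names},
                            "noncoding": {s: 0 for s in sig_names}}
    chrom_w = {}
    for region, bp in (("coding", coding_bp), ("noncoding", noncoding_bp)):
        n = int(rng.poisson(rate * bp / 1e6))
        w = region_weights[region]
        w = w / w.sum()
        sig_counts = rng.multinomial(n, w)
        for s_i, k in enumerate(sig_counts):
            if k == 0:
                continue
            truth.true_exposures[region][sig_names[s_i]] += int(k)
            chan_counts = rng.multinomial(k, signatures[sig_names[s_i]])
            for ch in np.flatnonzero(chan_counts):
                m = int(chan_counts[ch])
                ctx = channel_context32(int(ch))
                # chromosome weights by pool size for this context/region
                key = (region, ctx)
                if key not in chrom_w:
                    sizes = np.array([len(ctx_index.pool(c, ctx, region))
                                      for c in genome.names], dtype=float)
                    chrom_w[key] = sizes
                sizes = chrom_w[key]
                if sizes.sum() == 0:
                    continue      # shortfall: no matching sites
                chosen = rng.multinomial(m, sizes / sizes.sum())
                for c_i, kk in enumerate(chosen):
                    if kk == 0:
                        continue
                    pool = ctx_index.pool(genome.names[c_i], ctx, region)
                    pos = pool[rng.integers(0, len(pool), size=int(kk))]
                    for p in pos.tolist():
                        if (genome.names[c_i], p) in seen:
                            continue
                        seen.add((genome.names[c_i], p))
                        out.append(_emit_snv(sid, genome.names[c_i], int(p),
                                             int(ch), seqs, rng))

    # kataegis showers near SV breakpoints
    intra = [r for r in svs if r.intra]
    truth.kataegis_foci = []
    truth.kataegis_phase = []
    for _ in range(truth.n_kataegis_foci_planned):
        if not intra:
            break
        r = intra[rng.integers(len(intra))]
        bp = r.pos1 if rng.integers(2) else r.pos2
        chrom = r.chrom1
        start = max(3, bp + int(rng.integers(
            -config.kataegis.breakpoint_offset_bp,
            config.kataegis.breakpoint_offset_bp + 1)))
        n_mut = int(rng.integers(config.kataegis.shower_size[0],
                                 config.kataegis.shower_size[1] + 1))
        gaps = np.maximum(1, rng.exponential(
            config.kataegis.imd_mean_bp, size=n_mut - 1)).astype(int)
        positions = start + np.concatenate([[0], np.cumsum(gaps)])
        positions = positions[positions < genome.lengths[chrom] - 2]
        placed = []
        seq = seqs[chrom]
        for p in positions.tolist():
            # walk to the nearest C/G so the shower is C>T / C>G
            q = None
            for off in range(0, 20):
                cand = p + off
                if cand >= genome.lengths[chrom] - 1:
                    break
                if seq[cand - 1] in "CG":
                    q = cand
                    break
            if q is None or (chrom, q) in seen:
                continue
            seen.add((chrom, q))
            ref = seq[q - 1]
            if ref == "C":
                alt = "T" if rng.random() < 0.55 else "G"
            else:           # G on forward = C on pyrimidine strand
                alt = "A" if rng.random() < 0.55 else "C"
            out.append(SNVRecord(sample_id=sid, chrom=chrom, pos=q, ref=ref,
                                 alt=alt, **_support_counts(rng)))
            placed.append(q)
        if len(placed) >= 6:
            truth.kataegis_foci.append((chrom, min(placed), max(placed)))
            truth.kataegis_phase.append(0)   # same parental chromosome
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _largest_remainder(fracs: Mapping[str, float], n: int) -> Dict[str, int]:
    raw = {k: v * n for k, v in fracs.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    remaining = n - sum(out.values())
    order = sorted(raw, key=lambda k: raw[k] - out[k], reverse=True)
    for k in order[:remaining]:
        out[k] += 1
    return out


def simulate_cohort(config: Optional[CohortConfig] = None
                    ) -> Tuple[List[SampleCatalog], TruthTable, GenomeModel,
                               Dict[str, str], RegionSet]:
    """Simulate a full cohort: catalogs, truth, genome, reference, regions.

    Deterministic under ``config.seed``: a fixed seed yields byte-identical
    FASTA, catalogs and truth.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)
    genome, seqs = simulate_genome(
        len(chroms), [config.chrom_lengths[c] for c in chroms],
        seed=int(rng.integers(0, 2 ** 31 - 1)), names=chroms)
    coding = default_coding_regions(genome)
    ctx_index = ContextIndex(seqs, coding)
    signatures = default_signatures()

    n = config.n_samples
    ids = [f"S{i + 1:03d}" for i in range(n)]
    truths = {s: SampleTruth(sample_id=s) for s in ids}

    # --- assignments (deterministic counts, randomized membership) ---
    n_tdp = int(round(config.tdp_fraction * n))
    tdp_ids = list(rng.choice(ids, size=n_tdp, replace=False))
    group_counts = _largest_remainder(config.tdp_group_probs, n_tdp)
    pool = list(tdp_ids)
    rng.shuffle(pool)
    cursor = 0
    for group, k in group_counts.items():
        for s in pool[cursor:cursor + k]:
            truths[s].is_tdp = True
            truths[s].tdp_group = group
        cursor += k

    n_hyper = int(round(config.burden.hyper_fraction * n))
    for s in rng.choice(ids, size=n_hyper, replace=False):
        truths[s].is_hypermutated = True
    for s in ids:
        b = config.burden
        base = b.hyper_rate_per_mb if truths[s].is_hypermutated \
            else b.regular_rate_per_mb
        truths[s].mutation_rate_per_mb = float(
            10 ** (np.log10(base) + rng.normal(0, b.rate_log10_sd)))

    ct = config.chromothripsis
    for s in rng.choice(ids, size=int(round(ct.sample_fraction * n)),
                        replace=False):
        truths[s].chromothripsis_regions.append((ct.chrom, ct.start, ct.end))

    fb = config.foldback
    for s in rng.choice(ids, size=int(round(fb.sample_fraction * n)),
                        replace=False):
        truths[s].foldbacks.append((fb.chrom, fb.position, fb.separation))
        truths[s].bfb_loci.append((fb.chrom, fb.amplicon[0], fb.amplicon[1]))

    kt = config.kataegis
    for s in rng.choice(ids, size=int(round(kt.sample_fraction * n)),
                        replace=False):
        truths[s].n_kataegis_foci_planned = kt.foci_per_sample

    for s in ids:
        for i, locus in enumerate(config.hotspots):
            if rng.random() < locus.hit_prob:
                truths[s].hotspot_hits.append(i)

    conc = config.exposure_dirichlet_conc
    for s in ids:
        weights = {}
        for region, base in (("coding", config.coding_exposure),
                             ("noncoding", config.noncoding_exposure)):
            alpha = np.array([max(base[k], 1e-3) * conc for k in signatures])
            draw = rng.dirichlet(alpha)
            # keep structural zeros structural
            w = {k: (0.0 if base[k] == 0 else float(d))
                 for k, d in zip(signatures, draw)}
            tot = sum(w.values())
            weights[region] = {k: v / tot for k, v in w.items()}
        truths[s].true_exposure_weights = weights

    # --- generation ---
    catalogs = []
    for s in ids:
        t = truths[s]
        svs = simulate_sv_catalog(genome, config, t, rng)
        cn = simulate_cn_profile(genome, svs, truth=t,
                                 window_bp=config.cn_window_bp,
                                 noise_sd=config.cn_noise_sd, rng=rng,
                                 config=config)
        snvs = simulate_snvs(genome, seqs, config, t, svs, signatures,
                             ctx_index, coding, rng)
        catalogs.append(SampleCatalog(
            sample_id=s, svs=svs, snvs=snvs, cn_segments=cn,
            metadata={"ploidy": 2.0,
                      "genome_doubled": bool(rng.random() < 0.3),
                      "is_tdp_truth": t.is_tdp}))

    truth_table = TruthTable(
        samples=truths,
        hotspot_loci=list(config.hotspots),
        signatures={k: v.tolist() for k, v in signatures.items()})
    return catalogs, truth_table, genome, seqs, coding
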