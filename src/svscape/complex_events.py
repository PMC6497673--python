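"""Fold-back inversion / BFB inference, chromothripsis statistics, kataegis.

Fold-back inversions — the junction hallmark of breakage-fusion-bridge
(BFB) cycles — are single inverted junctions without a reciprocal
support-read cluster whose two breakends lie close together (<30 kb) and
which coincide with a significant copy-number step (BH q < 0.001 across all
cohort candidates).  A BFB locus additionally requires a co-localized
high-level amplification (integer CN >= 5 within 1 Mb) and telomeric
copy-number loss distal to the fold-back.

Chromothripsis is screened with two statistics on each chromosome arm:
(1) clustering of breakpoints — under random breakage the distances between
adjacent genome-sorted breakpoints are exponential with the empirical mean,
assessed by a parametric-bootstrap goodness-of-fit test; and (2) randomness
of fragment joins — the four join orientations (deletion-type, TD-type,
head-to-head, tail-to-tail) should be Multinomial(n, 1/4 each), assessed by
a goodness-of-fit test that must NOT reject.  A call further requires >10
intra-arm rearrangements and copy-number oscillation between 2-3 states
covering >=90% of the rearranged region.

Kataegis foci are runs of >= 6 consecutive SNVs with inter-mutation
distances <= 1 kb that colocalize with an SV breakpoint (<= 10 kb) and are
significantly enriched for C>T/C>G relative to the sample's genome-wide
fraction.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .catalog_io import CNSegment, GenomeModel, SNVRecord, SVRecord

logger = logging.getLogger(__name__)

JOIN_TYPES = ("del", "td", "hh", "tt")


# ---------------------------------------------------------------------------
# Fold-back inversions / BFB
# ---------------------------------------------------------------------------

@dataclass
class FoldbackCall:
    sample_id: str
    chrom: str
    pos1: int
    pos2: int
    strands: Tuple[str, str]
    separation: int
    cn_step_log2r: Optional[float]
    p_cn: Optional[float]
    q_cn: Optional[float] = None
    passes: Dict[str, bool] = field(default_factory=dict)
    called: bool = False


@dataclass
class BFBCall:
    sample_id: str
    chrom: str
    foldback_pos: int
    amp_start: int
    amp_end: int
    amp_cn: float
    has_telomere_loss: bool
    called: bool


def _flank_log2r(segments: Sequence[CNSegment], chrom: str,
                 lo: int, hi: int) -> np.ndarray:
    """log2R values of segments whose midpoint lies in [lo, hi]."""
    vals = [s.log2r for s in segments
            if s.chrom == chrom and lo <= (s.start + s.end) // 2 <= hi]
    return np.asarray(vals, dtype=float)


def detect_foldback_inversions(svs: Sequence[SVRecord],
                               segments: Sequence[CNSegment],
                               sep_max: int = 30_000,
                               q_max: float = 0.001,
                               flank_bp: int = 100_000
                               ) -> List[FoldbackCall]:
    """Detect fold-back inversions across a cohort.

    ``svs`` and ``segments`` may span multiple samples; candidates are
    inversion-orientation intra-chromosomal records without a reciprocal
    cluster.  The copy-number step at the junction is tested by a
    Welch-type comparison of per-window log2R in ``flank_bp`` flanks on
    either side, with BH adjustment across all cohort candidates; a call
    requires separation < ``sep_max`` and q < ``q_max``.
    """
    seg_by_sample: Dict[str, List[CNSegment]] = {}
    for s in segments:
        seg_by_sample.setdefault(s.sample_id, []).append(s)

    calls: List[FoldbackCall] = []
    for r in svs:
        if not r.intra or r.join_type not in ("hh", "tt"):
            continue
        if r.has_reciprocal_cluster:
            continue
        sep = r.pos2 - r.pos1
        segs = seg_by_sample.get(r.sample_id, [])
        left = _flank_log2r(segs, r.chrom1, r.pos1 - flank_bp, r.pos1 - 1)
        right = _flank_log2r(segs, r.chrom1, r.pos2 + 1, r.pos2 + flank_bp)
        if len(left) < 2 or len(right) < 2:
            logger.info("foldback candidate %s %s:%d lacks flanking "
                        "segments; skipped", r.sample_id, r.chrom1, r.pos1)
            continue
        if np.std(left) == 0 and np.std(right) == 0:
            p = 0.0 if left.mean() != right.mean() else 1.0
        else:
            _, p = stats.ttest_ind(left, right, equal_var=False)
        calls.append(FoldbackCall(
            sample_id=r.sample_id, chrom=r.chrom1, pos1=r.pos1, pos2=r.pos2,
            strands=(r.strand1, r.strand2), separation=sep,
            cn_step_log2r=float(right.mean() - left.mean()),
            p_cn=float(p),
            passes={"no_reciprocal": True, "separation": sep < sep_max}))
    if not calls:
        return calls
    from statsmodels.stats.multitest import multipletests

    q = multipletests([c.p_cn for c in calls], method="fdr_bh")[1]
    for c, qv in zip(calls, q):
        c.q_cn = float(qv)
        c.passes["cn_change"] = qv < q_max
        c.called = all(c.passes.values())
    return calls


def infer_bfb(foldbacks: Sequence[FoldbackCall],
              segments: Sequence[CNSegment],
              genome: GenomeModel,
              amp_min: int = 5,
              max_dist_bp: int = 1_000_000,
              ploidy: Mapping[str, float] | float = 2.0,
              loss_cover_min: float = 0.9) -> List[BFBCall]:
    """Flag BFB-amplified loci: a called fold-back co-localized (<=1 Mb)
    with a high-level amplification (integer CN >= ``amp_min``) plus
    telomeric copy-number loss from the fold-back to the chromosome end
    distal to the fold (strand-determined direction).

    Missing integer CN falls back to log2R thresholds (logged):
    amplification log2R >= log2(amp_min/2), loss log2R < 0.
    """
    seg_by_sample: Dict[str, List[CNSegment]] = {}
    for s in segments:
        seg_by_sample.setdefault(s.sample_id, []).append(s)

    def sample_ploidy(sid: str) -> float:
        if isinstance(ploidy, Mapping):
            return float(ploidy.get(sid, 2.0))
        return float(ploidy)

    calls: List[BFBCall] = []
    for fb in foldbacks:
        if not fb.called:
            continue
        segs = [s for s in seg_by_sample.get(fb.sample_id, [])
                if s.chrom == fb.chrom]
        if not segs:
            continue

        def cn_of(seg: CNSegment) -> float:
            if seg.copy_number is not None:
                return float(seg.copy_number)
            return 2.0 * 2 ** seg.log2r

        has_int = all(s.copy_number is not None for s in segs)
        if not has_int:
            logger.info("infer_bfb: %s %s missing integer CN; using log2R "
                        "thresholds", fb.sample_id, fb.chrom)
        amp = [s for s in segs
               if cn_of(s) >= amp_min
               and s.start <= fb.pos2 + max_dist_bp
               and s.end >= fb.pos1 - max_dist_bp]
        # loss side: head-to-head folds retain the proximal (left) segment,
        # so loss runs rightward to the telomere; tail-to-tail the reverse
        if fb.strands == ("+", "+"):
            lo, hi = fb.pos2 + 1, genome.lengths[fb.chrom]
        else:
            lo, hi = 1, fb.pos1 - 1
        base = round(sample_ploidy(fb.sample_id))
        tot = covered = 0
        for s in segs:
            o_lo, o_hi = max(s.start, lo), min(s.end, hi)
            if o_lo > o_hi:
                continue
            length = o_hi - o_lo + 1
            tot += length
            if cn_of(s) < base:
                covered += length
        telomere_loss = tot > 0 and covered / tot >= loss_cover_min
        if amp:
            amp_start = min(s.start for s in amp)
            amp_end = max(s.end for s in amp)
            amp_cn = max(cn_of(s) for s in amp)
        else:
            amp_start = amp_end = 0
            amp_cn = float("nan")
        calls.append(BFBCall(
            sample_id=fb.sample_id, chrom=fb.chrom, foldback_pos=fb.pos1,
            amp_start=amp_start, amp_end=amp_end, amp_cn=amp_cn,
            has_telomere_loss=telomere_loss,
            called=bool(amp) and telomere_loss))
    return calls


# ---------------------------------------------------------------------------
# Chromothripsis statistics
# ---------------------------------------------------------------------------

def _ks_exponential(x: np.ndarray) -> float:
    """KS statistic of a sample against Exp(mean(x)) (2D batched)."""
    x = np.sort(x, axis=-1)
    m = x.shape[-1]
    scale = x.mean(axis=-1, keepdims=True)
    cdf = 1.0 - np.exp(-x / np.maximum(scale, 1e-300))
    i = np.arange(1, m + 1)
    d_plus = (i / m - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / m).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def chromothripsis_spacing_test(positions: Sequence[int],
                                n_boot: int = 500,
                                seed: int = 0,
                                window: Optional[Tuple[int, int]] = None
                                ) -> Optional[float]:
    """Goodness-of-fit p for exponential inter-breakpoint spacings.

    The null of random breakage implies adjacent spacings are exponential
    with the empirical mean; because the mean is estimated from the same
    data, the null distribution of the KS statistic is obtained by
    parametric bootstrap (``n_boot`` resamples).  Small p indicates
    clustering.  Fewer than 10 breakpoints: undefined (None).

    With ``window`` = (start, end) of the observation window (e.g. the
    chromosome arm), the two boundary gaps are included as spacings: under
    a homogeneous Poisson null they are exponential too (memorylessness),
    and they make clustering detectable even when every breakpoint on the
    arm belongs to one cluster.

    p is #{bootstrap >= observed}/n_boot, so maximally clustered arms reach
    p = 0 and remain significant after multiplicity adjustment.
    """
    positions = np.sort(np.asarray(positions, dtype=float))
    n = len(positions)
    if n < 10:
        return None
    spacings = np.maximum(np.diff(positions), 1e-9)
    if window is not None:
        lo, hi = window
        spacings = np.concatenate([
            [max(positions[0] - lo, 1e-9)], spacings,
            [max(hi - positions[-1], 1e-9)]])
    obs = float(_ks_exponential(spacings[None, :])[0])
    rng = np.random.default_rng(seed)
    boot = rng.exponential(spacings.mean(), size=(n_boot, len(spacings)))
    boot_stats = _ks_exponential(boot)
    return float((boot_stats >= obs).mean())


def chromothripsis_join_test(counts: Sequence[int],
                             exact_max_n: int = 39) -> Optional[float]:
    """Goodness-of-fit p of the four join-orientation counts against
    Multinomial(n, 1/4 each).

    Chi-square for n >= 40; exact multinomial enumeration (summing the
    probability of all outcomes with chi-square statistic >= observed)
    below.  Large p is *consistent* with random joins.  Total < 10:
    undefined (None).
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (4,):
        raise ValueError("expected 4 join-orientation counts")
    n = int(counts.sum())
    if n < 10:
        return None
    expected = n / 4.0
    obs_stat = float(((counts - expected) ** 2 / expected).sum())
    if n > exact_max_n:
        return float(stats.chisquare(counts).pvalue)
    # exact enumeration over all compositions of n into 4 parts
    outcomes = []
    for a in range(n + 1):
        for b in range(n - a + 1):
            for c in range(n - a - b + 1):
                outcomes.append((a, b, c, n - a - b - c))
    outcomes = np.asarray(outcomes)
    stat = ((outcomes - expected) ** 2 / expected).sum(axis=1)
    pmf = stats.multinomial.pmf(outcomes, n=n, p=[0.25] * 4)
    return float(pmf[stat >= obs_stat - 1e-12].sum())


@dataclass
class ChromothripsisCall:
    sample_id: str
    chrom: str
    arm: str
    region_start: int
    region_end: int
    n_rearrangements: int
    p_spacing: Optional[float]
    q_spacing: Optional[float]
    p_joins: Optional[float]
    n_cn_states: Optional[int]
    verdict: bool
    undetermined: bool = False


def _cn_states_in_region(segments: Sequence[CNSegment], chrom: str,
                         start: int, end: int,
                         cover_min: float = 0.9) -> Optional[int]:
    """Number of integer CN states needed to cover >= ``cover_min`` of the
    region (length-weighted); None when integer CN is unavailable."""
    cover: Dict[int, int] = {}
    total = 0
    for s in segments:
        if s.chrom != chrom:
            continue
        lo, hi = max(s.start, start), min(s.end, end)
        if lo > hi:
            continue
        if s.copy_number is None:
            return None
        length = hi - lo + 1
        total += length
        cover[s.copy_number] = cover.get(s.copy_number, 0) + length
    if total == 0:
        return None
    fracs = sorted(cover.values(), reverse=True)
    acc = 0
    for i, f in enumerate(fracs, start=1):
        acc += f
        if acc / total >= cover_min:
            return i
    return len(fracs)


def call_chromothripsis(svs: Sequence[SVRecord],
                        segments: Sequence[CNSegment],
                        genome: GenomeModel,
                        min_rearr: int = 10,
                        alpha: float = 0.05,
                        join_alpha: float = 0.05,
                        n_boot: int = 500,
                        seed: int = 0,
                        region_gamma: float = 10.0) -> List[ChromothripsisCall]:
    """Screen every chromosome arm of one sample for chromothripsis.

    Per arm with >= 10 intra-arm breakpoints: the spacing test (boundary
    gaps included) must be significant after BH adjustment across the
    sample's tested arms (q <= ``alpha``); the candidate rearranged region
    is then refined to the densest piecewise-constant segment of the arm's
    log10 inter-breakpoint distances, and within it the join test must NOT
    reject randomness (p > ``join_alpha``), more than ``min_rearr``
    rearrangements are required, and the copy-number profile must oscillate
    between 2-3 states covering >= 90% of the region.  Arms without usable
    copy number yield an undetermined verdict.
    """
    from statsmodels.stats.multitest import multipletests
    from .hotspots import intermutation_log_distances, pcf

    sample_id = svs[0].sample_id if svs else "sample"
    calls: List[ChromothripsisCall] = []
    for chrom in genome.names:
        for arm in ("p", "q"):
            lo, hi = genome.arm_bounds(chrom, arm)
            recs = [r for r in svs
                    if r.intra and r.chrom1 == chrom
                    and lo <= r.pos1 <= hi and lo <= r.pos2 <= hi]
            bps = sorted(p for r in recs for p in (r.pos1, r.pos2))
            if len(bps) < 10:
                continue
            arm_seed = seed + (zlib.crc32(f"{chrom}:{arm}".encode())
                               % 100_000)
            p_spacing = chromothripsis_spacing_test(bps, n_boot=n_boot,
                                                    seed=arm_seed,
                                                    window=(lo, hi))
            # refine the rearranged region to the densest PCF segment
            values = intermutation_log_distances(np.asarray(bps))
            segs_pcf = pcf(values, gamma=region_gamma,
                           kmin=min(10, max(1, len(values))))
            big = [s for s in segs_pcf if s.length + 1 >= 10]
            target = min(big or segs_pcf, key=lambda s: s.mean)
            region_bps = bps[target.start:target.end + 2]
            # dense core: shortest window holding 80% of the segment's
            # breakpoints, trimming contaminated boundaries
            m = len(region_bps)
            k = max(int(np.ceil(0.8 * m)), min(m, 10))
            spans = [region_bps[i + k - 1] - region_bps[i]
                     for i in range(m - k + 1)]
            i0 = int(np.argmin(spans))
            region_start = region_bps[i0]
            region_end = region_bps[i0 + k - 1]
            region_recs = [r for r in recs
                           if region_start <= r.pos1 <= region_end
                           and region_start <= r.pos2 <= region_end]
            joins = [0, 0, 0, 0]
            for r in region_recs:
                joins[JOIN_TYPES.index(r.join_type)] += 1
            p_joins = chromothripsis_join_test(joins)
            sample_segs = [s for s in segments if s.sample_id == sample_id]
            n_states = _cn_states_in_region(sample_segs, chrom,
                                            region_start, region_end)
            calls.append(ChromothripsisCall(
                sample_id=sample_id, chrom=chrom, arm=arm,
                region_start=region_start, region_end=region_end,
                n_rearrangements=len(region_recs),
                p_spacing=p_spacing, q_spacing=None, p_joins=p_joins,
                n_cn_states=n_states, verdict=False,
                undetermined=n_states is None))
    tested = [c for c in calls if c.p_spacing is not None]
    if tested:
        q = multipletests([c.p_spacing for c in tested], method="fdr_bh")[1]
        for c, qv in zip(tested, q):
            c.q_spacing = float(qv)
    for c in calls:
        if c.undetermined:
            continue
        c.verdict = (
            c.q_spacing is not None and c.q_spacing <= alpha
            and c.p_joins is not None and c.p_joins > join_alpha
            and c.n_rearrangements > min_rearr
            and c.n_cn_states in (2, 3))
    return calls


# ---------------------------------------------------------------------------
# Kataegis
# ---------------------------------------------------------------------------

@dataclass
class KataegisFocus:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_imd: float
    dist_to_breakpoint: Optional[int]
    ctcg_fraction: float
    enrichment_p: float
    called: bool


def _is_ctcg(ref: str, alt: str) -> bool:
    """C>T or C>G on the pyrimidine strand."""
    pair = (ref.upper(), alt.upper())
    return pair in (("C", "T"), ("G", "A"), ("C", "G"), ("G", "C"))


def detect_kataegis(snvs: Sequence[SNVRecord],
                    svs: Sequence[SVRecord],
                    imd_max: int = 1_000,
                    min_mut: int = 6,
                    colocal_max: int = 10_000,
                    alpha: float = 0.05) -> List[KataegisFocus]:
    """Detect kataegis foci in one sample.

    Candidate clusters are maximal runs of >= ``min_mut`` consecutive SNVs
    with inter-mutation distance <= ``imd_max``; a focus is called when the
    nearest SV breakpoint is <= ``colocal_max`` away and the cluster's
    C>T + C>G fraction significantly exceeds the sample's genome-wide
    fraction (one-sided binomial).  Order-invariant (inputs are sorted
    internally).
    """
    sample_id = snvs[0].sample_id if snvs else "sample"
    all_ctcg = sum(1 for r in snvs if _is_ctcg(r.ref, r.alt))
    background = all_ctcg / len(snvs) if snvs else 0.0

    breakends: Dict[str, np.ndarray] = {}
    for r in svs:
        breakends.setdefault(r.chrom1, []).append(r.pos1)
        breakends.setdefault(r.chrom2, []).append(r.pos2)
    breakends = {c: np.sort(np.asarray(p)) for c, p in breakends.items()}

    def nearest_breakpoint(chrom: str, lo: int, hi: int) -> Optional[int]:
        pos = breakends.get(chrom)
        if pos is None or len(pos) == 0:
            return None
        inside = pos[(pos >= lo) & (pos <= hi)]
        if len(inside):
            return 0
        i = np.searchsorted(pos, lo)
        best = np.inf
        if i > 0:
            best = min(best, lo - pos[i - 1])
        if i < len(pos):
            best = min(best, pos[i] - hi if pos[i] > hi else abs(pos[i] - lo))
        return int(best)

    foci: List[KataegisFocus] = []
    by_chrom: Dict[str, List[SNVRecord]] = {}
    for r in snvs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.pos)
        run: List[SNVRecord] = []

        def flush(run):
            if len(run) < min_mut:
                return
            positions = [r.pos for r in run]
            lo, hi = positions[0], positions[-1]
            imds = np.diff(positions)
            ctcg = sum(1 for r in run if _is_ctcg(r.ref, r.alt))
            dist = nearest_breakpoint(chrom, lo, hi)
            p_enr = stats.binomtest(ctcg, len(run),
                                    max(min(background, 1.0), 1e-12),
                                    alternative="greater").pvalue
            called = (dist is not None and dist <= colocal_max
                      and p_enr < alpha)
            foci.append(KataegisFocus(
                sample_id=sample_id, chrom=chrom, start=lo, end=hi,
                n_mutations=len(run),
                mean_imd=float(imds.mean()) if len(imds) else 0.0,
                dist_to_breakpoint=dist,
                ctcg_fraction=ctcg / len(run),
                enrichment_p=float(p_enr), called=called))

        for r in recs:
            if run and r.pos - run[-1].pos <= imd_max:
                run.append(r)
            else:
                flush(run)
                run = [r]
        flush(run)
    return foci
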