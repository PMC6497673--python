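"""Fold-back/BFB inference, chromothripsis statistics, kataegis detection."""

import numpy as np
import pytest

from svscape.catalog_io import CNSegment, GenomeModel, SNVRecord, SVRecord
from svscape.complex_events import (call_chromothripsis,
                                    chromothripsis_join_test,
                                    chromothripsis_spacing_test,
                                    detect_foldback_inversions,
                                    detect_kataegis, infer_bfb)


def _genome(**lengths):
    return GenomeModel(names=tuple(lengths), lengths=lengths)


def _windows(sample, chrom, length, cn_by_region, baseline=2,
             window=10_000, noise=0.05, seed=0):
    """Windowed CN profile; cn_by_region = [(start, end, cn)] overrides."""
    rng = np.random.default_rng(seed)
    segs = []
    for s in range(1, length + 1, window):
        e = min(s + window - 1, length)
        mid = (s + e) // 2
        cn = baseline
        for a, b, v in cn_by_region:
            if a <= mid <= b:
                cn = v
        log2r = np.log2(max(cn, 0.25) / 2) + rng.normal(0, noise)
        segs.append(CNSegment(sample, chrom, s, e, float(log2r), cn))
    return segs


# ---------------------------------------------------------------------------
# fold-back inversions
# ---------------------------------------------------------------------------

def _fb(sample, chrom, pos, sep, reciprocal=False):
    return SVRecord(sample, chrom, pos, "+", chrom, pos + sep, "+",
                    "FB_INV", has_reciprocal_cluster=reciprocal)


def test_foldback_with_cn_step_called():
    g = _genome(c1=3_000_000)
    svs = [_fb("s1", "c1", 1_500_000, 5_000)]
    segs = _windows("s1", "c1", 3_000_000,
                    [(1_000_000, 1_500_000, 6)])
    calls = detect_foldback_inversions(svs, segs)
    assert len(calls) == 1 and calls[0].called
    assert calls[0].separation == 5_000


def test_foldback_wide_separation_rejected():
    g = _genome(c1=3_000_000)
    svs = [_fb("s1", "c1", 1_500_000, 40_000)]
    segs = _windows("s1", "c1", 3_000_000, [(1_000_000, 1_500_000, 6)])
    calls = detect_foldback_inversions(svs, segs)
    assert len(calls) == 1 and not calls[0].called
    assert not calls[0].passes["separation"]


def test_foldback_reciprocal_pair_not_candidate():
    svs = [_fb("s1", "c1", 1_500_000, 5_000, reciprocal=True)]
    segs = _windows("s1", "c1", 3_000_000, [(1_000_000, 1_500_000, 6)])
    assert detect_foldback_inversions(svs, segs) == []


def test_foldback_flat_cn_not_called():
    svs = [_fb("s1", "c1", 1_500_000, 5_000)]
    segs = _windows("s1", "c1", 3_000_000, [])
    calls = detect_foldback_inversions(svs, segs)
    assert len(calls) == 1 and not calls[0].called


def test_foldback_order_invariance():
    rng = np.random.default_rng(1)
    svs = [_fb(f"s{i}", "c1", 500_000 + 200_000 * i, 5_000)
           for i in range(5)]
    segs = []
    for i in range(5):
        segs += _windows(f"s{i}", "c1", 3_000_000,
                         [(1, 500_000 + 200_000 * i, 6)], seed=i)
    a = detect_foldback_inversions(svs, segs)
    shuffled = list(svs)
    rng.shuffle(shuffled)
    b = detect_foldback_inversions(shuffled, segs)
    key = lambda calls: sorted((c.sample_id, c.pos1, c.called)
                               for c in calls)
    assert key(a) == key(b)


# ---------------------------------------------------------------------------
# BFB
# ---------------------------------------------------------------------------

def test_bfb_planted_called():
    g = _genome(c1=3_000_000)
    svs = [_fb("s1", "c1", 2_000_000, 5_000)]
    segs = _windows("s1", "c1", 3_000_000,
                    [(1_700_000, 2_000_000, 8),
                     (2_005_001, 3_000_000, 1)])
    fbs = detect_foldback_inversions(svs, segs)
    calls = infer_bfb(fbs, segs, g)
    assert len(calls) == 1 and calls[0].called
    assert calls[0].amp_cn >= 5 and calls[0].has_telomere_loss


def test_bfb_without_telomere_loss_not_called():
    g = _genome(c1=3_000_000)
    svs = [_fb("s1", "c1", 2_000_000, 5_000)]
    segs = _windows("s1", "c1", 3_000_000, [(1_700_000, 2_000_000, 8)])
    fbs = detect_foldback_inversions(svs, segs)
    calls = infer_bfb(fbs, segs, g)
    assert len(calls) == 1 and not calls[0].called
    assert not calls[0].has_telomere_loss


def test_bfb_amplification_without_foldback_not_called():
    g = _genome(c1=3_000_000)
    segs = _windows("s1", "c1", 3_000_000,
                    [(1_700_000, 2_000_000, 8),
                     (2_005_001, 3_000_000, 1)])
    assert infer_bfb([], segs, g) == []


# ---------------------------------------------------------------------------
# spacing test
# ---------------------------------------------------------------------------

def test_spacing_clustered_significant():
    rng = np.random.default_rng(2)
    # 50 breakpoints packed into 1% of a 100 Mb chromosome
    positions = np.sort(rng.integers(40_000_000, 41_000_000, size=50))
    p = chromothripsis_spacing_test(positions, seed=0,
                                    window=(1, 100_000_000))
    assert p is not None and p < 1e-3


def test_spacing_exponential_null_not_extreme():
    rng = np.random.default_rng(3)
    positions = 1 + np.cumsum(rng.exponential(50_000, size=60))
    p = chromothripsis_spacing_test(positions, seed=0)
    assert p > 0.01


def test_spacing_too_few_breakpoints_undefined():
    assert chromothripsis_spacing_test([1, 2, 3, 4, 5]) is None


# ---------------------------------------------------------------------------
# join test
# ---------------------------------------------------------------------------

def test_join_perfect_fit():
    assert chromothripsis_join_test([25, 25, 25, 25]) == pytest.approx(1.0)


def test_join_degenerate_rejects():
    assert chromothripsis_join_test([100, 0, 0, 0]) < 1e-10


def test_join_exact_matches_chisquare_asymptotics():
    # exact (n<=39) and chi-square branches should agree roughly at n=36
    counts = [14, 9, 7, 6]
    p_exact = chromothripsis_join_test(counts, exact_max_n=39)
    p_chi2 = chromothripsis_join_test(counts, exact_max_n=10)
    assert abs(p_exact - p_chi2) < 0.1


def test_join_small_total_undefined():
    assert chromothripsis_join_test([2, 2, 2, 2]) is None


# ---------------------------------------------------------------------------
# chromothripsis calling
# ---------------------------------------------------------------------------

def _chromothriptic_sample(seed, joins="uniform"):
    g = _genome(c1=6_000_000, c2=5_000_000)
    rng = np.random.default_rng(seed)
    svs = []
    # planted shattering on c1 p-arm (arm = 1..3 Mb): 0.4-0.8 Mb
    states = []
    orient = {"uniform": [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")],
              "del_only": [("+", "-")]}[joins]
    for _ in range(35):
        a, b = sorted(rng.integers(400_000, 800_000, size=2).tolist())
        while b - a < 100:
            a, b = sorted(rng.integers(400_000, 800_000, size=2).tolist())
        s1, s2 = orient[rng.integers(len(orient))]
        svs.append(SVRecord("s1", "c1", int(a), s1, "c1", int(b), s2,
                            "OTHER"))
    # background elsewhere
    for _ in range(20):
        chrom = "c2"
        a = int(rng.integers(1, 4_000_000))
        svs.append(SVRecord("s1", chrom, a, "+", chrom, a + 30_000, "-",
                            "DEL"))
    # oscillating CN inside the region
    bps = sorted(p for r in svs if r.chrom1 == "c1"
                 for p in (r.pos1, r.pos2))
    pts = [400_000] + bps + [800_000]
    cn_regions = [(pts[i], pts[i + 1] - 1, 2 + (i % 2))
                  for i in range(len(pts) - 1)]
    segs = _windows("s1", "c1", 6_000_000, cn_regions, window=5_000,
                    seed=seed)
    segs += _windows("s1", "c2", 5_000_000, [], window=5_000, seed=seed + 1)
    return g, svs, segs


def test_chromothripsis_planted_called():
    g, svs, segs = _chromothriptic_sample(10)
    calls = call_chromothripsis(svs, segs, g, seed=0)
    hit = [c for c in calls if c.chrom == "c1" and c.arm == "p"]
    assert hit and hit[0].verdict
    assert hit[0].n_cn_states in (2, 3)


def test_chromothripsis_del_only_joins_rejected():
    g, svs, segs = _chromothriptic_sample(11, joins="del_only")
    calls = call_chromothripsis(svs, segs, g, seed=0)
    hit = [c for c in calls if c.chrom == "c1" and c.arm == "p"]
    assert hit and not hit[0].verdict
    assert hit[0].p_joins is not None and hit[0].p_joins <= 0.05


def test_chromothripsis_quiet_arm_not_called():
    g = _genome(c1=6_000_000)
    rng = np.random.default_rng(12)
    svs = []
    for _ in range(30):
        a = int(rng.integers(1, 5_900_000))
        svs.append(SVRecord("s1", "c1", a, "+", "c1", a + 20_000, "-",
                            "DEL"))
    segs = _windows("s1", "c1", 6_000_000, [], window=5_000)
    calls = call_chromothripsis(svs, segs, g, seed=0)
    assert not any(c.verdict for c in calls)


def test_chromothripsis_no_cn_undetermined():
    g, svs, _ = _chromothriptic_sample(13)
    calls = call_chromothripsis(svs, [], g, seed=0)
    hit = [c for c in calls if c.chrom == "c1" and c.arm == "p"]
    assert hit and hit[0].undetermined and not hit[0].verdict


# ---------------------------------------------------------------------------
# kataegis
# ---------------------------------------------------------------------------

def _shower(sample, chrom, start, n, imd, frac_ctcg=0.9, seed=0):
    rng = np.random.default_rng(seed)
    snvs = []
    pos = start
    for i in range(n):
        pos += int(max(1, rng.exponential(imd)))
        if rng.random() < frac_ctcg:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("C", "G")
        else:
            ref, alt = "T", "A"
        snvs.append(SNVRecord(sample, chrom, pos, ref, alt))
    return snvs


def _background(sample, chrom, n, length, seed=1):
    rng = np.random.default_rng(seed)
    snvs = []
    for p in sorted(rng.integers(1, length, size=n).tolist()):
        ref, alt = [("C", "T"), ("T", "C"), ("C", "A"), ("T", "G")][
            rng.integers(4)]
        snvs.append(SNVRecord(sample, chrom, int(p), ref, alt))
    return snvs


def test_kataegis_planted_shower_detected():
    sv = SVRecord("s1", "c1", 500_000, "-", "c1", 520_000, "+", "TD")
    snvs = _background("s1", "c1", 100, 10_000_000) + \
        _shower("s1", "c1", 498_000, 12, 300)
    foci = [f for f in detect_kataegis(snvs, [sv]) if f.called]
    assert len(foci) == 1
    f = foci[0]
    assert f.n_mutations >= 6
    assert f.dist_to_breakpoint <= 10_000
    assert f.ctcg_fraction > 0.5


def test_kataegis_far_from_breakpoint_rejected():
    sv = SVRecord("s1", "c1", 5_000_000, "-", "c1", 5_020_000, "+", "TD")
    snvs = _background("s1", "c1", 100, 10_000_000) + \
        _shower("s1", "c1", 498_000, 12, 300)
    foci = detect_kataegis(snvs, [sv])
    candidates = [f for f in foci if f.n_mutations >= 6
                  and f.start > 490_000 and f.end < 510_000]
    assert candidates and not candidates[0].called


def test_kataegis_uniform_null_rarely_fires():
    sv = SVRecord("s1", "c1", 5_000_000, "-", "c1", 5_020_000, "+", "TD")
    n_with_calls = 0
    for seed in range(200):
        snvs = _background("s1", "c1", 100, 10_000_000, seed=seed)
        if any(f.called for f in detect_kataegis(snvs, [sv])):
            n_with_calls += 1
    assert n_with_calls / 200 < 0.05


def test_kataegis_order_invariance():
    sv = SVRecord("s1", "c1", 500_000, "-", "c1", 520_000, "+", "TD")
    snvs = _background("s1", "c1", 100, 10_000_000) + \
        _shower("s1", "c1", 498_000, 12, 300)
    rng = np.random.default_rng(3)
    shuffled = list(snvs)
    rng.shuffle(shuffled)
    key = lambda foci: sorted((f.chrom, f.start, f.end, f.called)
                              for f in foci)
    assert key(detect_kataegis(snvs, [sv])) == \
        key(detect_kataegis(shuffled, [sv]))
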