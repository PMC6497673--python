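"""Truth-table evaluation and oracle/null-calibration routines.

These functions measure the pipeline against the synthetic cohort's planted
truth (label recovery) and against independent references: a brute-force
segmentation oracle for the PCF dynamic program, direct formula evaluation
for the TDP score, and simulated-null calibrations for the chromothripsis
statistics.  They back both the test suite and scripts/acceptance.py.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .catalog_io import ReferenceGenome, assign_region_class
from .synthetic_data import CohortConfig, simulate_cohort
from . import tdp as tdp_mod
from . import hotspots as hot_mod
from . import complex_events as cx_mod
from . import burden_signatures as bs_mod


# ---------------------------------------------------------------------------
# PCF brute-force oracle
# ---------------------------------------------------------------------------

def pcf_brute_force(values: Sequence[float], gamma: float, kmin: int
                    ) -> Tuple[float, List[Tuple[int, int]]]:
    """Exhaustive-search optimum of the PCF objective.

    Enumerates every composition of n into segments of length >= kmin and
    returns (optimal objective value, segment index ranges).  Independent of
    the dynamic program: plain recursion over cut positions with
    precomputed segment costs.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def cost(j, i):      # SSE of v[j:i]
        k = i - j
        return s2[i] - s2[j] - (s1[i] - s1[j]) ** 2 / k

    best = [np.inf, None]

    def recurse(start, acc, segs):
        if acc >= best[0]:
            return
        if start == n:
            best[0] = acc
            best[1] = list(segs)
            return
        for end in range(start + kmin, n + 1):
            if n - end != 0 and n - end < kmin:
                continue
            segs.append((start, end - 1))
            recurse(end, acc + cost(start, end) + gamma, segs)
            segs.pop()

    if n < kmin:
        return cost(0, n) + gamma, [(0, n - 1)]
    recurse(0, 0.0, [])
    return best[0], best[1]


def pcf_objective(values: Sequence[float], segments, gamma: float) -> float:
    v = np.asarray(values, dtype=float)
    total = gamma * len(segments)
    for seg in segments:
        chunk = v[seg.start:seg.end + 1]
        total += float(((chunk - chunk.mean()) ** 2).sum())
    return total


def pcf_oracle_check(n_fixtures: int = 500, seed: int = 0,
                     tol: float = 1e-9) -> float:
    """Fraction of random fixtures (n <= 30) on which the dynamic program
    attains the exhaustive-search optimum."""
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_fixtures):
        n = int(rng.integers(5, 31))
        kmin = int(rng.integers(2, 5)) if n <= 20 else int(rng.integers(3, 6))
        gamma = float(rng.uniform(0.2, 10.0))
        v = rng.normal(0, 1, size=n)
        if rng.random() < 0.5:          # planted level shift
            cut = int(rng.integers(1, n))
            v[cut:] += rng.uniform(1, 6)
        segs = hot_mod.pcf(v, gamma=gamma, kmin=kmin)
        obj = pcf_objective(v, segs, gamma)
        opt, _ = pcf_brute_force(v, gamma, kmin)
        if obj <= opt + tol:
            n_ok += 1
    return n_ok / n_fixtures


# ---------------------------------------------------------------------------
# TDP formula oracle and null behaviour
# ---------------------------------------------------------------------------

def tdp_oracle_check(n_catalogs: int = 1000, seed: int = 0
                     ) -> Tuple[float, float]:
    """(formula agreement fraction, fraction of uniform-placement catalogs
    with score > -0.6).

    Each catalog draws random per-chromosome TD counts; the score is checked
    against a direct, independent evaluation of
    -sum_i |Obs_i - Exp_i| / TD.  The null rate uses uniform
    length-proportional placement of 50-200 TDs.
    """
    from .catalog_io import GenomeModel, SVRecord

    rng = np.random.default_rng(seed)
    lengths = {"c1": 8_000_000, "c2": 7_000_000, "c3": 5_000_000,
               "c4": 4_000_000}
    genome = GenomeModel(names=tuple(lengths), lengths=lengths)
    total = sum(lengths.values())
    n_agree = 0
    n_null_ok = 0
    for _ in range(n_catalogs):
        # arbitrary (clustered) counts for the formula check
        counts = {c: int(rng.integers(0, 40)) for c in lengths}
        td = sum(counts.values())
        if td == 0:
            counts["c1"] = 1
            td = 1
        svs = []
        for c, k in counts.items():
            for _ in range(k):
                p = int(rng.integers(1, lengths[c] - 10_000))
                svs.append(SVRecord("s", c, p, "-", c, p + 5_000, "+", "TD"))
        score, _ = tdp_mod.tdp_score(svs, genome)
        expected = -sum(abs(counts[c] - td * lengths[c] / total)
                        for c in lengths) / td
        if abs(score - expected) < 1e-9:
            n_agree += 1
        # uniform placement null
        n_td = int(rng.integers(50, 201))
        probs = np.array([lengths[c] for c in lengths], dtype=float)
        null_counts = rng.multinomial(n_td, probs / probs.sum())
        s_null = -sum(abs(o - n_td * l / total)
                      for o, l in zip(null_counts, probs)) / n_td
        if s_null > -0.6:
            n_null_ok += 1
    return n_agree / n_catalogs, n_null_ok / n_catalogs


# ---------------------------------------------------------------------------
# Null calibrations
# ---------------------------------------------------------------------------

def _ks_uniform(pvals: np.ndarray) -> float:
    p = np.sort(np.asarray(pvals, dtype=float))
    n = len(p)
    i = np.arange(1, n + 1)
    return float(max((i / n - p).max(), (p - (i - 1) / n).max()))


def spacing_null_ks(n_reps: int = 2000, n_spacings: int = 50,
                    n_boot: int = 500, seed: int = 0) -> float:
    """KS distance from Uniform(0,1) of spacing-test p-values under the
    exponential null."""
    rng = np.random.default_rng(seed)
    pvals = []
    for rep in range(n_reps):
        gaps = rng.exponential(30_000, size=n_spacings)
        positions = 1 + np.cumsum(gaps)
        p = cx_mod.chromothripsis_spacing_test(
            positions, n_boot=n_boot, seed=int(rng.integers(0, 2 ** 31 - 1)))
        pvals.append(p)
    return _ks_uniform(np.asarray(pvals))


def join_null_ks(n_reps: int = 2000, n_joins: int = 200,
                 seed: int = 0) -> float:
    """KS distance from Uniform(0,1) of join-test p-values under the
    equal-frequency multinomial null."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_reps):
        counts = rng.multinomial(n_joins, [0.25] * 4)
        pvals.append(cx_mod.chromothripsis_join_test(counts))
    return _ks_uniform(np.asarray(pvals))


# ---------------------------------------------------------------------------
# Cohort-level label recovery
# ---------------------------------------------------------------------------

def evaluate_cohort(config: Optional[CohortConfig] = None,
                    detector_seed: int = 7,
                    nmf_seed: int = 1) -> Dict[str, float]:
    """Run every detector on a simulated cohort and score it against truth.

    Returns a flat metric dict (accuracies, recoveries, false-discovery and
    false-positive rates, signature recovery and the coding/noncoding
    exposure contrast).
    """
    config = config or CohortConfig()
    catalogs, truth, genome, seqs, coding = simulate_cohort(config)
    reference = ReferenceGenome(seqs)
    for c in catalogs:
        c.snvs = assign_region_class(c.snvs, coding)
    metrics: Dict[str, float] = {"n_samples": float(len(catalogs))}

    # --- TDP ---
    n_ok = 0
    group_total = group_ok = 0
    for c in catalogs:
        r = tdp_mod.classify_tdp(c.svs, genome, seed=detector_seed)
        t = truth.samples[c.sample_id]
        n_ok += r.is_tdp == t.is_tdp
        if t.is_tdp and r.is_tdp:
            group_total += 1
            group_ok += r.group == t.tdp_group
    metrics["tdp_accuracy"] = n_ok / len(catalogs)
    metrics["tdp_group_recovery"] = (group_ok / group_total
                                     if group_total else float("nan"))

    # --- hotspots ---
    all_svs = [r for c in catalogs for r in c.svs]
    spots = hot_mod.call_all_hotspots(all_svs, genome)
    loci = truth.hotspot_loci
    cat_map = {"short": "short", "modest": "modest", "long": "long",
               "deletion": "deletion"}
    recovered = 0
    for locus in loci:
        hit = any(h.category == cat_map[locus.category]
                  and h.chrom == locus.chrom
                  and h.start <= locus.end and h.end >= locus.start
                  for h in spots)
        recovered += hit
    n_false = 0
    for h in spots:
        ok = False
        for locus in loci:
            if h.category != cat_map[locus.category] \
                    or h.chrom != locus.chrom:
                continue
            pad = int(locus.span_range[1])
            if h.start <= locus.end + pad and h.end >= locus.start - pad:
                ok = True
        n_false += not ok
    metrics["hotspot_recovery"] = recovered / len(loci) if loci else 1.0
    metrics["hotspot_fdr"] = n_false / len(spots) if spots else 0.0

    # --- chromothripsis ---
    tp = fn = fp = nn = 0
    for c in catalogs:
        t = truth.samples[c.sample_id]
        calls = cx_mod.call_chromothripsis(c.svs, c.cn_segments, genome,
                                           seed=detector_seed)
        called = {(x.chrom, x.arm) for x in calls if x.verdict}
        planted = {(ch, genome.arm_of(ch, (s + e) // 2))
                   for ch, s, e in t.chromothripsis_regions}
        for p in planted:
            tp += p in called
            fn += p not in called
        for ch in genome.names:
            for arm in ("p", "q"):
                if (ch, arm) not in planted:
                    nn += 1
                    fp += (ch, arm) in called
    metrics["chromothripsis_sensitivity"] = (tp / (tp + fn)
                                             if tp + fn else float("nan"))
    metrics["chromothripsis_arm_fpr"] = fp / nn if nn else float("nan")

    # --- kataegis ---
    k_tot = k_rec = 0
    for c in catalogs:
        t = truth.samples[c.sample_id]
        foci = [f for f in cx_mod.detect_kataegis(c.snvs, c.svs) if f.called]
        for chrom, lo, hi in t.kataegis_foci:
            k_tot += 1
            k_rec += any(f.chrom == chrom and f.start <= hi and f.end >= lo
                         for f in foci)
    metrics["kataegis_recovery"] = k_rec / k_tot if k_tot else float("nan")

    # --- fold-backs / BFB ---
    all_segs = [s for c in catalogs for s in c.cn_segments]
    fbs = cx_mod.detect_foldback_inversions(all_svs, all_segs)
    bfb = cx_mod.infer_bfb(fbs, all_segs, genome)
    planted_fb = {(s, t.foldbacks[0][0])
                  for s, t in truth.samples.items() if t.foldbacks}
    called_fb = {(f.sample_id, f.chrom) for f in fbs if f.called}
    called_bfb = {(b.sample_id, b.chrom) for b in bfb if b.called}
    metrics["foldback_recovery"] = (len(planted_fb & called_fb)
                                    / len(planted_fb)
                                    if planted_fb else float("nan"))
    metrics["bfb_recovery"] = (len(planted_fb & called_bfb)
                               / len(planted_fb)
                               if planted_fb else float("nan"))
    metrics["bfb_false_calls"] = float(len(called_bfb - planted_fb))

    # --- hypermutation ---
    snv_map = {c.sample_id: c.snvs for c in catalogs}
    points = bs_mod.mutation_rates(snv_map, coding, genome.total_length)
    hyper = bs_mod.classify_hypermutation(points)
    h_ok = sum((hyper.labels[s] == "hypermutated")
               == truth.samples[s].is_hypermutated for s in snv_map)
    metrics["hypermutation_accuracy"] = h_ok / len(snv_map)

    # --- signatures ---
    spectrum = bs_mod.build_spectrum_96(snv_map, reference)
    sigset, _, _ = bs_mod.extract_signatures_nmf(
        spectrum, k_range=range(1, 6), seed=nmf_seed)
    true_sigs = {k: np.asarray(v) for k, v in truth.signatures.items()}
    cosines = {
        name: max(bs_mod.cosine_similarity(v, sigset.profiles[i])
                  for i in range(sigset.k))
        for name, v in true_sigs.items()}
    metrics["signature_min_cosine"] = min(cosines.values())
    metrics["nmf_k_selected"] = float(sigset.k)

    coding_bp = coding.footprint
    region_df = bs_mod.compare_region_exposures(
        snv_map, sigset, reference, coding_bp,
        genome.total_length - coding_bp)
    sims = [bs_mod.cosine_similarity(true_sigs["c_to_a"], sigset.profiles[i])
            for i in range(sigset.k)]
    c2a_name = sigset.names[int(np.argmax(sims))]
    test = region_df.attrs["tests"][c2a_name]
    metrics["c2a_noncoding_coding_ratio"] = test["ratio"]
    metrics["c2a_region_paired_p"] = test["p"]
    return metrics
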