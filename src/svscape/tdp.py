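"""Tandem-duplicator phenotype (TDP) scoring, classification and subgrouping.

A TDP tumor carries frequent tandem duplications spread across the whole
genome.  The score compares the observed per-chromosome TD counts Obs_i with
the counts Exp_i expected if TDs fell proportionally to chromosome length:

    TDP score = - sum_i |Obs_i - Exp_i| / TD

where TD is the total tandem-duplication count.  The score is 0 for a
perfectly length-proportional catalog and grows more negative the more the
TDs concentrate.  A tumor is called TDP when simultaneously
score >= -0.6, TD proportion >= 20% of all SVs, and TD count >= 50
(all boundaries inclusive).

TDP tumors are subgrouped by the modal structure of their TD span-size
distribution (finite Gaussian mixture on log10 span): group 1 for a single
peak in 1.64-51 kb, group 2 for a single peak in 51-622 kb, group 1/2 mix
for peaks in both ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_io import GenomeModel, RegionSet, SVRecord, sv_span

logger = logging.getLogger(__name__)

GROUP1_RANGE_BP = (1_640.0, 51_000.0)
GROUP2_RANGE_BP = (51_000.0, 622_000.0)


@dataclass
class TDPResult:
    sample_id: str
    td_count: int
    per_chrom: pd.DataFrame          # columns: chrom, obs, exp
    tdp_score: Optional[float]
    td_proportion: float
    criteria: Dict[str, bool]
    is_tdp: bool
    group: str = "not_tdp"
    peaks: List[Tuple[float, float]] = field(default_factory=list)


def tdp_score(svs: Sequence[SVRecord], genome: GenomeModel
              ) -> Tuple[Optional[float], pd.DataFrame]:
    """TDP score and the per-chromosome Obs/Exp table.

    Exp_i = TD x effective_length_i / total_effective_length (restricted to a
    callable footprint when the genome model carries one).  Zero TDs yield an
    undefined (None) score rather than an exception.
    """
    tds = [r for r in svs if r.svtype == "TD"]
    obs = {c: 0 for c in genome.names}
    for r in tds:
        if r.chrom1 in obs:
            obs[r.chrom1] += 1
    td = len(tds)
    total = genome.total_effective_length
    exp = {c: td * genome.effective_length(c) / total for c in genome.names}
    table = pd.DataFrame({
        "chrom": list(genome.names),
        "obs": [obs[c] for c in genome.names],
        "exp": [exp[c] for c in genome.names]})
    if td == 0:
        return None, table
    score = -float(sum(abs(obs[c] - exp[c]) for c in genome.names)) / td
    return score, table


def classify_tdp(svs: Sequence[SVRecord], genome: GenomeModel,
                 score_min: float = -0.6,
                 proportion_min: float = 0.20,
                 count_min: int = 50,
                 subgroup: bool = True,
                 seed: int = 0) -> TDPResult:
    """Apply the three TDP criteria conjunctively and subgroup TDP tumors.

    All boundary values pass (the criteria are >= / >= / >=).  Samples with
    no SVs or no TDs are non-TDP with an undefined score.
    """
    score, table = tdp_score(svs, genome)
    td_count = int(table["obs"].sum())
    n_sv = len(svs)
    proportion = td_count / n_sv if n_sv else 0.0
    criteria = {
        "score": score is not None and score >= score_min,
        "proportion": proportion >= proportion_min,
        "count": td_count >= count_min,
    }
    is_tdp = all(criteria.values())
    result = TDPResult(
        sample_id=svs[0].sample_id if svs else "sample",
        td_count=td_count, per_chrom=table, tdp_score=score,
        td_proportion=proportion, criteria=criteria, is_tdp=is_tdp)
    if is_tdp and subgroup:
        spans = [sv_span(r) for r in svs if r.svtype == "TD" and r.intra]
        peaks = fit_span_mixture(np.asarray(spans, dtype=float), seed=seed)
        result.peaks = peaks
        result.group = assign_tdp_group(peaks)
    return result


def td_span_categories(svs: Sequence[SVRecord]) -> Dict[str, int]:
    """Partition TD spans into short (<100 kb), modest (100 kb - 1 Mb,
    boundaries inclusive) and long (>1 Mb)."""
    counts = {"short": 0, "modest": 0, "long": 0}
    for r in svs:
        if r.svtype != "TD" or not r.intra:
            continue
        span = sv_span(r)
        if span < 1e5:
            counts["short"] += 1
        elif span <= 1e6:
            counts["modest"] += 1
        else:
            counts["long"] += 1
    return counts


def fit_span_mixture(spans_bp: np.ndarray,
                     max_components: int = 3,
                     seed: int = 0,
                     min_spans: int = 20,
                     density_frac: float = 0.25
                     ) -> List[Tuple[float, float]]:
    """Fit a Gaussian mixture to log10 TD spans and return its density peaks.

    EM with 10 seed-derived restarts per component count; the component count
    is chosen by BIC (ties toward fewer).  Peaks are the component means
    whose mixture density reaches at least ``density_frac`` of the maximum
    peak density (the 25% rule).  Fewer than ``min_spans`` spans yield no
    peaks (sample not subgroupable).  On EM failure a kernel-density mode
    finder is the logged fallback.
    """
    spans_bp = np.asarray(spans_bp, dtype=float)
    spans_bp = spans_bp[spans_bp > 0]
    if len(spans_bp) < min_spans:
        return []
    x = np.log10(spans_bp).reshape(-1, 1)
    try:
        from sklearn.mixture import GaussianMixture

        best = None
        for k in range(1, max_components + 1):
            if k >= len(x):
                break
            gm = GaussianMixture(n_components=k, n_init=10,
                                 random_state=seed, reg_covar=1e-4)
            gm.fit(x)
            bic = gm.bic(x)
            if best is None or bic < best[0] - 1e-9:
                best = (bic, gm)
        gm = best[1]
        means = gm.means_.ravel()
        dens = np.exp(gm.score_samples(means.reshape(-1, 1)))
    except Exception:                      # pragma: no cover - EM fallback
        logger.warning("mixture EM failed; falling back to KDE modes")
        kde = stats.gaussian_kde(x.ravel())
        grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 512)
        y = kde(grid)
        idx = [i for i in range(1, len(grid) - 1)
               if y[i] >= y[i - 1] and y[i] >= y[i + 1]]
        means = grid[idx]
        dens = y[idx]
    keep = dens >= density_frac * dens.max()
    peaks = sorted(zip(means[keep].tolist(), dens[keep].tolist()))
    return [(float(m), float(d)) for m, d in peaks]


def assign_tdp_group(peaks: Sequence[Tuple[float, float]]) -> str:
    """Subgroup a TDP tumor from its span-distribution peaks.

    Group 1: all peaks in 1.64-51 kb; group 2: all in 51-622 kb; mix12:
    peaks in both ranges; otherwise "other" (including no usable peaks).
    """
    if not peaks:
        return "other"
    ranges_hit = set()
    for log10_bp, _ in peaks:
        bp = 10 ** log10_bp
        if GROUP1_RANGE_BP[0] <= bp <= GROUP1_RANGE_BP[1]:
            ranges_hit.add("1")
        elif GROUP2_RANGE_BP[0] < bp <= GROUP2_RANGE_BP[1]:
            ranges_hit.add("2")
        else:
            ranges_hit.add("out")
    if ranges_hit == {"1"}:
        return "1"
    if ranges_hit == {"2"}:
        return "2"
    if ranges_hit == {"1", "2"}:
        return "mix12"
    return "other"


def breakpoint_region_enrichment(svs: Sequence[SVRecord],
                                 regions: RegionSet,
                                 genome: GenomeModel
                                 ) -> Tuple[Optional[float], Optional[float]]:
    """Exact test of breakpoint enrichment in a region set.

    Each breakend counts once; the in-region count is tested against the
    region footprint fraction of the genome (exact binomial, two-sided).
    Returns (odds ratio vs footprint odds, p).  Undefined (None, None) for
    zero breakpoints or an empty region set.
    """
    footprint = regions.footprint
    total = genome.total_length
    if footprint <= 0 or footprint >= total:
        return None, None
    breakends = []
    for r in svs:
        breakends.append((r.chrom1, r.pos1))
        breakends.append((r.chrom2, r.pos2))
    m = len(breakends)
    if m == 0:
        return None, None
    k = sum(1 for c, p in breakends if regions.contains(c, p))
    f = footprint / total
    p = stats.binomtest(k, m, f, alternative="two-sided").pvalue
    if k == m:
        return float("inf"), float(p)
    odds_obs = (k / m) / (1 - k / m) if k else 0.0
    odds_exp = f / (1 - f)
    return odds_obs / odds_exp, float(p)


def tdp_table(results: Sequence[TDPResult]) -> pd.DataFrame:
    """Cohort TDP summary table (one row per sample)."""
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.sample_id,
            "td_count": r.td_count,
            "tdp_score": r.tdp_score,
            "td_proportion": r.td_proportion,
            "pass_score": r.criteria["score"],
            "pass_proportion": r.criteria["proportion"],
            "pass_count": r.criteria["count"],
            "is_tdp": r.is_tdp,
            "group": r.group,
            "peaks_log10bp": ";".join(f"{m:.3f}" for m, _ in r.peaks),
        })
    return pd.DataFrame(rows)
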