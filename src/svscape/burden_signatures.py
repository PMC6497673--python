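"""Mutation burden, hypermutation classification, 96-context spectra,
NMF signature extraction, exposure refitting and region comparisons.

The 96-channel spectrum follows the canonical pyrimidine-reference order:
six substitution classes C>A, C>G, C>T, T>A, T>C, T>G, each crossed with the
16 flanking-base contexts (5' base major, 3' base minor, both A,C,G,T).
Purine-reference mutations are mapped onto the pyrimidine strand by reverse
complement before counting.

The hypermutation classifier is a density-based outlier rule on the plane of
(genome-wide mutation rate, coding mutation rate): for each retained tumor j
the median Euclidean distance d_j to the other tumors and the local density
rho_j (fraction of tumors closer than the cohort distance scale d_c, the
median over all pairwise distances) are computed; hypermutated tumors are
those with simultaneously low rho_j and high d_j.  Tumors with coding rate
below 1/Mb are excluded up front.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog_io import RegionSet, SNVRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical channel labels, e.g. "A[C>A]A", substitution-major order
CHANNELS: Tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def channel_of(ref: str, alt: str, five: str, three: str) -> Optional[int]:
    """Canonical channel index for a substitution with its flanking bases.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand.  Returns None for non-ACGT input.
    """
    ref, alt = ref.upper(), alt.upper()
    five, three = five.upper(), three.upper()
    if any(b not in _COMP for b in (ref, alt, five, three)):
        return None
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
        five, three = _COMP[three], _COMP[five]
    return _CHANNEL_INDEX.get(f"{five}[{ref}>{alt}]{three}")


def channel_context32(channel: int) -> int:
    """Map a channel (0..95) to its pyrimidine-strand trinucleotide context
    id (0..31): (center is T)*16 + five*4 + three."""
    sub, ctx = divmod(channel, 16)
    return (sub // 3) * 16 + ctx


def channel_parts(channel: int) -> Tuple[str, str, str, str]:
    """(five, ref, alt, three) of a canonical channel."""
    label = CHANNELS[channel]
    return label[0], label[2], label[4], label[6]


# ---------------------------------------------------------------------------
# Burden / hypermutation
# ---------------------------------------------------------------------------

@dataclass
class BurdenPoint:
    """Per-sample mutation rates: genome-wide (x) and coding (y), per Mb."""

    sample_id: str
    x: float
    y: float


@dataclass
class HypermutationResult:
    labels: Dict[str, str]                # sample -> hypermutated/regular/excluded
    d_j: Dict[str, float]
    rho_j: Dict[str, float]
    d_c: float

    def hypermutated_samples(self) -> List[str]:
        return [s for s, l in self.labels.items() if l == "hypermutated"]


def mutation_rates(snvs_by_sample: Mapping[str, Sequence[SNVRecord]],
                   coding: RegionSet,
                   genome_footprint_bp: int,
                   coding_footprint_bp: Optional[int] = None
                   ) -> List[BurdenPoint]:
    """Genome-wide and coding mutation rates per Mb.

    Denominators are the callable footprints: the supplied genome footprint
    and the coding region footprint (merged length by default).  SNVs must
    already carry region classes (see assign_region_class).
    """
    if genome_footprint_bp <= 0:
        raise ValueError("zero genome footprint")
    coding_bp = coding_footprint_bp or coding.footprint
    if coding_bp <= 0:
        raise ValueError("zero coding footprint")
    points = []
    for sample, snvs in snvs_by_sample.items():
        n_total = len(snvs)
        n_coding = sum(1 for r in snvs if r.region_class == "coding")
        points.append(BurdenPoint(
            sample_id=sample,
            x=n_total / (genome_footprint_bp / 1e6),
            y=n_coding / (coding_bp / 1e6)))
    return points


def classify_hypermutation(points: Sequence[BurdenPoint],
                           coding_rate_min: float = 1.0,
                           rho_quantile: float = 0.10,
                           dist_quantile: float = 0.90) -> HypermutationResult:
    """Density-based hypermutation call on the (x, y) mutation-rate plane.

    Samples with coding rate below ``coding_rate_min`` (per Mb) are excluded
    before the density computation.  d_c is the median over all pairwise
    distances of retained samples; rho_j counts the fraction of samples
    (including j itself) closer than d_c; d_j is the median distance of j to
    the other samples.  A sample is hypermutated iff rho_j is at or below the
    ``rho_quantile`` cohort quantile and d_j at or above the
    ``dist_quantile`` quantile.
    """
    labels: Dict[str, str] = {}
    retained = []
    for p in points:
        if p.y < coding_rate_min:
            labels[p.sample_id] = "excluded"
        else:
            retained.append(p)
    if len(retained) < 5:
        raise ValueError("fewer than 5 retained samples")
    ids = [p.sample_id for p in retained]
    xy = np.array([[p.x, p.y] for p in retained])
    n = len(retained)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    iu = np.triu_indices(n, k=1)
    pairwise = d[iu]
    if np.allclose(pairwise, 0):
        logger.warning("degenerate identical burden points; all regular")
        for s in ids:
            labels[s] = "regular"
        return HypermutationResult(labels, {s: 0.0 for s in ids},
                                   {s: 1.0 for s in ids}, 0.0)
    d_c = float(np.median(pairwise))
    # median distance to the *other* tumors
    d_off = np.where(np.eye(n, dtype=bool), np.nan, d)
    d_j = np.nanmedian(d_off, axis=1)
    rho_j = (d < d_c).sum(axis=1) / n   # includes self (d_jj = 0 < d_c)
    rho_thr = float(np.quantile(rho_j, rho_quantile))
    d_thr = float(np.quantile(d_j, dist_quantile))
    for i, s in enumerate(ids):
        hyper = rho_j[i] <= rho_thr and d_j[i] >= d_thr
        labels[s] = "hypermutated" if hyper else "regular"
    return HypermutationResult(
        labels,
        {s: float(d_j[i]) for i, s in enumerate(ids)},
        {s: float(rho_j[i]) for i, s in enumerate(ids)},
        d_c)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumMatrix:
    """Samples x 96 channel count matrix in canonical channel order."""

    sample_ids: List[str]
    counts: np.ndarray          # shape (n_samples, 96), nonnegative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), 96):
            raise ValueError("spectrum shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=list(CHANNELS))


def build_spectrum_96(snvs_by_sample: Mapping[str, Sequence[SNVRecord]],
                      reference,
                      region_filter: Optional[str] = None) -> SpectrumMatrix:
    """Count SNVs into the canonical 96 trinucleotide channels per sample.

    ``region_filter`` restricts to records with that region_class (e.g.
    "coding"); records whose reference base disagrees with the FASTA are
    skipped and counted.
    """
    samples = list(snvs_by_sample)
    counts = np.zeros((len(samples), 96))
    n_mismatch = 0
    for si, sample in enumerate(samples):
        for r in snvs_by_sample[sample]:
            if region_filter is not None and r.region_class != region_filter:
                continue
            tri = reference.fetch(r.chrom, r.pos - 1, r.pos + 1).upper()
            if len(tri) != 3 or tri[1] != r.ref.upper():
                n_mismatch += 1
                continue
            ch = channel_of(r.ref, r.alt, tri[0], tri[2])
            if ch is None:
                n_mismatch += 1
                continue
            counts[si, ch] += 1
    if n_mismatch:
        logger.info("build_spectrum_96: skipped %d records (reference "
                    "mismatch or ambiguous base)", n_mismatch)
    return SpectrumMatrix(samples, counts)


# ---------------------------------------------------------------------------
# NMF signature extraction
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """k mutational signatures, each a probability vector over 96 channels."""

    names: List[str]
    profiles: np.ndarray        # shape (k, 96), rows sum to 1

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] != 96:
            raise ValueError("signature profiles must be k x 96")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature rows must sum to 1")

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles.T, index=list(CHANNELS),
                            columns=self.names)


@dataclass
class ExposureMatrix:
    """Samples x signatures nonnegative exposure counts."""

    sample_ids: List[str]
    signature_names: List[str]
    exposures: np.ndarray       # shape (n_samples, k)

    @property
    def proportions(self) -> np.ndarray:
        totals = self.exposures.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(totals > 0, self.exposures / totals, 0.0)
        return prop

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exposures, index=self.sample_ids,
                            columns=self.signature_names)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _cluster_stability(all_sigs: np.ndarray, reference: np.ndarray) -> float:
    """Mean silhouette (cosine distance) of restart signatures assigned to
    the best run's components; 1.0 for a single component."""
    k = reference.shape[0]
    if k == 1:
        return 1.0
    norm = lambda m: m / np.maximum(np.linalg.norm(m, axis=1, keepdims=True),
                                    1e-12)
    S, R = norm(all_sigs), norm(reference)
    sim = S @ R.T                             # (n_sigs, k)
    assign = sim.argmax(axis=1)
    dist = 1.0 - S @ S.T
    sil = []
    for i in range(len(S)):
        own = assign == assign[i]
        own[i] = False
        if not own.any():
            continue
        a = dist[i, own].mean()
        b = min(dist[i, assign == c].mean()
                for c in range(k) if c != assign[i] and (assign == c).any())
        sil.append((b - a) / max(a, b, 1e-12))
    return float(np.mean(sil)) if sil else 0.0


def extract_signatures_nmf(spectrum: SpectrumMatrix,
                           k_range: Sequence[int] = (1, 2, 3, 4, 5),
                           n_restarts: int = 30,
                           seed: int = 0,
                           improvement_min: float = 0.05,
                           stability_min: float = 0.8
                           ) -> Tuple[SignatureSet, ExposureMatrix, pd.DataFrame]:
    """De-novo signature extraction by multi-restart KL-divergence NMF.

    For each candidate rank k, ``n_restarts`` seeded multiplicative-update
    NMF runs are fitted; the best run's reconstruction error and the
    stability of its components across restarts (cosine silhouette) form the
    model-selection report.  The selected rank is the largest k reachable by
    successive relative error improvements of at least ``improvement_min``
    while stability stays at or above ``stability_min``.  Signatures are
    L1-normalized with exposures rescaled accordingly.
    """
    from sklearn.decomposition import NMF

    X = np.asarray(spectrum.counts, dtype=float)
    n = X.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    usable = [k for k in k_range if k <= n]
    if len(usable) < len(k_range):
        logger.warning("k_range trimmed to sample count %d", n)
    rng = np.random.default_rng(seed)
    # KL-NMF requires strictly positive entries for mu updates on zero rows
    Xf = X + 1e-9
    rows = []
    per_k = {}
    for k in usable:
        best = None
        restart_sigs = []
        for _ in range(n_restarts):
            rs = int(rng.integers(0, 2 ** 31 - 1))
            model = NMF(n_components=k, init="random", solver="mu",
                        beta_loss="kullback-leibler", max_iter=600,
                        random_state=rs, tol=1e-5)
            import warnings as _warnings
            from sklearn.exceptions import ConvergenceWarning
            with _warnings.catch_warnings():
                # best-of-restarts; per-run convergence is non-critical
                _warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(Xf)
            H = model.components_
            err = model.reconstruction_err_
            restart_sigs.append(H)
            if best is None or err < best[0]:
                best = (err, W, H)
        err, W, H = best
        stability = _cluster_stability(np.vstack(restart_sigs), H)
        per_k[k] = (err, W, H, stability)
        rows.append({"k": k, "kl_error": err, "stability": stability})
    report = pd.DataFrame(rows)
    # accept a larger rank whenever it is stable and meaningfully improves
    # on the best accepted rank so far (unstable intermediate ranks do not
    # block a stable larger one)
    chosen = usable[0]
    for k in usable[1:]:
        prev_err = per_k[chosen][0]
        err, _, _, stability = per_k[k]
        if stability >= stability_min and err < (1 - improvement_min) * prev_err:
            chosen = k
    err, W, H = per_k[chosen][:3]
    scale = H.sum(axis=1)
    H_norm = H / scale[:, None]
    W_scaled = W * scale[None, :]
    names = [f"S{i + 1}" for i in range(chosen)]
    sigset = SignatureSet(names, H_norm)
    exposures = ExposureMatrix(list(spectrum.sample_ids), names, W_scaled)
    return sigset, exposures, report


def refit_exposures(spectrum: SpectrumMatrix,
                    signatures: SignatureSet) -> ExposureMatrix:
    """Per-sample nonnegative least-squares fit of counts to fixed signatures."""
    A = signatures.profiles.T                    # 96 x k
    exp = np.zeros((len(spectrum.sample_ids), signatures.k))
    residuals = np.zeros(len(spectrum.sample_ids))
    for i, row in enumerate(np.asarray(spectrum.counts, dtype=float)):
        exp[i], residuals[i] = optimize.nnls(A, row)
    out = ExposureMatrix(list(spectrum.sample_ids), list(signatures.names), exp)
    out.residuals = residuals
    return out


def match_signatures(signatures: SignatureSet,
                     reference: Optional[pd.DataFrame] = None,
                     threshold: float = 0.8) -> Dict[str, str]:
    """Name extracted signatures by best cosine match against a reference
    signature table (rows = 96 channels, columns = named profiles); matches
    below ``threshold`` are labelled novel."""
    if reference is None:
        reference = load_reference_signatures()
    ref = reference.reindex(list(CHANNELS)).to_numpy().T
    names = {}
    for i, name in enumerate(signatures.names):
        sims = [cosine_similarity(signatures.profiles[i], r) for r in ref]
        j = int(np.argmax(sims))
        names[name] = (reference.columns[j] if sims[j] >= threshold
                       else f"novel_{i + 1}")
    return names


def load_reference_signatures() -> pd.DataFrame:
    """Bundled synthetic reference-signature table (96 x named profiles).

    These profiles are parametric stand-ins built from the published channel
    structure of well-known processes (CpG-deamination aging, APOBEC TpC,
    the T>G "17*-like" and the C>A "18*-like" patterns), not copied values.
    """
    with importlib.resources.files("svscape.data").joinpath(
            "reference_signatures.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df


# ---------------------------------------------------------------------------
# Region comparison / association
# ---------------------------------------------------------------------------

def compare_region_exposures(snvs_by_sample: Mapping[str, Sequence[SNVRecord]],
                             signatures: SignatureSet,
                             reference,
                             coding_footprint_bp: int,
                             noncoding_footprint_bp: int,
                             presence_min: float = 0.25,
                             low_support_min: int = 10) -> pd.DataFrame:
    """Refit exposures on coding and noncoding sub-spectra per sample and
    compare per-signature mutation rates (exposure per Mb) between regions.

    Returns a long-format frame with one row per sample x region x signature
    (columns: exposure, proportion, present, per_mb, low_support) plus the
    cohort-level paired two-sided t-test per signature stored in ``.attrs``
    as {signature: {"p": ..., "ratio": ...}} where ratio is the cohort mean
    noncoding/coding per-Mb rate ratio.
    """
    spectra = {
        "coding": build_spectrum_96(snvs_by_sample, reference,
                                    region_filter="coding"),
        "noncoding": build_spectrum_96(snvs_by_sample, reference,
                                       region_filter="noncoding"),
    }
    footprints = {"coding": coding_footprint_bp,
                  "noncoding": noncoding_footprint_bp}
    rows = []
    per_mb = {}
    for region, spec in spectra.items():
        exp = refit_exposures(spec, signatures)
        prop = exp.proportions
        mb = footprints[region] / 1e6
        per_mb[region] = exp.exposures / mb
        support = spec.counts.sum(axis=1)
        for i, sample in enumerate(exp.sample_ids):
            for j, sig in enumerate(exp.signature_names):
                rows.append({
                    "sample_id": sample, "region": region, "signature": sig,
                    "exposure": exp.exposures[i, j],
                    "proportion": prop[i, j],
                    "present": bool(prop[i, j] > presence_min),
                    "per_mb": exp.exposures[i, j] / mb,
                    "low_support": bool(support[i] < low_support_min),
                })
    df = pd.DataFrame(rows)
    tests = {}
    for j, sig in enumerate(signatures.names):
        c = per_mb["coding"][:, j]
        nc = per_mb["noncoding"][:, j]
        if len(c) >= 2 and (np.std(nc - c) > 0):
            t, p = stats.ttest_rel(nc, c)
        else:
            t, p = np.nan, np.nan
        mean_c = float(np.mean(c))
        ratio = float(np.mean(nc) / mean_c) if mean_c > 0 else np.inf
        tests[sig] = {"t": float(t), "p": float(p), "ratio": ratio,
                      "mean_coding_per_mb": mean_c,
                      "mean_noncoding_per_mb": float(np.mean(nc))}
    df.attrs["tests"] = tests
    return df


def associate_feature_with_exposure(proportions: Mapping[str, float],
                                    features: Mapping[str, Mapping[str, bool]],
                                    presence_min: float = 0.25,
                                    prevalence_min: float = 0.04
                                    ) -> pd.DataFrame:
    """Test binary sample features (e.g. gene mutation status) against one
    signature's exposure proportions.

    Features mutated in at most ``prevalence_min`` of samples are skipped (the
    gene-selection rule).  Per feature: a two-sided t-test on proportions, a
    Fisher exact test on the presence dichotomy (proportion > presence_min),
    and BH adjustment across all tested features.
    """
    from statsmodels.stats.multitest import multipletests

    samples = list(proportions)
    prop = np.array([proportions[s] for s in samples])
    present = prop > presence_min
    rows = []
    for feat, status in features.items():
        mask = np.array([bool(status.get(s, False)) for s in samples])
        prevalence = mask.mean()
        if prevalence <= prevalence_min or prevalence >= 1 - 1e-12:
            continue
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        t, p_t = stats.ttest_ind(prop[mask], prop[~mask], equal_var=False)
        table = [[int((present & mask).sum()), int((present & ~mask).sum())],
                 [int((~present & mask).sum()), int((~present & ~mask).sum())]]
        _, p_f = stats.fisher_exact(table)
        rows.append({"feature": feat, "prevalence": prevalence,
                     "t": float(t), "p_ttest": float(p_t),
                     "p_fisher": float(p_f)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_ttest"] = multipletests(df["p_ttest"], method="fdr_bh")[1]
        df["q_fisher"] = multipletests(df["p_fisher"], method="fdr_bh")[1]
    return df
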