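"""Cohort-level orchestration: load (or simulate) inputs, run every
analysis stage, and write per-module TSV reports.

Every output file carries a header comment with the package version and a
hash of the run configuration; reruns with an identical configuration are
byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .catalog_io import (GenomeModel, ReferenceGenome, RegionSet,
                         SampleCatalog, assign_region_class,
                         filter_somatic_snvs, read_bed, read_genome_model,
                         read_seg, read_snv_table, read_sv_bedpe,
                         write_bed, write_fasta, write_genome_model,
                         write_seg, write_snv_table, write_sv_bedpe)
from .synthetic_data import CohortConfig, simulate_cohort
from . import tdp as tdp_mod
from . import hotspots as hot_mod
from . import complex_events as cx_mod
from . import burden_signatures as bs_mod

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 in the CLI)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    out_dir: str = "svscape_out"
    seed: int = 7
    # inputs (ignored when simulate=True)
    simulate: bool = True
    n_samples: int = 50
    sv_bedpe: Optional[str] = None
    snv_table: Optional[str] = None
    seg_file: Optional[str] = None
    genome_sizes: Optional[str] = None
    reference_fasta: Optional[str] = None
    coding_bed: Optional[str] = None
    enhancer_bed: Optional[str] = None
    features_json: Optional[str] = None      # gene -> {sample: bool}
    # module thresholds (defaults as documented per module)
    tdp_score_min: float = -0.6
    tdp_proportion_min: float = 0.20
    tdp_count_min: int = 50
    pcf_gamma: float = 25.0
    pcf_kmin: int = 10
    hotspot_fold: float = 2.0
    hotspot_min_samples: int = 6
    foldback_sep_max: int = 30_000
    foldback_q_max: float = 0.001
    foldback_flank_bp: int = 100_000
    bfb_amp_min: int = 5
    chromothripsis_min_rearr: int = 10
    kataegis_imd_max: int = 1_000
    kataegis_min_mut: int = 6
    kataegis_colocal_max: int = 10_000
    hyper_coding_rate_min: float = 1.0
    hyper_rho_quantile: float = 0.10
    hyper_dist_quantile: float = 0.90
    nmf_k_max: int = 5
    nmf_restarts: int = 30
    presence_min: float = 0.25

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded, so
        identical analyses in different directories share a hash)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# svscape {__version__} config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def summarize_cohort(catalogs: Sequence[SampleCatalog]) -> pd.DataFrame:
    """Cohort summary: totals and percentages by SV type, per-sample SV/SNV
    burdens, and TD span-category totals."""
    from .catalog_io import SV_TYPES

    type_counts = {t: 0 for t in SV_TYPES}
    per_sample = []
    all_svs = []
    for cat in catalogs:
        for r in cat.svs:
            type_counts[r.svtype] = type_counts.get(r.svtype, 0) + 1
        all_svs.extend(cat.svs)
        per_sample.append({"sample_id": cat.sample_id,
                           "n_sv": len(cat.svs), "n_snv": len(cat.snvs)})
    total = sum(type_counts.values())
    rows = []
    for t, k in type_counts.items():
        rows.append({"metric": f"sv_type_{t}", "value": k,
                     "percent": 100.0 * k / total if total else 0.0})
    rows.append({"metric": "sv_total", "value": total, "percent": 100.0})
    n_svs = [p["n_sv"] for p in per_sample] or [0]
    rows.append({"metric": "sv_per_sample_min", "value": min(n_svs),
                 "percent": float("nan")})
    rows.append({"metric": "sv_per_sample_mean",
                 "value": sum(n_svs) / len(n_svs), "percent": float("nan")})
    rows.append({"metric": "sv_per_sample_max", "value": max(n_svs),
                 "percent": float("nan")})
    spans = tdp_mod.td_span_categories(all_svs)
    for cat_name, k in spans.items():
        rows.append({"metric": f"td_span_{cat_name}", "value": k,
                     "percent": float("nan")})
    df = pd.DataFrame(rows)
    df.attrs["per_sample"] = pd.DataFrame(per_sample)
    return df


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full analysis and write the report bundle to out_dir.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    raises StageError with the stage name; partial outputs are preserved.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    results: Dict[str, object] = {}
    with open(os.path.join(config.out_dir, "run_config.json"), "w") as fh:
        fh.write(config.to_json())

    # ---- load or simulate ----
    stage = "load"
    try:
        if config.simulate:
            sim = CohortConfig(n_samples=config.n_samples, seed=config.seed)
            catalogs, truth, genome, seqs, coding = simulate_cohort(sim)
            reference = ReferenceGenome(seqs)
            enhancers = None
            from .synthetic_data import default_enhancer_regions
            enhancers = default_enhancer_regions()
            inputs = os.path.join(config.out_dir, "inputs")
            os.makedirs(inputs, exist_ok=True)
            write_sv_bedpe([r for c in catalogs for r in c.svs],
                           os.path.join(inputs, "svs.bedpe"))
            write_snv_table([r for c in catalogs for r in c.snvs],
                            os.path.join(inputs, "snvs.tsv"))
            write_seg([s for c in catalogs for s in c.cn_segments],
                      os.path.join(inputs, "cn.seg"))
            write_genome_model(genome, os.path.join(inputs, "chrom.sizes"))
            write_fasta(seqs, os.path.join(inputs, "reference.fa"))
            write_bed(coding, os.path.join(inputs, "coding.bed"))
            truth.to_json(os.path.join(inputs, "truth.json"))
            results["truth"] = truth
        else:
            if not config.genome_sizes or not config.sv_bedpe:
                raise ConfigError("genome_sizes and sv_bedpe are required "
                                  "when simulate=False")
            if not os.path.exists(config.genome_sizes):
                raise ConfigError(f"missing genome model "
                                  f"{config.genome_sizes!r}")
            genome = read_genome_model(config.genome_sizes)
            svs = read_sv_bedpe(config.sv_bedpe, genome=genome)
            snvs = read_snv_table(config.snv_table) if config.snv_table \
                else []
            segs = read_seg(config.seg_file) if config.seg_file else []
            coding = read_bed(config.coding_bed, "coding") \
                if config.coding_bed else None
            enhancers = read_bed(config.enhancer_bed, "enhancers") \
                if config.enhancer_bed else None
            reference = ReferenceGenome(config.reference_fasta) \
                if config.reference_fasta else None
            by_sample: Dict[str, SampleCatalog] = {}
            for r in svs:
                by_sample.setdefault(
                    r.sample_id, SampleCatalog(r.sample_id)).svs.append(r)
            for r in snvs:
                by_sample.setdefault(
                    r.sample_id, SampleCatalog(r.sample_id)).snvs.append(r)
            for s in segs:
                by_sample.setdefault(
                    s.sample_id,
                    SampleCatalog(s.sample_id)).cn_segments.append(s)
            catalogs = [by_sample[s] for s in sorted(by_sample)]
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(stage, exc)

    have_snvs = any(c.snvs for c in catalogs)
    have_cn = any(c.cn_segments for c in catalogs)

    # ---- SNV filtering and region assignment ----
    stage = "filter"
    try:
        if have_snvs:
            for c in catalogs:
                kept = filter_somatic_snvs(c.snvs)
                if len(kept) != len(c.snvs):
                    logger.info("%s: %d/%d SNVs pass read-support filters",
                                c.sample_id, len(kept), len(c.snvs))
                c.snvs = kept
            if coding is not None:
                for c in catalogs:
                    c.snvs = assign_region_class(c.snvs, coding)
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- cohort summary ----
    stage = "summarize"
    try:
        summary = summarize_cohort(catalogs)
        _write_tsv(summary, os.path.join(config.out_dir, "cohort_summary.tsv"),
                   config)
        _write_tsv(summary.attrs["per_sample"],
                   os.path.join(config.out_dir, "sample_burdens.tsv"), config)
        results["summary"] = summary
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- TDP ----
    stage = "tdp"
    try:
        tdp_results = [tdp_mod.classify_tdp(
            c.svs, genome, score_min=config.tdp_score_min,
            proportion_min=config.tdp_proportion_min,
            count_min=config.tdp_count_min, seed=config.seed)
            for c in catalogs]
        tdp_df = tdp_mod.tdp_table(tdp_results)
        _write_tsv(tdp_df, os.path.join(config.out_dir, "tdp.tsv"), config)
        results["tdp"] = tdp_results
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- hotspots ----
    stage = "hotspots"
    try:
        all_svs = [r for c in catalogs for r in c.svs]
        spots = hot_mod.call_all_hotspots(
            all_svs, genome, gamma=config.pcf_gamma, kmin=config.pcf_kmin,
            fold=config.hotspot_fold, min_samples=config.hotspot_min_samples)
        region_sets = [rs for rs in (coding, enhancers) if rs is not None]
        hot_mod.annotate_hotspots(spots, region_sets)
        _write_tsv(hot_mod.hotspot_table(spots),
                   os.path.join(config.out_dir, "hotspots.tsv"), config)
        results["hotspots"] = spots
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- complex events ----
    stage = "complex"
    try:
        if have_cn:
            all_segs = [s for c in catalogs for s in c.cn_segments]
            foldbacks = cx_mod.detect_foldback_inversions(
                all_svs, all_segs, sep_max=config.foldback_sep_max,
                q_max=config.foldback_q_max,
                flank_bp=config.foldback_flank_bp)
            ploidy = {c.sample_id: c.ploidy for c in catalogs}
            bfb = cx_mod.infer_bfb(foldbacks, all_segs, genome,
                                   amp_min=config.bfb_amp_min, ploidy=ploidy)
            ct_calls: List[cx_mod.ChromothripsisCall] = []
            for c in catalogs:
                ct_calls.extend(cx_mod.call_chromothripsis(
                    c.svs, c.cn_segments, genome,
                    min_rearr=config.chromothripsis_min_rearr,
                    seed=config.seed))
            _write_tsv(pd.DataFrame([dataclasses.asdict(f)
                                     for f in foldbacks]),
                       os.path.join(config.out_dir, "foldbacks.tsv"), config)
            _write_tsv(pd.DataFrame([dataclasses.asdict(b) for b in bfb]),
                       os.path.join(config.out_dir, "bfb_calls.tsv"), config)
            _write_tsv(pd.DataFrame([dataclasses.asdict(x)
                                     for x in ct_calls]),
                       os.path.join(config.out_dir,
                                    "chromothripsis_calls.tsv"), config)
            results["foldbacks"] = foldbacks
            results["bfb"] = bfb
            results["chromothripsis"] = ct_calls
        else:
            _mark_not_run(config, "foldbacks", "bfb_calls",
                          "chromothripsis_calls")
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- kataegis ----
    stage = "kataegis"
    try:
        if have_snvs:
            foci: List[cx_mod.KataegisFocus] = []
            for c in catalogs:
                foci.extend(cx_mod.detect_kataegis(
                    c.snvs, c.svs, imd_max=config.kataegis_imd_max,
                    min_mut=config.kataegis_min_mut,
                    colocal_max=config.kataegis_colocal_max))
            _write_tsv(pd.DataFrame([dataclasses.asdict(f) for f in foci]),
                       os.path.join(config.out_dir, "kataegis_foci.tsv"),
                       config)
            results["kataegis"] = foci
        else:
            _mark_not_run(config, "kataegis_foci")
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- burden / hypermutation ----
    stage = "burden"
    try:
        if have_snvs and coding is not None:
            snv_map = {c.sample_id: c.snvs for c in catalogs}
            points = bs_mod.mutation_rates(snv_map, coding,
                                           genome.total_length)
            hyper = bs_mod.classify_hypermutation(
                points, coding_rate_min=config.hyper_coding_rate_min,
                rho_quantile=config.hyper_rho_quantile,
                dist_quantile=config.hyper_dist_quantile)
            df = pd.DataFrame([{
                "sample_id": p.sample_id, "rate_genome_per_mb": p.x,
                "rate_coding_per_mb": p.y,
                "label": hyper.labels[p.sample_id],
                "d_j": hyper.d_j.get(p.sample_id),
                "rho_j": hyper.rho_j.get(p.sample_id),
            } for p in points])
            _write_tsv(df, os.path.join(config.out_dir,
                                        "hypermutation.tsv"), config)
            results["burden"] = (points, hyper)
        else:
            _mark_not_run(config, "hypermutation")
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- signatures ----
    stage = "signatures"
    try:
        if have_snvs and reference is not None and coding is not None:
            snv_map = {c.sample_id: c.snvs for c in catalogs}
            spectrum = bs_mod.build_spectrum_96(snv_map, reference)
            sigset, exposures, report = bs_mod.extract_signatures_nmf(
                spectrum, k_range=range(1, config.nmf_k_max + 1),
                n_restarts=config.nmf_restarts, seed=config.seed)
            names = bs_mod.match_signatures(sigset)
            coding_bp = coding.footprint
            region_df = bs_mod.compare_region_exposures(
                snv_map, sigset, reference, coding_bp,
                genome.total_length - coding_bp,
                presence_min=config.presence_min)
            _write_tsv(spectrum.to_frame().reset_index(names="sample_id"),
                       os.path.join(config.out_dir, "spectrum96.tsv"), config)
            sig_df = sigset.to_frame()
            sig_df.columns = [f"{c}({names[c]})" for c in sig_df.columns]
            _write_tsv(sig_df.reset_index(names="channel"),
                       os.path.join(config.out_dir, "signatures.tsv"), config)
            _write_tsv(exposures.to_frame().reset_index(names="sample_id"),
                       os.path.join(config.out_dir, "exposures.tsv"), config)
            _write_tsv(region_df,
                       os.path.join(config.out_dir,
                                    "signature_regions.tsv"), config)
            tests = pd.DataFrame(region_df.attrs["tests"]).T \
                .reset_index(names="signature")
            _write_tsv(tests, os.path.join(config.out_dir,
                                           "signature_region_tests.tsv"),
                       config)
            results["signatures"] = (sigset, exposures, names, region_df,
                                     report)
        else:
            _mark_not_run(config, "spectrum96", "signatures", "exposures",
                          "signature_regions")
    except Exception as exc:
        raise StageError(stage, exc)

    # ---- associations ----
    stage = "associate"
    try:
        if config.features_json and "signatures" in results:
            with open(config.features_json) as fh:
                features = json.load(fh)
            sigset, exposures, names, region_df, _ = results["signatures"]
            prop = exposures.proportions
            assoc_frames = []
            for j, sig in enumerate(exposures.signature_names):
                proportions = {s: float(prop[i, j])
                               for i, s in enumerate(exposures.sample_ids)}
                df = bs_mod.associate_feature_with_exposure(
                    proportions, features,
                    presence_min=config.presence_min)
                df.insert(0, "signature", sig)
                assoc_frames.append(df)
            assoc = pd.concat(assoc_frames, ignore_index=True)
            _write_tsv(assoc, os.path.join(config.out_dir,
                                           "associations.tsv"), config)
            results["associations"] = assoc
        elif config.features_json:
            _mark_not_run(config, "associations")
    except Exception as exc:
        raise StageError(stage, exc)

    return results


def _mark_not_run(config: RunConfig, *names: str) -> None:
    for name in names:
        path = os.path.join(config.out_dir, f"{name}.tsv")
        with open(path, "w") as fh:
            fh.write(f"# svscape {__version__} "
                     f"config_hash={config.config_hash}\n")
            fh.write("# not run: required inputs absent\n")
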