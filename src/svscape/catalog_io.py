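"""Data model and I/O for somatic SV/SNV/copy-number catalogs.

Internal coordinates are 1-based breakend / base positions throughout the
package; BEDPE and BED input (0-based, half-open) are converted on read and
back on write.  SEG and VCF are 1-based already.

The SV-type vocabulary is fixed to the seven rearrangement classes used in
cancer WGS catalogs (deletion, tandem duplication, inversion, inter-
chromosomal translocation, insertion, complex deletion, fold-back inversion)
plus ``OTHER`` for anything else.  Unknown type strings map to OTHER with a
warning rather than an error so that third-party supplementary tables parse
regardless of their labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "TD", "INV", "ITX", "INS", "COMPLEX_DEL", "FB_INV", "OTHER")

#: aliases seen in the wild -> canonical type
_SV_TYPE_ALIASES = {
    "DEL": "DEL", "DELETION": "DEL", "DEL_INV": "COMPLEX_DEL",
    "TD": "TD", "TANDEM_DUP": "TD", "TANDEMDUP": "TD", "DUP": "TD",
    "TANDEM_DUPLICATION": "TD",
    "INV": "INV", "INVERSION": "INV",
    "ITX": "ITX", "TRA": "ITX", "CTX": "ITX", "TRANSLOCATION": "ITX",
    "INTER": "ITX", "INTER_CHROMOSOMAL": "ITX",
    "INS": "INS", "INSERTION": "INS",
    "COMPLEX_DEL": "COMPLEX_DEL", "COMPLEX_DELETION": "COMPLEX_DEL",
    "DEL_INS": "COMPLEX_DEL", "DEL_INVERS": "COMPLEX_DEL",
    "FB_INV": "FB_INV", "FOLDBACK": "FB_INV", "FOLD_BACK_INVERSION": "FB_INV",
    "FOLDBACK_INVERSION": "FB_INV", "INVERS_FOLDBACK": "FB_INV",
    "OTHER": "OTHER",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def canonical_svtype(label: str) -> str:
    """Map a free-text SV-type label to the canonical vocabulary."""
    key = str(label).strip().upper().replace("-", "_").replace(" ", "_")
    if key in _SV_TYPE_ALIASES:
        return _SV_TYPE_ALIASES[key]
    warnings.warn(f"unknown SV type label {label!r} mapped to OTHER")
    return "OTHER"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CatalogError(ValueError):
    """Raised on malformed input that violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names with lengths (bp) and optional centromeres.

    ``centromeres`` (bp) split chromosomes into p/q arms for arm-level
    statistics; when absent the midpoint is used.  ``footprint`` optionally
    restricts per-chromosome callable length (bp) used for expectations.
    """

    names: Tuple[str, ...]
    lengths: Mapping[str, int]
    centromeres: Optional[Mapping[str, int]] = None
    footprint: Optional[Mapping[str, int]] = None

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise CatalogError("duplicate chromosome names")
        if not self.names:
            raise CatalogError("empty genome model")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise CatalogError(f"non-positive length for {name}")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths[n] for n in self.names))

    def effective_length(self, chrom: str) -> int:
        if self.footprint is not None and chrom in self.footprint:
            return int(self.footprint[chrom])
        return int(self.lengths[chrom])

    @property
    def total_effective_length(self) -> int:
        return int(sum(self.effective_length(n) for n in self.names))

    def centromere(self, chrom: str) -> int:
        if self.centromeres is not None and chrom in self.centromeres:
            return int(self.centromeres[chrom])
        return int(self.lengths[chrom] // 2)

    def arm_of(self, chrom: str, pos: int) -> str:
        return "p" if pos <= self.centromere(chrom) else "q"

    def arm_bounds(self, chrom: str, arm: str) -> Tuple[int, int]:
        c = self.centromere(chrom)
        return (1, c) if arm == "p" else (c + 1, int(self.lengths[chrom]))

    def offsets(self) -> Dict[str, int]:
        """Cumulative genome offsets (strictly increasing) per chromosome."""
        out, acc = {}, 0
        for n in self.names:
            out[n] = acc
            acc += int(self.lengths[n])
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom in self.lengths and 1 <= pos <= self.lengths[chrom]


@dataclass
class SVRecord:
    """One somatic rearrangement: two breakends with strands plus a type.

    Strand pair encodes join orientation: (+,−) deletion-type, (−,+) TD-type,
    (+,+) head-to-head inverted, (−,−) tail-to-tail inverted.  When svtype and
    strands conflict, strands win for join-type statistics and svtype wins for
    type counting.
    """

    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    svtype: str = "OTHER"
    n_support_reads: Optional[int] = None
    has_reciprocal_cluster: Optional[bool] = None
    homology_length: Optional[int] = None

    def __post_init__(self):
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise CatalogError(
                f"malformed strand {self.strand1!r}/{self.strand2!r}")
        if self.svtype not in SV_TYPES:
            self.svtype = canonical_svtype(self.svtype)
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            # normalize intra-chromosomal records to pos1 < pos2
            self.pos1, self.pos2 = self.pos2, self.pos1
            self.strand1, self.strand2 = self.strand2, self.strand1
        if self.svtype == "ITX" and self.chrom1 == self.chrom2:
            raise CatalogError("ITX record with identical chromosomes")

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def join_type(self) -> str:
        """Join orientation class: del / td / hh / tt (strands win)."""
        pair = (self.strand1, self.strand2)
        return {("+", "-"): "del", ("-", "+"): "td",
                ("+", "+"): "hh", ("-", "-"): "tt"}[pair]


@dataclass
class SNVRecord:
    """One somatic single-base substitution with tumor/normal read support."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_depth: Optional[int] = None
    tumor_alt: Optional[int] = None
    normal_depth: Optional[int] = None
    normal_alt: Optional[int] = None
    region_class: str = "unassigned"

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise CatalogError("ref/alt must be single bases")
        if self.ref == self.alt:
            raise CatalogError("ref equals alt")
        for alt, depth in ((self.tumor_alt, self.tumor_depth),
                           (self.normal_alt, self.normal_depth)):
            if alt is not None and depth is not None and alt > depth:
                raise CatalogError("alt count exceeds depth")


@dataclass
class CNSegment:
    """A copy-number segment: log2 depth ratio plus optional integer CN."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2r: float
    copy_number: Optional[int] = None
    q_value: Optional[float] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise CatalogError("segment start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Named collection of 1-based inclusive intervals (e.g. coding exons)."""

    name: str
    intervals: List[Tuple[str, int, int, str]] = field(default_factory=list)

    def merged(self) -> Dict[str, np.ndarray]:
        """Per-chromosome (n,2) arrays of merged, sorted intervals."""
        per: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end, _ in self.intervals:
            per.setdefault(chrom, []).append((start, end))
        out = {}
        for chrom, ivs in per.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return out

    @property
    def footprint(self) -> int:
        """Total merged length in bp."""
        return int(sum((m[:, 1] - m[:, 0] + 1).sum()
                       for m in self.merged().values()))

    def footprint_on(self, chrom: str) -> int:
        m = self.merged().get(chrom)
        return 0 if m is None else int((m[:, 1] - m[:, 0] + 1).sum())

    def contains(self, chrom: str, pos: int, _cache={}) -> bool:
        key = id(self)
        merged = _cache.get(key)
        if merged is None or _cache.get((key, "n")) != len(self.intervals):
            merged = self.merged()
            _cache[key] = merged
            _cache[(key, "n")] = len(self.intervals)
        m = merged.get(chrom)
        if m is None or len(m) == 0:
            return False
        i = np.searchsorted(m[:, 0], pos, side="right") - 1
        return i >= 0 and pos <= m[i, 1]


@dataclass
class SampleCatalog:
    """One tumor's SV, SNV and CN records plus metadata."""

    sample_id: str
    svs: List[SVRecord] = field(default_factory=list)
    snvs: List[SNVRecord] = field(default_factory=list)
    cn_segments: List[CNSegment] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        for rec in self.svs + self.snvs + self.cn_segments:
            if rec.sample_id != self.sample_id:
                raise CatalogError(
                    f"record sample {rec.sample_id!r} != catalog "
                    f"{self.sample_id!r}")

    @property
    def ploidy(self) -> float:
        return float(self.metadata.get("ploidy", 2.0))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genome_model(path) -> GenomeModel:
    """Read a two-column chromosome-size TSV (name, length in bp)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["name", "length"], dtype={"name": str})
    names = tuple(df["name"])
    if len(set(names)) != len(names):
        raise CatalogError("duplicate chromosome names in size table")
    lengths = {n: int(l) for n, l in zip(df["name"], df["length"])}
    return GenomeModel(names=names, lengths=lengths)


def write_genome_model(model: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for n in model.names:
            fh.write(f"{n}\t{model.lengths[n]}\n")


_BEDPE_CANONICAL = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                    "sample_id", "svtype", "score", "strand1", "strand2"]
_BEDPE_OPTIONAL = ["n_support_reads", "has_reciprocal_cluster",
                   "homology_length"]

#: header-driven aliases for third-party / supplementary table layouts
_BEDPE_HEADER_ALIASES = {
    "chrom1": ["chrom1", "chr1", "chr_from", "chrom_a", "#chrom1", "#chr1"],
    "start1": ["start1", "pos1_start", "chr_from_bkpt_start", "start_a"],
    "end1": ["end1", "pos1_end", "chr_from_bkpt", "end_a"],
    "chrom2": ["chrom2", "chr2", "chr_to", "chrom_b"],
    "start2": ["start2", "pos2_start", "chr_to_bkpt_start", "start_b"],
    "end2": ["end2", "pos2_end", "chr_to_bkpt", "end_b"],
    "sample_id": ["sample_id", "sample", "tumor", "tumour", "case_id", "name"],
    "svtype": ["svtype", "sv_type", "type", "variant_type", "mechanism"],
    "strand1": ["strand1", "strand_a", "str1", "chr_from_strand"],
    "strand2": ["strand2", "strand_b", "str2", "chr_to_strand"],
    "score": ["score"],
    "n_support_reads": ["n_support_reads", "support_reads", "num_reads",
                        "supporting_reads"],
    "has_reciprocal_cluster": ["has_reciprocal_cluster", "reciprocal"],
    "homology_length": ["homology_length", "homology", "microhomology"],
}


def _resolve_bedpe_columns(columns: Sequence[str],
                           dialect: Optional[Mapping[str, str]]) -> Dict[str, str]:
    """Map canonical field -> actual column name, header-driven and tolerant."""
    lower = {c.lower().strip(): c for c in columns}
    mapping: Dict[str, str] = {}
    for canon, aliases in _BEDPE_HEADER_ALIASES.items():
        if dialect and canon in dialect:
            if dialect[canon] in columns:
                mapping[canon] = dialect[canon]
            continue
        for alias in aliases:
            if alias in lower:
                mapping[canon] = lower[alias]
                break
    return mapping


def read_sv_bedpe(path, dialect: Optional[Mapping[str, str]] = None,
                  genome: Optional[GenomeModel] = None) -> List[SVRecord]:
    """Read a headered BEDPE(-like) table into 1-based SVRecords.

    ``dialect`` optionally maps canonical field names to this file's column
    headers; common aliases are recognized automatically.  BEDPE starts are
    0-based half-open: the breakend position is start+1.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = _resolve_bedpe_columns(df.columns, dialect)
    required = ["chrom1", "start1", "chrom2", "start2", "strand1", "strand2"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise CatalogError(f"BEDPE missing columns for {missing}")
    records: List[SVRecord] = []
    for idx, row in df.iterrows():
        pos1 = int(row[cols["start1"]]) + 1
        pos2 = int(row[cols["start2"]]) + 1
        chrom1 = str(row[cols["chrom1"]])
        chrom2 = str(row[cols["chrom2"]])
        if genome is not None:
            for c, p in ((chrom1, pos1), (chrom2, pos2)):
                if not genome.contains(c, p):
                    raise CatalogError(
                        f"row {idx}: breakend {c}:{p} outside genome")
        kwargs = {}
        for opt in _BEDPE_OPTIONAL:
            if opt in cols and not pd.isna(row[cols[opt]]):
                val = row[cols[opt]]
                kwargs[opt] = bool(val) if opt == "has_reciprocal_cluster" \
                    else int(val)
        records.append(SVRecord(
            sample_id=str(row[cols["sample_id"]]) if "sample_id" in cols
            else "sample",
            chrom1=chrom1, pos1=pos1, strand1=str(row[cols["strand1"]]),
            chrom2=chrom2, pos2=pos2, strand2=str(row[cols["strand2"]]),
            svtype=canonical_svtype(row[cols["svtype"]])
            if "svtype" in cols else "OTHER",
            **kwargs))
    return records


def write_sv_bedpe(records: Iterable[SVRecord], path) -> None:
    """Write canonical headered BEDPE (0-based half-open breakend intervals)."""
    rows = []
    for r in records:
        rows.append({
            "chrom1": r.chrom1, "start1": r.pos1 - 1, "end1": r.pos1,
            "chrom2": r.chrom2, "start2": r.pos2 - 1, "end2": r.pos2,
            "sample_id": r.sample_id, "svtype": r.svtype, "score": ".",
            "strand1": r.strand1, "strand2": r.strand2,
            "n_support_reads": r.n_support_reads,
            "has_reciprocal_cluster": r.has_reciprocal_cluster,
            "homology_length": r.homology_length,
        })
    pd.DataFrame(rows, columns=_BEDPE_CANONICAL + _BEDPE_OPTIONAL).to_csv(
        path, sep="\t", index=False)


def read_snv_table(path, fmt: str = "TSV",
                   tumor_sample: str = "TUMOR",
                   normal_sample: str = "NORMAL",
                   sample_id: Optional[str] = None) -> List[SNVRecord]:
    """Read somatic SNVs from a VCF (AD/DP format fields) or MAF-like TSV.

    Multi-allelic VCF rows are rejected with their row index; indels are
    skipped and counted in the skip log.
    """
    fmt = fmt.upper()
    if fmt == "VCF":
        return _read_snv_vcf(path, tumor_sample, normal_sample, sample_id)
    if fmt == "TSV":
        return _read_snv_tsv(path)
    raise CatalogError(f"unknown SNV format {fmt!r}")


def _read_snv_vcf(path, tumor_sample, normal_sample, sample_id) -> List[SNVRecord]:
    import pysam

    records: List[SNVRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for idx, rec in enumerate(vcf):
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                raise CatalogError(f"multi-allelic row at index {idx}")
            alt = rec.alts[0]
            if len(rec.ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            def _counts(sample):
                if sample not in rec.samples:
                    return None, None
                ad = rec.samples[sample].get("AD")
                if ad is None or ad[0] is None:
                    return None, None
                depth = int(sum(a for a in ad if a is not None))
                return depth, int(ad[1]) if len(ad) > 1 else 0
            td, ta = _counts(tumor_sample)
            nd, na = _counts(normal_sample)
            records.append(SNVRecord(
                sample_id=sample_id or tumor_sample,
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                tumor_depth=td, tumor_alt=ta,
                normal_depth=nd, normal_alt=na))
    if n_skipped:
        logger.info("read_snv_table: skipped %d indel rows", n_skipped)
    return records


def _read_snv_tsv(path) -> List[SNVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records: List[SNVRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        ref, alt = str(row["ref"]), str(row["alt"])
        if len(ref) != 1 or len(alt) != 1:
            n_skipped += 1
            continue
        def _opt(col):
            return int(row[col]) if col in row and not pd.isna(row[col]) \
                else None
        records.append(SNVRecord(
            sample_id=str(row["sample_id"]), chrom=str(row["chrom"]),
            pos=int(row["pos"]), ref=ref, alt=alt,
            tumor_depth=_opt("tumor_depth"), tumor_alt=_opt("tumor_alt"),
            normal_depth=_opt("normal_depth"), normal_alt=_opt("normal_alt"),
            region_class=str(row["region_class"])
            if "region_class" in row and not pd.isna(row["region_class"])
            else "unassigned"))
    if n_skipped:
        logger.info("read_snv_table: skipped %d indel rows", n_skipped)
    return records


def write_snv_table(records: Iterable[SNVRecord], path) -> None:
    rows = [{
        "sample_id": r.sample_id, "chrom": r.chrom, "pos": r.pos,
        "ref": r.ref, "alt": r.alt,
        "tumor_depth": r.tumor_depth, "tumor_alt": r.tumor_alt,
        "normal_depth": r.normal_depth, "normal_alt": r.normal_alt,
        "region_class": r.region_class,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path) -> List[CNSegment]:
    """Read a SEG table (sample, chrom, start, end, log2R [, copy_number])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = {c.lower(): c for c in df.columns}
    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise CatalogError(f"SEG missing column among {names}")
    out = []
    cn_col = next((cols[n] for n in ("copy_number", "cn") if n in cols), None)
    for _, row in df.iterrows():
        out.append(CNSegment(
            sample_id=str(row[col("sample_id", "sample", "id")]),
            chrom=str(row[col("chrom", "chromosome", "chr")]),
            start=int(row[col("start", "loc.start")]),
            end=int(row[col("end", "loc.end")]),
            log2r=float(row[col("log2r", "seg.mean", "log2ratio")]),
            copy_number=int(row[cn_col])
            if cn_col and not pd.isna(row[cn_col]) else None))
    return out


def write_seg(segments: Iterable[CNSegment], path) -> None:
    rows = [{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "log2r": s.log2r, "copy_number": s.copy_number,
    } for s in segments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bed(path, name: str = "regions") -> RegionSet:
    """Read BED3/BED4 into a RegionSet (converted to 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ivs = []
    for _, row in df.iterrows():
        label = str(row[3]) if len(row) > 3 else name
        ivs.append((str(row[0]), int(row[1]) + 1, int(row[2]), label))
    return RegionSet(name=name, intervals=ivs)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in regions.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# Record-level utilities
# ---------------------------------------------------------------------------

def filter_somatic_snvs(records: Sequence[SNVRecord],
                        tumor_alt_min: int = 4,
                        normal_alt_max: int = 2,
                        tumor_depth_min: int = 14,
                        normal_depth_min: int = 10) -> List[SNVRecord]:
    """Post-call read-support filter: tumor alt reads >=4 with coverage >=14,
    normal alt reads <=2 with coverage >=10.  Records missing counts are
    dropped and logged; order is preserved and the operation is idempotent."""
    kept: List[SNVRecord] = []
    n_missing = 0
    for r in records:
        counts = (r.tumor_alt, r.tumor_depth, r.normal_alt, r.normal_depth)
        if any(c is None for c in counts):
            n_missing += 1
            continue
        if (r.tumor_alt >= tumor_alt_min and r.normal_alt <= normal_alt_max
                and r.tumor_depth >= tumor_depth_min
                and r.normal_depth >= normal_depth_min):
            kept.append(r)
    if n_missing:
        logger.info("filter_somatic_snvs: dropped %d records with missing "
                    "counts", n_missing)
    return kept


def sv_span(record: SVRecord) -> Optional[int]:
    """pos2 - pos1 for intra-chromosomal records; None for translocations."""
    if not record.intra:
        return None
    return record.pos2 - record.pos1


def assign_region_class(snvs: Sequence[SNVRecord],
                        coding: RegionSet) -> List[SNVRecord]:
    """Label each SNV coding/noncoding by membership in the coding regions."""
    merged = coding.merged()
    out = []
    for r in snvs:
        m = merged.get(r.chrom)
        hit = False
        if m is not None and len(m):
            i = np.searchsorted(m[:, 0], r.pos, side="right") - 1
            hit = i >= 0 and r.pos <= m[i, 1]
        out.append(replace(r, region_class="coding" if hit else "noncoding"))
    return out


def _junction_flanks(record: SVRecord, reference, max_len: int):
    """Four junction flank strings read outward from the junction on the
    derivative strand.

    side1 is the segment that *ends* at breakend 1, side2 the segment that
    *begins* at breakend 2.  ``in`` flanks lie inside the retained segments,
    ``out`` flanks are the reference continuation beyond the junction.
    """
    def fetch(chrom, start, end):  # 1-based inclusive, clipped
        if start > end:
            return ""
        return reference.fetch(chrom, max(start, 1), end).upper()

    c1, p1, s1 = record.chrom1, record.pos1, record.strand1
    c2, p2, s2 = record.chrom2, record.pos2, record.strand2
    if s1 == "+":
        in1 = fetch(c1, p1 - max_len + 1, p1)[::-1]
        out1 = fetch(c1, p1 + 1, p1 + max_len)
    else:  # retained segment right of p1, derivative = revcomp
        in1 = fetch(c1, p1, p1 + max_len - 1).translate(_COMPLEMENT)
        out1 = revcomp(fetch(c1, p1 - max_len, p1 - 1))
    if s2 == "-":
        in2 = fetch(c2, p2, p2 + max_len - 1)
        out2 = fetch(c2, p2 - max_len, p2 - 1)[::-1]
    else:  # retained segment left of p2, derivative = revcomp
        in2 = revcomp(fetch(c2, p2 - max_len + 1, p2))
        out2 = fetch(c2, p2 + 1, p2 + max_len).translate(_COMPLEMENT)
    return in1, out1, in2, out2


def junction_microhomology(record: SVRecord, reference,
                           max_len: int = 200) -> int:
    """Longest junction-flank sequence identity (bp), 0 when none.

    Computed symmetrically: the bases entering the junction on one side are
    compared with the reference continuation beyond the other side, in both
    directions, and the maximum match length is reported.  Ambiguity between
    inserted sequence and homology is resolved homology-first (any identity
    counts).
    """
    for c, p in ((record.chrom1, record.pos1), (record.chrom2, record.pos2)):
        if not (1 <= p <= reference.chrom_length(c)):
            raise CatalogError(f"breakend {c}:{p} outside reference")
    in1, out1, in2, out2 = _junction_flanks(record, reference, max_len)

    def lcp(a: str, b: str) -> int:
        n = 0
        for x, y in zip(a, b):
            if x != y or x == "N":
                break
            n += 1
        return n

    return max(lcp(in2, out1), lcp(in1, out2))


class ReferenceGenome:
    """Minimal 1-based reference sequence accessor.

    Wraps either an in-memory dict of chromosome strings (as produced by the
    simulator) or an indexed FASTA via pyfaidx.
    """

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {k: str(v) for k, v in source.items()}
            self._fasta = None
        else:
            from pyfaidx import Fasta
            self._fasta = Fasta(str(source))
            self._seqs = None

    def chrom_length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive fetch, clipped to chromosome bounds."""
        start = max(int(start), 1)
        end = min(int(end), self.chrom_length(chrom))
        if start > end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1:end]
        return str(self._fasta[chrom][start - 1:end])

    def chroms(self) -> List[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
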