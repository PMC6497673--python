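"""Data model, format I/O and record-level utilities."""

import numpy as np
import pytest

from svscape.catalog_io import (CatalogError, GenomeModel, ReferenceGenome,
                                RegionSet, SNVRecord, SVRecord,
                                assign_region_class, filter_somatic_snvs,
                                junction_microhomology, read_genome_model,
                                read_snv_table, read_sv_bedpe, revcomp,
                                sv_span, write_snv_table, write_sv_bedpe)


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

def test_read_genome_model_totals(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("chrA\t1000000\nchrB\t500000\n")
    model = read_genome_model(p)
    assert model.names == ("chrA", "chrB")
    assert model.total_length == 1_500_000


def test_read_genome_model_single_chrom(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("only\t1\n")
    assert read_genome_model(p).total_length == 1


def test_read_genome_model_duplicate_error(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("chrA\t100\nchrA\t200\n")
    with pytest.raises(CatalogError):
        read_genome_model(p)


def test_genome_offsets_strictly_increasing(tiny_genome):
    off = list(tiny_genome.offsets().values())
    assert off == sorted(off) and len(set(off)) == len(off)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def test_bedpe_coordinate_convention(tmp_path):
    p = tmp_path / "sv.bedpe"
    p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tsample_id\t"
                 "svtype\tscore\tstrand1\tstrand2\n"
                 "chr1\t99\t100\tchr1\t1099\t1100\ts1\tTD\t.\t-\t+\n")
    (rec,) = read_sv_bedpe(p)
    assert (rec.pos1, rec.pos2) == (100, 1100)
    assert rec.svtype == "TD"


def test_bedpe_round_trip_identity(tmp_path, rng):
    records = []
    for i in range(50):
        intra = rng.random() < 0.7
        c1 = "chr1"
        c2 = "chr1" if intra else "chr2"
        p1 = int(rng.integers(1, 900_000))
        p2 = p1 + int(rng.integers(100, 50_000)) if intra \
            else int(rng.integers(1, 900_000))
        records.append(SVRecord(
            sample_id=f"s{i % 5}", chrom1=c1, pos1=p1,
            strand1="+-"[rng.integers(2)], chrom2=c2, pos2=p2,
            strand2="+-"[rng.integers(2)],
            svtype="TD" if intra else "ITX",
            n_support_reads=int(rng.integers(3, 60)),
            has_reciprocal_cluster=bool(rng.integers(2))))
    path = tmp_path / "rt.bedpe"
    write_sv_bedpe(records, path)
    back = read_sv_bedpe(path)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.sample_id, a.chrom1, a.pos1, a.strand1, a.chrom2, a.pos2,
                a.strand2, a.svtype, a.n_support_reads,
                a.has_reciprocal_cluster) == \
               (b.sample_id, b.chrom1, b.pos1, b.strand1, b.chrom2, b.pos2,
                b.strand2, b.svtype, b.n_support_reads,
                b.has_reciprocal_cluster)


def test_bedpe_dialect_equivalence(tmp_path):
    canonical = tmp_path / "a.bedpe"
    canonical.write_text(
        "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tsample_id\tsvtype\t"
        "score\tstrand1\tstrand2\n"
        "chr1\t99\t100\tchr1\t1999\t2000\tT01\tTD\t.\t-\t+\n")
    supp = tmp_path / "b.tsv"
    supp.write_text(
        "Sample\tchr_from\tchr_from_bkpt_start\tchr_from_bkpt\tchr_to\t"
        "chr_to_bkpt_start\tchr_to_bkpt\tvariant_type\tstr1\tstr2\n"
        "T01\tchr1\t99\t100\tchr1\t1999\t2000\ttandem_dup\t-\t+\n")
    (a,) = read_sv_bedpe(canonical)
    (b,) = read_sv_bedpe(supp, dialect={
        "sample_id": "Sample", "chrom1": "chr_from",
        "start1": "chr_from_bkpt_start", "chrom2": "chr_to",
        "start2": "chr_to_bkpt_start", "svtype": "variant_type",
        "strand1": "str1", "strand2": "str2"})
    assert (a.sample_id, a.chrom1, a.pos1, a.pos2, a.svtype,
            a.strand1, a.strand2) == \
           (b.sample_id, b.chrom1, b.pos1, b.pos2, b.svtype,
            b.strand1, b.strand2)


def test_unknown_svtype_maps_to_other():
    with pytest.warns(UserWarning):
        rec = SVRecord("s", "chr1", 10, "+", "chr1", 20, "-",
                       svtype="weird_thing")
    assert rec.svtype == "OTHER"


def test_bedpe_out_of_bounds_rejected(tmp_path, tiny_genome):
    p = tmp_path / "sv.bedpe"
    p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tsample_id\t"
                 "svtype\tscore\tstrand1\tstrand2\n"
                 "chrA\t99\t100\tchrA\t2000000\t2000001\ts1\tDEL\t.\t+\t-\n")
    with pytest.raises(CatalogError):
        read_sv_bedpe(p, genome=tiny_genome)


# ---------------------------------------------------------------------------
# SNV tables
# ---------------------------------------------------------------------------

_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=chr1,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
chr1\t1000\t.\tC\tT\t.\t.\t.\tAD\t28,1\t10,5
chr1\t2000\t.\tA\tAT\t.\t.\t.\tAD\t30,0\t20,6
"""


def test_vcf_ad_arithmetic_and_indel_skip(tmp_path):
    p = tmp_path / "m.vcf"
    p.write_text(_VCF)
    recs = read_snv_table(p, fmt="VCF", sample_id="T01")
    assert len(recs) == 1          # indel skipped
    r = recs[0]
    assert (r.tumor_depth, r.tumor_alt) == (15, 5)
    assert (r.normal_depth, r.normal_alt) == (29, 1)


def test_tsv_vcf_dual_encoding_equivalence(tmp_path):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(_VCF)
    v = read_snv_table(vcf, fmt="VCF", sample_id="T01")[0]
    tsv = tmp_path / "m.tsv"
    write_snv_table([v], tsv)
    t = read_snv_table(tsv, fmt="TSV")[0]
    assert (v.chrom, v.pos, v.ref, v.alt, v.tumor_depth, v.tumor_alt,
            v.normal_depth, v.normal_alt) == \
           (t.chrom, t.pos, t.ref, t.alt, t.tumor_depth, t.tumor_alt,
            t.normal_depth, t.normal_alt)


# ---------------------------------------------------------------------------
# somatic filter
# ---------------------------------------------------------------------------

def _snv(ta, na, td, nd):
    return SNVRecord("s", "chr1", 100, "C", "T", tumor_depth=td,
                     tumor_alt=ta, normal_depth=nd, normal_alt=na)


def test_filter_boundary_values_kept():
    # the stated thresholds are inclusive on every margin
    rec = _snv(ta=4, na=2, td=14, nd=10)
    assert filter_somatic_snvs([rec]) == [rec]


@pytest.mark.parametrize("kwargs", [
    dict(ta=3, na=2, td=14, nd=10),
    dict(ta=4, na=3, td=14, nd=10),
    dict(ta=4, na=2, td=13, nd=10),
    dict(ta=4, na=2, td=14, nd=9),
])
def test_filter_single_violation_dropped(kwargs):
    assert filter_somatic_snvs([_snv(**kwargs)]) == []


def test_filter_empty_and_idempotent(rng):
    assert filter_somatic_snvs([]) == []
    recs = []
    for _ in range(100):
        td = int(rng.integers(5, 40))
        nd = int(rng.integers(5, 40))
        recs.append(_snv(int(rng.integers(0, min(10, td + 1))),
                         int(rng.integers(0, min(5, nd + 1))), td, nd))
    once = filter_somatic_snvs(recs)
    assert set(id(r) for r in once) <= set(id(r) for r in recs)
    assert filter_somatic_snvs(once) == once


# ---------------------------------------------------------------------------
# span
# ---------------------------------------------------------------------------

def test_sv_span_values():
    td = SVRecord("s", "chr1", 100, "-", "chr1", 1100, "+", "TD")
    assert sv_span(td) == 1000
    itx = SVRecord("s", "chr1", 100, "+", "chr2", 5000, "-", "ITX")
    assert sv_span(itx) is None
    dele = SVRecord("s", "chr3", 5000, "+", "chr3", 5001, "-", "DEL")
    assert sv_span(dele) == 1


# ---------------------------------------------------------------------------
# junction microhomology
# ---------------------------------------------------------------------------

def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _plant_deletion_homology(rng, h, cross_chrom=False):
    """Reference where the downstream flanks of both deletion breakends
    share exactly ``h`` bases."""
    n = 4000
    s1 = list(_random_seq(rng, n))
    s2 = list(_random_seq(rng, n)) if cross_chrom else s1
    p1, p2 = 1000, 2500
    motif = _random_seq(rng, h)
    for i in range(h):
        s1[p1 + i] = motif[i]          # 0-based: bases at pos1+1..pos1+h
        s2[p2 - 1 + i] = motif[i]      # bases at pos2..pos2+h-1
    # force mismatch at h+1 in the junction direction and at the first
    # upstream base so only the planted tract matches
    s1[p1 + h] = "A"
    s2[p2 - 1 + h] = "C"
    s1[p1 - 1] = "G"
    s2[p2 - 2] = "T"
    seqs = {"c1": "".join(s1)}         # intra-chromosomal: s2 aliases s1
    chrom2 = "c1"
    if cross_chrom:
        seqs["c2"] = "".join(s2)
        chrom2 = "c2"
    ref = ReferenceGenome(seqs)
    rec = SVRecord("s", "c1", p1, "+", chrom2, p2, "-",
                   "ITX" if cross_chrom else "DEL")
    return rec, ref


@pytest.mark.parametrize("h,cross", [(4, False), (0, False), (12, True)])
def test_microhomology_planted(h, cross):
    rng = np.random.default_rng(100 + h)
    rec, ref = _plant_deletion_homology(rng, h, cross_chrom=cross)
    assert junction_microhomology(rec, ref) == h


def _oracle_microhomology(rec, ref, max_len=200):
    """Independent char-by-char oracle using Bio.Seq for strand handling."""
    from Bio.Seq import Seq

    def fetch(c, a, b):
        return ref.fetch(c, a, b).upper()

    c1, p1, s1 = rec.chrom1, rec.pos1, rec.strand1
    c2, p2, s2 = rec.chrom2, rec.pos2, rec.strand2
    L = max_len
    if s1 == "+":
        in1 = fetch(c1, p1 - L + 1, p1)[::-1]
        out1 = fetch(c1, p1 + 1, p1 + L)
    else:
        in1 = str(Seq(fetch(c1, p1, p1 + L - 1)).complement())
        out1 = str(Seq(fetch(c1, p1 - L, p1 - 1)).reverse_complement())
    if s2 == "-":
        in2 = fetch(c2, p2, p2 + L - 1)
        out2 = fetch(c2, p2 - L, p2 - 1)[::-1]
    else:
        in2 = str(Seq(fetch(c2, p2 - L + 1, p2)).reverse_complement())
        out2 = str(Seq(fetch(c2, p2 + 1, p2 + L)).complement())

    def lcp(a, b):
        n = 0
        for x, y in zip(a, b):
            if x != y or x == "N":
                break
            n += 1
        return n

    return max(lcp(in2, out1), lcp(in1, out2))


def test_microhomology_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    seqs = {"c1": _random_seq(rng, 20_000), "c2": _random_seq(rng, 20_000)}
    ref = ReferenceGenome(seqs)
    for _ in range(200):
        intra = rng.random() < 0.6
        c1 = "c1"
        c2 = "c1" if intra else "c2"
        p1 = int(rng.integers(500, 9_000))
        p2 = p1 + int(rng.integers(300, 9_000)) if intra \
            else int(rng.integers(500, 19_000))
        rec = SVRecord("s", c1, p1, "+-"[rng.integers(2)], c2, p2,
                       "+-"[rng.integers(2)],
                       "OTHER" if intra else "ITX")
        assert junction_microhomology(rec, ref) == \
            _oracle_microhomology(rec, ref)


def test_microhomology_outside_reference_errors():
    ref = ReferenceGenome({"c1": "ACGT" * 100})
    rec = SVRecord("s", "c1", 10, "+", "c1", 5000, "-", "DEL")
    with pytest.raises(CatalogError):
        junction_microhomology(rec, ref)


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def test_region_class_bed_convention():
    # BED interval [100, 200) -> 1-based 101..200 inclusive
    regions = RegionSet("coding", [("chr1", 101, 200, "exon")])
    snvs = [SNVRecord("s", "chr1", p, "C", "A") for p in (101, 200, 201)]
    out = assign_region_class(snvs, regions)
    assert [r.region_class for r in out] == ["coding", "coding", "noncoding"]


def test_region_class_fraction_matches_footprint(rng):
    length = 1_000_000
    regions = RegionSet("coding", [("chr1", s + 1, s + 10_000, "x")
                                   for s in range(0, length, 100_000)])
    frac = regions.footprint / length
    positions = rng.integers(1, length + 1, size=1000)
    snvs = [SNVRecord("s", "chr1", int(p), "C", "A") for p in positions]
    out = assign_region_class(snvs, regions)
    k = sum(1 for r in out if r.region_class == "coding")
    sd = np.sqrt(1000 * frac * (1 - frac))
    assert abs(k - 1000 * frac) < 3 * sd
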