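"""Peak ingestion, replicate matching, score correlation and gene assignment."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apcscreen.intervals import (GeneModel, Peak, RegionClass, assign_to_genes,
                                 classify_location, intersect_replicates,
                                 peak_score_correlation, read_genes_gtf, read_peaks,
                                 shared_peaks, write_genes_gtf)
from oracles import brute_nearest_tss


def peak(summit, chrom="chr1", width=200, score=10.0, nlp=5.0):
    start = max(0, summit - width // 2)
    return Peak(chrom=chrom, start=start, end=start + width, summit=summit,
                score=score, neg_log10_p=nlp)


# -- Peak invariants ---------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    dict(start=100, end=100, summit=100),          # empty interval
    dict(start=100, end=200, summit=200),          # summit past the end
    dict(start=100, end=200, summit=99),           # summit before the start
    dict(start=100, end=200, summit=150, neg_log10_p=-1.0),
])
def test_peak_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        Peak(chrom="chr1", **kwargs)


# -- file readers ------------------------------------------------------------

def test_read_narrowpeak_summit_offset(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t300\tpk1\t57\t.\t57\t8.5\t-1\t40\n")
    peaks = read_peaks(p, format="narrowPeak")
    assert len(peaks) == 1
    assert peaks[0].summit == 140
    assert peaks[0].score == 57
    assert peaks[0].neg_log10_p == 8.5


def test_read_bed_midpoint_summit(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t201\n")
    peaks = read_peaks(p, format="BED")
    assert peaks[0].summit == 150  # floor midpoint


def test_read_peaks_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "empty.bed"
    p.write_text("")
    with caplog.at_level("WARNING"):
        assert read_peaks(p, format="BED") == []
    assert "no peak records" in caplog.text


def test_read_peaks_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.narrowPeak"
    p.write_text("chr1\t100\t300\tpk\t5\t.\t5\t2\t-1\t40\nchr1\tnotanumber\t300\n")
    with pytest.raises(ValueError, match="line 2"):
        read_peaks(p, format="narrowPeak")


def test_read_peaks_unknown_format_token(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t1\t2\n")
    with pytest.raises(ValueError, match="unknown peak format"):
        read_peaks(p, format="gff")


# -- replicate intersection --------------------------------------------------

def test_intersect_identical_lists_pairs_everything():
    a = [peak(s) for s in (1000, 5000, 9000)]
    pairs = intersect_replicates(a, a)
    assert len(pairs) == 3
    assert all(pa.summit == pb.summit for pa, pb in pairs)


def test_intersect_greedy_consumes_nearest_first():
    # 450 pairs with 600 (d=150), not with 100 (d=350); 100 left unpaired
    a = [peak(s) for s in (100, 600, 1000)]
    b = [peak(s) for s in (450, 990)]
    pairs = intersect_replicates(a, b, max_summit_dist=400, strict=True)
    assert {(pa.summit, pb.summit) for pa, pb in pairs} == {(600, 450), (1000, 990)}


def test_intersect_strict_boundary():
    a, b = [peak(1000)], [peak(1400)]
    assert intersect_replicates(a, b, 400, strict=True) == []
    assert len(intersect_replicates(a, b, 400, strict=False)) == 1


def test_intersect_zero_distance_strict_is_empty():
    a = [peak(s) for s in (100, 200)]
    assert intersect_replicates(a, a, max_summit_dist=0, strict=True) == []


def test_intersect_negative_distance_rejected():
    with pytest.raises(ValueError):
        intersect_replicates([peak(100)], [peak(100)], max_summit_dist=-1)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.data())
def test_intersect_symmetric_and_bounded(data):
    summits_a = data.draw(st.lists(st.integers(0, 20_000), min_size=0, max_size=30,
                                   unique=True))
    summits_b = data.draw(st.lists(st.integers(0, 20_000), min_size=0, max_size=30,
                                   unique=True))
    a = [peak(s + 200) for s in summits_a]
    b = [peak(s + 200) for s in summits_b]
    fwd = intersect_replicates(a, b, 400, strict=True)
    rev = intersect_replicates(b, a, 400, strict=True)
    assert {(x.summit, y.summit) for x, y in fwd} == {(y.summit, x.summit) for x, y in rev}
    assert len(fwd) <= min(len(a), len(b))


# -- score correlation -------------------------------------------------------

def test_correlation_identical_scores_is_one():
    pairs = [(peak(100, score=s), peak(100, score=s)) for s in (5.0, 50.0, 500.0)]
    assert peak_score_correlation(pairs) == pytest.approx(1.0)


def test_correlation_reversed_log_scores_is_minus_one():
    pairs = [(peak(100, score=a), peak(100, score=b))
             for a, b in ((10, 1000), (100, 100), (1000, 10))]
    assert peak_score_correlation(pairs) == pytest.approx(-1.0)


def test_correlation_two_pairs_is_plus_or_minus_one():
    pairs = [(peak(1, score=3.0), peak(1, score=7.0)), (peak(2, score=9.0), peak(2, score=2.0))]
    assert abs(peak_score_correlation(pairs)) == pytest.approx(1.0)


def test_correlation_rejects_nonpositive_score():
    pairs = [(peak(1, score=0.0), peak(1, score=1.0)), (peak(2, score=2.0), peak(2, score=2.0))]
    with pytest.raises(ValueError, match="non-positive score"):
        peak_score_correlation(pairs)


def test_correlation_needs_two_pairs():
    with pytest.raises(ValueError):
        peak_score_correlation([(peak(1), peak(1))])


# -- gene assignment ---------------------------------------------------------

def gene(tss, strand="+", gene_id="GA", chrom="chr1", length=3000, intron=None):
    if strand == "+":
        span = (tss, tss + length)
    else:
        span = (tss - length + 1, tss + 1)
    return GeneModel(gene_id=gene_id, symbol=gene_id, chrom=chrom, strand=strand,
                     tss=tss, span=span, first_intron=intron)


def test_assign_nearest_tss_and_sign():
    genes = [gene(1000, gene_id="GA"), gene(5000, gene_id="GB")]
    links = assign_to_genes([peak(1200)], genes)
    assert links[0].gene.gene_id == "GA"
    assert links[0].signed_tss_distance == 200  # downstream on + strand


def test_assign_midway_tie_goes_to_lower_coordinate():
    genes = [gene(1000, gene_id="GB"), gene(3000, gene_id="GA")]
    links = assign_to_genes([peak(2000)], genes)
    assert links[0].gene.tss == 1000


def test_assign_unknown_chromosome_yields_unassigned(caplog):
    with caplog.at_level("WARNING"):
        links = assign_to_genes([peak(100, chrom="chrUn")], [gene(1000)])
    assert links[0].gene is None
    assert not links[0].is_assigned


def test_assign_matches_bruteforce_oracle(default_fixture):
    genes = default_fixture.genes
    peaks = shared_peaks(intersect_replicates(default_fixture.planted.rep1,
                                              default_fixture.planted.rep2))
    links = assign_to_genes(peaks, genes)
    for ln in links:
        expected = brute_nearest_tss(genes, ln.peak.chrom, ln.peak.summit)
        assert ln.gene.gene_id == expected.gene_id


def test_assign_minus_strand_upstream_sign():
    g = gene(5000, strand="-", gene_id="GM")
    links = assign_to_genes([peak(6000)], [g])  # genomically right = upstream on -
    assert links[0].signed_tss_distance == -1000


def test_assign_distance_cap():
    links = assign_to_genes([peak(50_000)], [gene(1000)], max_distance=10_000)
    assert links[0].gene is None


# -- region classification ---------------------------------------------------

def test_classify_upstream_window():
    g = gene(50_000)
    links = assign_to_genes([peak(45_000)], [g])
    assert classify_location(links[0]) is RegionClass.UPSTREAM_10KB


def test_classify_first_intron_containment_and_precedence():
    g = gene(10_000, intron=(10_200, 12_000))
    links = assign_to_genes([peak(11_000)], [g])
    assert classify_location(links[0]) is RegionClass.FIRST_INTRON


def test_classify_window_boundaries():
    g = gene(50_000)
    at_edge = assign_to_genes([peak(40_000)], [g])[0]       # exactly 10 kb upstream
    past_edge = assign_to_genes([peak(39_999)], [g])[0]     # 10 kb + 1
    far = assign_to_genes([peak(29_999)], [g])[0]           # 20,001 upstream
    assert classify_location(at_edge) is RegionClass.UPSTREAM_10KB
    assert classify_location(past_edge) is RegionClass.OTHER
    assert classify_location(far) is RegionClass.OTHER


# -- GTF round trip ----------------------------------------------------------

def test_gtf_round_trip(tmp_path, tiny_fixture):
    path = tmp_path / "genes.gtf"
    write_genes_gtf(tiny_fixture.genes, path)
    back = read_genes_gtf(path)
    assert back == sorted(tiny_fixture.genes, key=lambda g: (g.chrom, g.span[0], g.gene_id))
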