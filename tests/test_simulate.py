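"""Synthetic-data generators: determinism, invariants, planted truth."""
import hashlib
import json

import pytest

from apcscreen.intervals import intersect_replicates, read_genes_gtf, write_genes_gtf
from apcscreen.motifs import MotifPattern
from apcscreen.simulate import (child_seed, make_annotation, make_expression,
                                make_fixture, make_genome, make_reporter, plant_peaks,
                                write_fasta)

AP1 = MotifPattern("AP-1", "TGASTCA")


def genome_hash(genome):
    h = hashlib.sha256()
    for chrom in sorted(genome):
        h.update(chrom.encode())
        h.update(genome[chrom].encode())
    return h.hexdigest()


# -- genome ------------------------------------------------------------------

def test_genome_deterministic_per_seed():
    assert genome_hash(make_genome(4, 1, 20_000)) == genome_hash(make_genome(4, 1, 20_000))
    assert genome_hash(make_genome(4, 1, 20_000)) != genome_hash(make_genome(5, 1, 20_000))


def test_genome_gc_fraction_near_half():
    g = make_genome(12, n_chrom=1, chrom_len=1_000_000)["chr1"]
    gc = (g.count("G") + g.count("C")) / len(g)
    assert gc == pytest.approx(0.5, abs=0.01)


def test_genome_rejects_tiny_chromosomes():
    with pytest.raises(ValueError):
        make_genome(1, 1, 5_000)


def test_fasta_write_round_trip(tmp_path):
    from pyfaidx import Fasta
    g = make_genome(6, n_chrom=2, chrom_len=10_000)
    path = tmp_path / "g.fa"
    write_fasta(g, path)
    fa = Fasta(str(path))
    assert str(fa["chr2"][:]) == g["chr2"]


# -- annotation --------------------------------------------------------------

def test_annotation_models_satisfy_invariants():
    genes = make_annotation(8, {"chr1": 500_000, "chr2": 500_000}, n_genes=80)
    assert len(genes) == 80
    strands = [g.strand for g in genes]
    assert abs(strands.count("+") - strands.count("-")) <= 1
    by_chrom = {}
    for g in genes:
        s, e = g.span
        assert g.first_intron is not None
        i0, i1 = g.first_intron
        assert s < i0 < i1 < e
        assert g.tss == (s if g.strand == "+" else e - 1)
        by_chrom.setdefault(g.chrom, []).append(g.span)
    for spans in by_chrom.values():  # non-overlapping placement
        spans.sort()
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


def test_annotation_raises_when_genome_too_small():
    with pytest.raises(ValueError, match="longer genome"):
        make_annotation(1, {"chr1": 20_000}, n_genes=50)


def test_annotation_gtf_round_trip(tmp_path):
    genes = make_annotation(3, {"chr1": 300_000}, n_genes=20)
    path = tmp_path / "ann.gtf"
    write_genes_gtf(genes, path)
    assert read_genes_gtf(path) == genes


# -- peak planting -----------------------------------------------------------

def test_planted_peaks_all_recovered_without_dropout_or_jitter():
    g = make_genome(14, 1, 300_000)
    planted = plant_peaks(14, g, n_peaks=50, replicate_jitter_sd=0.0, dropout=0.0)
    pairs = intersect_replicates(planted.rep1, planted.rep2)
    assert len(pairs) == 50
    assert all(pa.summit == pb.summit for pa, pb in pairs)


def test_dropout_fraction_controls_shared_recovery():
    g = make_genome(15, 1, 400_000)
    planted = plant_peaks(15, g, n_peaks=60, dropout=0.2)
    assert planted.n_shared == 48  # exactly 80% shared
    pairs = intersect_replicates(planted.rep1, planted.rep2)
    assert len(pairs) == 48


def test_motif_plan_fractions_exact():
    g = make_genome(16, 1, 400_000)
    planted = plant_peaks(16, g, n_peaks=100, dropout=0.0, top_frac=0.2,
                          motif_plan={AP1: (0.5, 0.25)})
    top = set(planted.top_ids)
    carriers = set(planted.motif_carriers["AP-1"])
    assert len(carriers & top) == 10          # 50% of 20 top peaks
    assert len(carriers - top) == 20          # 25% of 80 remaining peaks


def test_plant_peaks_deterministic():
    g = make_genome(17, 1, 300_000)
    a = plant_peaks(17, g, n_peaks=30, dropout=0.1)
    b = plant_peaks(17, g, n_peaks=30, dropout=0.1)
    assert a.rep1 == b.rep1 and a.rep2 == b.rep2
    assert genome_hash(a.genome) == genome_hash(b.genome)


def test_plant_peaks_rejects_oversized_motif():
    g = make_genome(18, 1, 50_000)
    long_motif = MotifPattern("long", "A" * 200)
    with pytest.raises(ValueError, match="too long"):
        plant_peaks(18, g, n_peaks=5, motif_plan={long_motif: (0.5, 0.5)})


# -- expression and reporter -------------------------------------------------

def test_expression_shuffling_gene_order_is_irrelevant():
    symbols = [f"GENE{i:03d}" for i in range(50)]
    conc = {symbols[i]: "up" for i in range(10)}
    data = make_expression(44, symbols, conc, noise_sd=0.0)
    shuffled = make_expression(44, symbols, conc, noise_sd=0.0)
    assert [r.gene for r in data.human_de] == [r.gene for r in shuffled.human_de]
    assert data.expr_a.equals(shuffled.expr_a)


def test_expression_rejects_unknown_planted_gene():
    with pytest.raises(ValueError, match="absent"):
        make_expression(1, ["A"], {"B": "up"})


def test_reporter_zero_noise_reproduces_planted_effects():
    data = make_reporter(9, noise_cv=0.0)
    from apcscreen.reporter import normalize_plate
    df = normalize_plate(data.wells)
    means = df.groupby(["construct", "condition"])["activity"].mean()
    for (construct, cond), effect in data.effects.items():
        base = data.base_activity[construct]
        assert means[(construct, cond)] == pytest.approx(base * effect, rel=1e-9)


# -- fixture-level properties ------------------------------------------------

def test_fixture_seed_fanout_is_stable():
    assert child_seed(11, "genome") == child_seed(11, "genome")
    assert child_seed(11, "genome") != child_seed(11, "genes")
    assert 0 <= child_seed(123456, "peaks") < 2**31


def test_fixture_write_is_reproducible(tmp_path):
    d1 = make_fixture(2, preset="tiny").write(tmp_path / "a")
    d2 = make_fixture(2, preset="tiny").write(tmp_path / "b")
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_fixture_write_refuses_nonempty_dir(tmp_path):
    out = tmp_path / "fx"
    out.mkdir()
    (out / "sentinel.txt").write_text("x")
    with pytest.raises(FileExistsError):
        make_fixture(2, preset="tiny").write(out)
    make_fixture(2, preset="tiny").write(out, force=True)  # explicit override


def test_fixture_truth_json_is_valid(tmp_path):
    fx = make_fixture(2, preset="tiny")
    out = fx.write(tmp_path / "fx")
    truth = json.loads((out / "truth.json").read_text())
    assert truth["candidates"] == fx.truth.candidates
    assert truth["n_shared"] == fx.planted.n_shared
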