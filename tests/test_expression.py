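"""Human DE filtering, BH correction, and the mouse concordance filter."""
import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from apcscreen.expression import (AdenomaPanel, DERecord, bh_fdr, build_adenoma_panels,
                                  filter_human_de, map_orthologs, mouse_concordance,
                                  read_cuffdiff, write_cuffdiff)
from apcscreen.simulate import make_expression, mouse_symbol
from oracles import literal_bh


def de(gene, log2fc, q, p=None):
    return DERecord(gene=gene, fpkm_control=10.0, fpkm_knockdown=10.0 * 2 ** log2fc,
                    log2fc=log2fc, p=p if p is not None else q / 2, q=q)


# -- human DE filter ---------------------------------------------------------

def test_filter_human_de_splits_by_direction():
    records = [de("A", 1.0, 0.01), de("B", -2.0, 0.02), de("C", 0.5, 0.9)]
    up, down = filter_human_de(records)
    assert [r.gene for r in up] == ["A"]
    assert [r.gene for r in down] == ["B"]


def test_filter_human_de_boundary_is_strict():
    up, down = filter_human_de([de("A", 1.0, 0.05)])
    assert up == [] and down == []


def test_filter_human_de_all_insignificant():
    up, down = filter_human_de([de(g, 1.0, 1.0) for g in "ABC"])
    assert up == [] and down == []


def test_filter_human_de_skips_missing_q(caplog):
    with caplog.at_level("WARNING"):
        up, down = filter_human_de([de("A", 1.0, float("nan")), de("B", 1.0, 0.01)])
    assert [r.gene for r in up] == ["B"]
    assert "missing q-values" in caplog.text


def test_cuffdiff_round_trip(tmp_path):
    records = [de("A", 1.5, 0.01), de("B", -0.5, 0.7)]
    path = tmp_path / "de.tsv"
    write_cuffdiff(records, path)
    back = read_cuffdiff(path)
    assert [r.gene for r in back] == ["A", "B"]
    assert back[0].log2fc == pytest.approx(1.5)


# -- BH correction -----------------------------------------------------------

def test_bh_literal_worked_example():
    assert bh_fdr([0.01, 0.02, 0.04]).tolist() == pytest.approx([0.03, 0.03, 0.04])


def test_bh_single_p_unchanged():
    assert bh_fdr([0.37]).tolist() == [0.37]


def test_bh_literal_matches_hand_formula_on_five_element_vectors():
    rng = np.random.default_rng(21)
    for _ in range(200):
        p = rng.uniform(0, 1, size=5).round(3).tolist()
        assert bh_fdr(p).tolist() == pytest.approx(literal_bh(p))


def test_bh_order_free_per_value():
    rng = np.random.default_rng(4)
    p = rng.uniform(0, 1, size=20)
    p = np.unique(p)  # distinct values so the per-value map is well defined
    perm = rng.permutation(p.size)
    direct = dict(zip(p.tolist(), bh_fdr(p).tolist()))
    shuffled = dict(zip(p[perm].tolist(), bh_fdr(p[perm]).tolist()))
    assert direct == pytest.approx(shuffled)


def test_bh_step_up_matches_statsmodels():
    rng = np.random.default_rng(8)
    for _ in range(50):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
        want = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p, mode="step-up").tolist() == pytest.approx(want.tolist())


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_fdr([0.1, 1.2])
    with pytest.raises(ValueError):
        bh_fdr([0.1], mode="bonferroni")


# -- mouse concordance -------------------------------------------------------

def panel(gene, fc_a, fc_b):
    return AdenomaPanel(gene=gene, model_a_fc=tuple(fc_a), model_b_fc=tuple(fc_b))


def test_concordance_requires_fold_in_both_models():
    p = panel("Aaa", [1.2, 1.2, 1.2], [2.0, 2.0, 2.0])
    df = mouse_concordance([p], {"Aaa": "up"})
    assert not df.iloc[0]["passed"]
    assert not df.iloc[0]["fold_ok"]


def test_concordance_passes_clean_concordant_gene():
    p = panel("Aaa", [2.0, 2.1, 1.9], [2.0, 2.2, 1.8])
    df = mouse_concordance([p], {"Aaa": "up"})
    assert bool(df.iloc[0]["passed"])


def test_concordance_direction_must_match_human():
    p = panel("Aaa", [2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    df = mouse_concordance([p], {"Aaa": "down"})
    assert not df.iloc[0]["passed"]


def test_concordance_down_direction():
    p = panel("Aaa", [0.4, 0.5, 0.45], [0.5, 0.4, 0.5])
    df = mouse_concordance([p], {"Aaa": "down"})
    assert bool(df.iloc[0]["passed"])


def test_concordance_t_test_matches_textbook_formula():
    from scipy import stats
    fc_a, fc_b = [1.8, 2.4, 2.1], [1.6, 2.9, 2.2]
    p = panel("Aaa", fc_a, fc_b)
    df = mouse_concordance([p], {"Aaa": "up"})
    x = np.log2(np.array(fc_a + fc_b))
    t = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
    want = 2 * stats.t.sf(abs(t), df=x.size - 1)
    assert df.iloc[0]["t_p"] == pytest.approx(want, rel=1e-9)


def test_concordance_monotone_in_thresholds():
    rng = np.random.default_rng(13)
    panels = [panel(f"G{i}", rng.uniform(0.3, 3.0, 3), rng.uniform(0.3, 3.0, 3))
              for i in range(60)]
    dirs = {f"G{i}": ("up" if i % 2 else "down") for i in range(60)}
    n_loose = mouse_concordance(panels, dirs, min_fold=1.2, fdr_max=0.3)["passed"].sum()
    n_tight_fold = mouse_concordance(panels, dirs, min_fold=1.8, fdr_max=0.3)["passed"].sum()
    n_tight_fdr = mouse_concordance(panels, dirs, min_fold=1.2, fdr_max=0.05)["passed"].sum()
    assert n_tight_fold <= n_loose
    assert n_tight_fdr <= n_loose


def test_concordance_recovers_planted_set_at_zero_noise():
    symbols = [f"GENE{i:03d}" for i in range(120)]
    concordant = {s: ("up" if i % 2 else "down") for i, s in enumerate(symbols[:40])}
    data = make_expression(99, symbols, concordant, noise_sd=0.0)
    panels = build_adenoma_panels(data.expr_a, data.manifest_a, data.expr_b, data.manifest_b)
    dirs = {mouse_symbol(s): d for s, d in concordant.items()}
    dirs.update({mouse_symbol(s): "up" for s in symbols[40:]})
    df = mouse_concordance(panels, dirs)
    passed = set(df.loc[df["passed"], "gene"])
    assert passed == {mouse_symbol(s) for s in concordant}


def test_concordance_untestable_with_too_few_samples():
    p = AdenomaPanel(gene="Aaa", model_a_fc=(2.0,), model_b_fc=())
    df = mouse_concordance([p], {"Aaa": "up"})
    assert not df.iloc[0]["testable"]
    assert not df.iloc[0]["passed"]


# -- ortholog mapping --------------------------------------------------------

def test_map_orthologs_case_insensitive():
    pairs, unmapped = map_orthologs(["PHLDB2", "MALL"], ["Phldb2", "Tom1l2"])
    assert pairs == [("PHLDB2", "Phldb2")]
    assert unmapped == ["MALL"]


def test_map_orthologs_explicit_mapping_overrides():
    pairs, unmapped = map_orthologs(["MYC"], ["Myc", "Mycl"], mapping={"MYC": "Mycl"})
    assert pairs == [("MYC", "Mycl")]


def test_map_orthologs_duplicate_rows_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        map_orthologs(["A"], ["a"], mapping=[("A", "a"), ("A", "b")])
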