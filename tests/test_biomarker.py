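import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermoscore as ts
from conftest import make_study


def _tab(rows):
    df = pd.DataFrame(
        rows, columns=["gene", "cultivar", "log2_induction", "p_value", "stress_level"]
    )
    return ts.InductionTable(table=df, contrasts={}, genes=sorted(set(df["gene"])))


def _candidate_rows(gene, induction, ratio, level):
    return [
        (gene, "AT", induction, 0.01, level),
        (gene, "SF", 1.0, 0.01, level - ratio),
    ]


@pytest.mark.parametrize(
    "induction, ratio, level, selected",
    [
        (6.5, 1.5, 12.5, True),
        (6.0, 1.5, 12.5, False),  # induction boundary: strict inequality
        (6.5, 1.5, 12.0, False),  # level boundary
        (5.0, 3.0, 14.0, False),
    ],
)
def test_selection_criteria_are_strict(induction, ratio, level, selected):
    panel = ts.select_candidates(
        _tab(_candidate_rows("g1", induction, ratio, level)), "AT", "SF"
    )
    assert (panel.genes == ["g1"]) is selected


def test_ratio_criterion_boundary_is_strict():
    # tolerant level 12.5, sensitive 11.0: difference exactly 1.5
    tab = _tab(_candidate_rows("g1", 6.5, 1.5, 12.5))
    assert ts.select_candidates(tab, "AT", "SF", ratio_min_log2=1.5).genes == []
    assert ts.select_candidates(tab, "AT", "SF", ratio_min_log2=1.4375).genes == ["g1"]


def test_selection_monotone_in_each_threshold():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(150):
        rows += _candidate_rows(f"g{i:03d}", rng.uniform(4, 9), rng.uniform(0, 3),
                                rng.uniform(10, 15))
    tab = _tab(rows)
    base = set(ts.select_candidates(tab, "AT", "SF").genes)
    for kw in ("induction_min_log2", "ratio_min_log2", "level_min_log2"):
        defaults = {"induction_min_log2": 6.0, "ratio_min_log2": 1.4, "level_min_log2": 12.0}
        defaults[kw] += 0.7
        tighter = set(ts.select_candidates(tab, "AT", "SF", **defaults).genes)
        assert tighter <= base


def test_panel_sorted_by_tolerant_induction():
    rows = (
        _candidate_rows("gb", 7.0, 2.0, 13.0)
        + _candidate_rows("ga", 7.0, 2.0, 13.0)
        + _candidate_rows("gc", 8.5, 2.0, 13.0)
    )
    panel = ts.select_candidates(_tab(rows), "AT", "SF")
    assert panel.genes == ["gc", "ga", "gb"]  # descending induction, lexicographic tie


def test_selected_genes_are_hsf_pathway(default_sim):
    study, _, _, truth = default_sim
    tab = ts.induction(study, ("acute_50", 1.0), ("control_25", 0.0))
    panel = ts.select_candidates(tab, "AT", "SF")
    assert len(panel.genes) > 0
    assert all(truth.gene_class[g] in ("HSE", "DRE_HSE") for g in panel.genes)


def _scoring_study(gene_means, n_rep=2, noise=0.0):
    """gene_means: {gene: {cultivar: mean log2 at stress}} plus a control group."""
    genes = list(gene_means)
    cultivars = sorted({c for v in gene_means.values() for c in v})
    cols, meta = [], []
    for c in cultivars:
        for treatment, time_h in (("control_25", 0.0), ("acute_50", 2.0)):
            for r in range(1, n_rep + 1):
                col = [
                    gene_means[g][c] if treatment == "acute_50" else 0.0 for g in genes
                ]
                cols.append(col)
                meta.append((c, treatment, time_h, r))
    vals = np.array(cols, dtype=float).T
    return make_study(
        vals,
        cultivars=[m[0] for m in meta],
        treatments=[m[1] for m in meta],
        times=[m[2] for m in meta],
        replicates=[m[3] for m in meta],
        genes=genes,
    )


def test_single_gene_scoring_is_plain_zscore():
    study = _scoring_study({"g1": {"A": 10.0, "B": 8.0, "C": 6.0}})
    st = ts.score_cultivars(study, ["g1"], ("acute_50", 2.0))
    np.testing.assert_allclose(st.mean_z[["A", "B", "C"]], [1.0, 0.0, -1.0])
    assert st.ranking == ["A", "B", "C"]


def test_opposite_genes_cancel():
    study = _scoring_study(
        {"g1": {"A": 10.0, "B": 8.0, "C": 6.0}, "g2": {"A": 6.0, "B": 8.0, "C": 10.0}}
    )
    st = ts.score_cultivars(study, ["g1", "g2"], ("acute_50", 2.0))
    np.testing.assert_allclose(st.mean_z.to_numpy(), 0.0, atol=1e-12)
    assert st.ranking == ["A", "B", "C"]  # all-tied mean z -> lexicographic


def test_scoring_invariant_to_per_gene_location_shift():
    means = {"g1": {"A": 10.0, "B": 8.0, "C": 6.0}, "g2": {"A": 9.0, "B": 9.5, "C": 7.0}}
    st1 = ts.score_cultivars(_scoring_study(means), ["g1", "g2"], ("acute_50", 2.0))
    shifted = {g: {c: v + (50.0 if g == "g1" else 0.0) for c, v in d.items()}
               for g, d in means.items()}
    st2 = ts.score_cultivars(_scoring_study(shifted), ["g1", "g2"], ("acute_50", 2.0))
    np.testing.assert_allclose(st1.mean_z.to_numpy(), st2.mean_z.to_numpy(), atol=1e-9)


def test_degenerate_genes_dropped_then_error(caplog):
    study = _scoring_study({"g1": {"A": 10.0, "B": 8.0}, "flat": {"A": 5.0, "B": 5.0}})
    with caplog.at_level("WARNING", logger="thermoscore"):
        st = ts.score_cultivars(study, ["g1", "flat"], ("acute_50", 2.0))
    assert st.panel_size == 1
    with pytest.raises(ts.ValidationError, match="empty"):
        ts.score_cultivars(study, ["flat"], ("acute_50", 2.0))
    with pytest.raises(ts.ValidationError, match="empty"):
        ts.score_cultivars(study, [], ("acute_50", 2.0))


def _physio_index_from_totals(totals):
    ranking = sorted(totals, key=lambda c: (-totals[c], c))
    return ts.PhysioIndex(
        ratios=pd.DataFrame(), zscores=pd.DataFrame(),
        total=pd.Series(totals), ranking=ranking,
    )


def _score_table_from_means(means):
    s = pd.Series(means)
    ranking = sorted(s.index, key=lambda c: (-s[c], c))
    return ts.ScoreTable(gene_z=pd.DataFrame(), mean_z=s, ranking=ranking, panel_size=1)


def brute_spearman(x, y):
    """Rank both vectors (mean ranks on ties) and Pearson-correlate the ranks."""
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v), float)
        r[order] = np.arange(1, len(v) + 1)
        for val in set(v):
            mask = np.asarray(v) == val
            r[mask] = r[mask].mean()
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def test_concordance_extremes():
    phys = _physio_index_from_totals({"a": 2.0, "b": 1.0, "c": 0.0, "d": -1.0, "e": -2.0})
    same = _score_table_from_means({"a": 1.5, "b": 0.4, "c": 0.1, "d": -0.6, "e": -1.4})
    assert ts.concordance(same, phys) == pytest.approx(1.0)
    flipped = _score_table_from_means({"a": -1.5, "b": -0.4, "c": -0.1, "d": 0.6, "e": 1.4})
    assert ts.concordance(flipped, phys) == pytest.approx(-1.0)
    with pytest.raises(ts.ValidationError):
        ts.concordance(_score_table_from_means({"a": 1, "b": 0}),
                       _physio_index_from_totals({"a": 1.0, "b": 0.0}))


def test_concordance_matches_brute_force_on_synthetic(default_sim):
    study, _, physio, truth = default_sim
    idx = ts.composite_index(ts.parameter_ratios(physio))
    tab = ts.induction(study, ("acute_50", 1.0), ("control_25", 0.0))
    panel = ts.select_candidates(tab, "AT", "SF")
    st = ts.score_cultivars(study, panel.genes, ("acute_50", 1.0))
    rho = ts.concordance(st, idx)
    common = list(st.mean_z.index)
    expected = brute_spearman(
        [st.mean_z[c] for c in common], [idx.total[c] for c in common]
    )
    assert rho == pytest.approx(expected, abs=1e-12)


def test_four_gene_subpanel_keeps_extremes(default_sim):
    """A 4-gene sub-panel and the full panel agree on the extreme cultivars."""
    study, _, _, truth = default_sim
    tab = ts.induction(study, ("acute_50", 1.0), ("control_25", 0.0))
    panel = ts.select_candidates(tab, "AT", "SF")
    full = ts.score_cultivars(study, panel.genes, ("acute_50", 1.0))
    sub = ts.score_cultivars(study, panel.genes[:4], ("acute_50", 1.0))
    assert (full.most_tolerant, full.most_sensitive) == (sub.most_tolerant, sub.most_sensitive)
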