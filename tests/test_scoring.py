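import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from looa.errors import DegenerateDataError, GraphSizeError, ParameterError
from looa.perturbation import loeo_deltas, lovo_deltas
from looa.scoring import (
    ComponentSelection,
    PcaModel,
    classify_hubs,
    composite_scores,
    correlation_matrix,
    cos2,
    fit_pca,
    rank_elements,
    score_influence,
    select_components,
)
from tests.conftest import random_delta_matrix


def delta_frame(data: dict) -> pd.DataFrame:
    frame = pd.DataFrame(data)
    frame.index = pd.Index([f"E{i}" for i in range(len(frame))], name="element")
    return frame


def dummy_model(eigenvalues, variance_pct) -> PcaModel:
    empty = pd.DataFrame()
    return PcaModel(
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        variance_pct=np.asarray(variance_pct, dtype=float),
        loadings=empty,
        scores=empty,
        components=empty,
    )


class TestCorrelationMatrix:
    def test_perfect_linear_relation(self):
        base = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        d = delta_frame({"dDC": base, "dEC": 2 * base, "dBC": [0, 1, 0, 1, 2],
                         "dCC": [5, 3, 1, 2, 4], "dGCC": [1, 1, 2, 3, 5]})
        corr = correlation_matrix(d)
        assert corr.loc["dDC", "dEC"] == pytest.approx(1.0)

    def test_zero_variance_column_reported_missing(self):
        d = delta_frame({"dDC": [2.0, 2.0, 2.0], "dEC": [1.0, 2.0, 3.0], "dBC": [3.0, 1.0, 2.0]})
        corr = correlation_matrix(d)
        assert corr["dDC"].isna().all()
        assert corr.loc["dEC", "dBC"] == pytest.approx(-0.5)

    def test_matches_textbook_pearson_formula(self):
        rng = np.random.default_rng(2)
        d = delta_frame({c: rng.normal(size=5) for c in ["dDC", "dEC", "dBC", "dCC", "dGCC"]})
        corr = correlation_matrix(d)
        for a in d.columns:
            for b in d.columns:
                x, y = d[a].to_numpy(), d[b].to_numpy()
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert corr.loc[a, b] == pytest.approx(num / den, abs=1e-12)

    def test_too_few_rows(self):
        with pytest.raises(GraphSizeError):
            correlation_matrix(delta_frame({"dDC": [1.0, 2.0]}))


class TestFitPca:
    def test_identical_columns_give_rank_one_model(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        d = delta_frame({c: base for c in ["dDC", "dEC", "dBC", "dCC", "dGCC"]})
        model = fit_pca(d)
        assert model.eigenvalues[0] == pytest.approx(5.0)
        assert model.variance_pct[0] == pytest.approx(100.0)
        assert model.eigenvalues[1:] == pytest.approx(np.zeros(4), abs=1e-9)

    def test_independent_noise_gives_flat_spectrum(self):
        rng = np.random.default_rng(0)
        d = delta_frame({c: rng.normal(size=10000) for c in ["dDC", "dEC", "dBC", "dCC", "dGCC"]})
        model = fit_pca(d)
        assert model.eigenvalues == pytest.approx(np.ones(5), abs=0.1)

    def test_loeo_sum_mode_drops_constant_degree_column(self, toys):
        model = fit_pca(loeo_deltas(toys["barbell"]))
        assert model.dropped_columns == ["dDC"]
        assert model.retained_columns == ["dEC", "dBC", "dCC", "dGCC"]

    def test_degenerate_matrix_names_constant_columns(self):
        d = delta_frame({"dDC": [2.0] * 4, "dEC": [0.0] * 4, "dBC": [1.0, 2.0, 3.0, 4.0],
                         "dCC": [1.0] * 4, "dGCC": [0.5] * 4})
        with pytest.raises(DegenerateDataError, match="dDC"):
            fit_pca(d)

    def test_eigenvalue_sum_cos2_rows_and_reconstruction(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            d = random_delta_matrix(rng)
            model = fit_pca(d)
            assert model.eigenvalues.sum() == pytest.approx(len(model.retained_columns), abs=1e-9)
            assert model.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)
            table = cos2(model)
            assert table.sum(axis=1).to_numpy() == pytest.approx(np.ones(len(table)), abs=1e-9)
            assert ((table.to_numpy() >= -1e-12) & (table.to_numpy() <= 1 + 1e-12)).all()
            data = d[model.retained_columns].to_numpy()
            z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
            recon = model.scores.to_numpy() @ model.components.to_numpy().T
            assert np.abs(recon - z).max() < 1e-8

    def test_two_variable_cos2_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.6 * x + 0.8 * rng.normal(size=200)
        d = delta_frame({"dDC": x, "dEC": y})
        r = abs(np.corrcoef(x, y)[0, 1])
        table = cos2(fit_pca(d))
        assert table["PC1"].to_numpy() == pytest.approx(np.full(2, (1 + r) / 2), abs=1e-9)


class TestSelectComponents:
    def test_kaiser_rule_prefix(self):
        sel = select_components(dummy_model([3.2, 1.1, 0.45, 0.15, 0.10], [64, 22, 9, 3, 2]))
        assert sel.selected == (0, 1)
        assert "eigenvalue" in sel.rule_hits[0]

    def test_variance_rule_extends_selection(self):
        sel = select_components(dummy_model([2.0, 0.9, 0.6, 0.3, 0.2], [40, 18, 12, 6, 4]))
        assert sel.selected == (0, 1, 2)
        assert sel.rule_hits[1] == ("variance",)
        assert sel.rule_hits[2] == ("variance",)

    def test_minimum_one_component_fallback(self):
        sel = select_components(dummy_model([0.9, 0.45], [9.0, 4.5]))
        assert sel.selected == (0,)
        assert sel.rule_hits[0] == ("fallback",)

    def test_invalid_thresholds(self):
        with pytest.raises(ParameterError):
            select_components(dummy_model([1.0], [100.0]), kaiser_cut=0)


class TestCompositeAndRanking:
    def test_single_component_is_identity(self):
        rng = np.random.default_rng(4)
        d = random_delta_matrix(rng)
        model = fit_pca(d)
        scores = composite_scores(model, ComponentSelection((0,), {0: ("eigenvalue",)}))
        assert scores["composite_score"].to_numpy() == pytest.approx(
            model.scores["PC1"].to_numpy()
        )

    def test_element_at_column_means_scores_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 5))
        mean = x.mean(axis=0)
        data = np.vstack([x, 2 * mean - x, mean])
        d = pd.DataFrame(data, columns=["dDC", "dEC", "dBC", "dCC", "dGCC"],
                         index=pd.Index([f"E{i:02d}" for i in range(17)], name="element"))
        model = fit_pca(d)
        scores = composite_scores(model, select_components(model))
        assert scores.loc["E16", "composite_score"] == pytest.approx(0.0, abs=1e-10)

    def test_ranking_tie_break_and_truncation(self):
        table = pd.DataFrame(
            {"composite_score": [2.0, 2.0, 1.0]},
            index=pd.Index(["B", "A", "C"], name="element"),
        )
        top = rank_elements(table, top_n=2)
        assert list(top.index) == ["A", "B"]
        assert list(top["rank"]) == [1, 2]
        assert len(rank_elements(table, top_n=10)) == 3
        with pytest.raises(ParameterError):
            rank_elements(table, top_n=0)

    def test_ranking_invariant_under_column_rescaling(self):
        rng = np.random.default_rng(13)
        d = random_delta_matrix(rng)
        scaled = d.copy()
        scaled["dCC"] = scaled["dCC"] * 37.0
        r1 = score_influence(d).ranking
        r2 = score_influence(scaled).ranking
        assert list(r1.index) == list(r2.index)

    def test_star_center_is_rank_one(self, toys):
        result = score_influence(lovo_deltas(toys["star4"]), graph=toys["star4"])
        assert result.ranking.index[0] == "C"

    def test_clique_vertices_tie_exactly(self, toys):
        result = score_influence(lovo_deltas(toys["k5"]), graph=toys["k5"])
        assert (result.scores["composite_score"] == 0.0).all()
        assert list(result.ranking.index) == sorted(result.ranking.index)

    def test_barbell_bridge_is_top_interaction(self, toys):
        result = score_influence(loeo_deltas(toys["barbell"]))
        assert result.ranking.index[0] == "L0---R0"


class TestHubClasses:
    @pytest.mark.parametrize(
        "degree,expected",
        [(100, "mega"), (150, "mega"), (99, "major"), (50, "major"),
         (49, "midi"), (10, "midi"), (9, "mini"), (6, "mini"), (5, "sub"), (1, "sub")],
    )
    def test_degree_bins(self, degree, expected):
        g = nx.star_graph(degree)
        assert classify_hubs(g)[0] == expected
        assert classify_hubs(g)[1] == "sub"

    def test_lovo_ranking_carries_hub_class(self, toys):
        result = score_influence(lovo_deltas(toys["star4"]), graph=toys["star4"])
        assert list(result.ranking["hub_class"]) == ["sub"] * 5
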