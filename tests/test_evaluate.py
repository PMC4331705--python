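"""Enrichment testing, grid selection, cross-validation and GO-style helpers."""

import numpy as np
import pandas as pd
import pytest

from netrank import (
    EvalResult,
    GeneSet,
    GeneSetCollection,
    GeneUniverse,
    TuningGrid,
    aggregate,
    coexpression_rank_lists,
    correlation_with_training_size,
    cross_validate,
    filter_gene_sets,
    log_p_fold,
    select_parameters,
    wilcoxon_enrichment_p,
)
from netrank.containers import AggregationResult
from netrank.synthetic import FixtureConfig, generate_fixture

from conftest import make_rank_matrix


def _result_with_ranks(genes, ranks):
    universe = GeneUniverse(genes)
    return AggregationResult(
        universe, np.asarray(ranks, dtype=float), np.asarray(ranks, dtype=np.int64), "rra"
    )


class TestWilcoxonEnrichment:
    def test_exact_top_two_of_four(self):
        res = _result_with_ranks(["a", "b", "c", "d"], [1, 2, 3, 4])
        # 6 equally likely rank assignments for the positive pair; one is {1,2}
        assert wilcoxon_enrichment_p(res, ["a", "b"]) == pytest.approx(1 / 6)

    def test_bottom_positives_not_enriched(self):
        res = _result_with_ranks(["a", "b", "c", "d", "e", "f"], [1, 2, 3, 4, 5, 6])
        assert wilcoxon_enrichment_p(res, ["e", "f"]) >= 0.5

    def test_boundary_stays_in_unit_interval(self):
        genes = [f"g{i}" for i in range(8)]
        res = _result_with_ranks(genes, range(1, 9))
        p = wilcoxon_enrichment_p(res, genes[1:])  # all but the best-ranked gene
        assert 0 < p <= 1

    def test_excluded_genes_leave_background(self):
        res = _result_with_ranks(["a", "b", "c", "d", "e"], [1, 2, 3, 4, 5])
        p_all = wilcoxon_enrichment_p(res, ["a"])
        p_excl = wilcoxon_enrichment_p(res, ["a"], excluded=["b", "c"])
        assert p_excl != p_all  # background shrank from 4 to 2 genes

    def test_empty_groups_rejected(self):
        res = _result_with_ranks(["a", "b"], [1, 2])
        with pytest.raises(ValueError):
            wilcoxon_enrichment_p(res, [])
        with pytest.raises(ValueError):
            wilcoxon_enrichment_p(res, ["a"], excluded=["b"])


@pytest.fixture(scope="module")
def small_fixture():
    cfg = FixtureConfig(
        n_genes=80, n_lists=3, n_positives=12, p_in=0.4, p_out=0.03,
        signal_strength=1.5, seed=42,
    )
    return generate_fixture(cfg)


class TestSelectParameters:
    def test_no_network_point_dominates(self, small_fixture):
        net, ranks, gsc = small_fixture
        training = list(gsc["planted"].genes)[:6]
        grid = TuningGrid(taus=(0.1,), lams=(0.0, 0.5, 2.0))
        sel = select_parameters(ranks, net, training, grid, "cgi", "rra")
        baseline = select_parameters(
            ranks, net, training, TuningGrid(taus=(0.1,), lams=(0.0,)), "cgi", "rra"
        )
        assert sel.p <= baseline.p

    def test_singleton_grid_returned_verbatim(self, small_fixture):
        net, ranks, gsc = small_fixture
        training = list(gsc["planted"].genes)[:6]
        sel = select_parameters(
            ranks, net, training, TuningGrid(ds=(0.3,)), "gr", "endeavour"
        )
        assert sel.params == {"d": 0.3}
        assert sel.method == "gr_endeavour"

    def test_empty_training_rejected(self, small_fixture):
        net, ranks, _ = small_fixture
        with pytest.raises(ValueError):
            select_parameters(ranks, net, [], TuningGrid(), "cgi", "rra")


class TestCrossValidate:
    def test_emits_rounds_times_folds_records(self, small_fixture):
        net, ranks, gsc = small_fixture
        ev = cross_validate(
            ranks, None, list(gsc["planted"].genes), TuningGrid(),
            tuner="none", aggregator="rra", rounds=3, folds=4, seed=5,
        )
        assert len(ev) == 12
        assert set(ev.records["method"]) == {"rra"}

    def test_plain_arm_reproduces_direct_aggregation(self, small_fixture):
        net, ranks, gsc = small_fixture
        positives = list(gsc["planted"].genes)
        ev = cross_validate(
            ranks, None, positives, TuningGrid(), tuner="none",
            aggregator="endeavour", rounds=1, folds=4, seed=9,
        )
        # recompute one fold by hand from the plain aggregated list
        res = aggregate(ranks, method="endeavour")
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(positives))
        fold0 = sorted(np.array_split(np.array(sorted(set(positives)), dtype=object)[perm], 4)[0].tolist())
        validation = sorted(set(positives) - set(fold0))
        expected = wilcoxon_enrichment_p(res, validation, excluded=fold0)
        assert ev.records.loc[0, "p"] == pytest.approx(expected)

    def test_same_seed_identical_results(self, small_fixture):
        net, ranks, gsc = small_fixture
        kwargs = dict(
            lists=ranks, net=net, positives=list(gsc["planted"].genes),
            grid=TuningGrid(taus=(0.1,), lams=(0.0, 1.0)), tuner="cgi",
            aggregator="rra", rounds=2, folds=4, seed=21,
        )
        pd.testing.assert_frame_equal(
            cross_validate(**kwargs).records, cross_validate(**kwargs).records
        )

    def test_too_few_positives_rejected(self, small_fixture):
        net, ranks, _ = small_fixture
        with pytest.raises(ValueError, match="at least"):
            cross_validate(
                ranks, net, ["g0000", "g0001"], TuningGrid(),
                tuner="none", aggregator="rra", folds=10,
            )


class TestLogPFold:
    @pytest.mark.parametrize(
        "p_base, p_net, expected",
        [(0.01, 0.001, 1.0), (0.01, 0.01, 0.0), (0.001, 0.01, -1.0)],
    )
    def test_values(self, p_base, p_net, expected):
        assert log_p_fold(p_base, p_net) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_p_fold(0.0, 0.5)


def _records(rows):
    df = pd.DataFrame(rows)
    for col in ("tau", "lam", "d"):
        df[col] = np.nan
    return EvalResult(df)


class TestCorrelationWithTrainingSize:
    def _paired_records(self, lpf_by_set):
        rows = []
        for gs, lpf in lpf_by_set.items():
            for fold in range(3):
                rows.append(dict(gene_set=gs, method="rra", round=0, fold=fold, p=1e-3))
                rows.append(
                    dict(gene_set=gs, method="cgi_rra", round=0, fold=fold, p=1e-3 * 10 ** (-lpf))
                )
        return _records(rows)

    def test_perfectly_increasing_improvement(self):
        records = self._paired_records({"A": 0.5, "B": 1.0, "C": 2.0})
        sizes = {"A": 3, "B": 5, "C": 9}
        mean_corr, sd, mean_p = correlation_with_training_size(
            records, sizes, method="cgi_rra", baseline="rra"
        )
        assert mean_corr == pytest.approx(1.0)
        assert mean_p < 0.5

    def test_two_gene_sets_rejected(self):
        records = self._paired_records({"A": 0.5, "B": 1.0})
        with pytest.raises(ValueError, match="3 gene sets"):
            correlation_with_training_size(records, {"A": 3, "B": 5}, "cgi_rra", "rra")

    def test_size_independent_improvement_near_zero(self):
        # permute the improvements across many synthetic rounds: the mean
        # correlation over rounds should hover near 0
        rng = np.random.default_rng(123)
        sizes = {f"S{i}": i + 3 for i in range(8)}
        rows = []
        for rnd in range(40):
            lpf = rng.permutation(8) / 4.0
            for i, gs in enumerate(sizes):
                rows.append(dict(gene_set=gs, method="rra", round=rnd, fold=0, p=1e-2))
                rows.append(
                    dict(gene_set=gs, method="cgi_rra", round=rnd, fold=0, p=1e-2 * 10 ** (-lpf[i]))
                )
        mean_corr, _sd, _p = correlation_with_training_size(
            _records(rows), sizes, "cgi_rra", "rra"
        )
        assert abs(mean_corr) < 0.2


class TestFilterGeneSets:
    def _gsc(self, n_genes, n_tfs):
        genes = tuple(f"g{i}" for i in range(n_genes))
        tfs = tuple(f"tf{i}" for i in range(n_tfs))
        return GeneSetCollection([GeneSet("S", genes, tfs)])

    @pytest.mark.parametrize(
        "n_genes, n_tfs, kept",
        [
            (29, 6, False),   # too few genes
            (30, 5, True),    # inclusive boundaries
            (30, 4, False),   # too few TFs
            (30, 40, True),   # upper boundary inclusive
            (30, 41, False),  # too many TFs
        ],
    )
    def test_thresholds(self, n_genes, n_tfs, kept):
        out = filter_gene_sets(self._gsc(n_genes, n_tfs))
        assert ("S" in out) == kept


class TestCoexpressionRankLists:
    def _expr(self):
        rng = np.random.default_rng(4)
        tf = rng.normal(size=10)
        data = {
            "TF1": tf,
            "copy": tf * 2.0,          # |r| = 1
            "anti": -tf,               # |r| = 1
            "flat": np.zeros(10),      # zero variance
            "noise": rng.normal(size=10),
        }
        return pd.DataFrame.from_dict(data, orient="index")

    def test_tf_and_copies_rank_top(self):
        rm = coexpression_rank_lists(self._expr(), ["TF1"])
        ranks = dict(zip(rm.universe.genes, rm.ranks["TF1"]))
        assert ranks["TF1"] < ranks["noise"]
        assert ranks["copy"] <= 3 and ranks["anti"] <= 3
        assert ranks["flat"] == 5  # zero-variance profile sinks to the bottom

    def test_too_few_conditions_rejected(self):
        expr = pd.DataFrame({"c1": [1.0, 2.0], "c2": [2.0, 1.0]}, index=["TF1", "g"])
        with pytest.raises(ValueError, match="3 conditions"):
            coexpression_rank_lists(expr, ["TF1"])

    def test_unknown_tf_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            coexpression_rank_lists(self._expr(), ["nope"])
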