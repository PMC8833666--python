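import numpy as np
import pandas as pd
import pytest

from selenet import synthetic
from selenet.errors import DataError, ParameterError
from selenet.expression import (
    CqTable,
    ExpressionMatrix,
    consensus_direction,
    ddcq_fold_change,
    direction_table,
    mean_profiles,
    select_de_genes,
)


def make_matrix(values: dict[str, list[float]], genes: list[str], groups: dict[str, str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=genes), groups)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return make_matrix(
        {"t1": [8.0, 3.0, 5.0], "t2": [8.0, 3.0, 5.0], "n1": [2.0, 2.0, 5.0], "n2": [2.0, 2.0, 5.0]},
        ["G_UP", "G_MID", "G_FLAT"],
        {"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"},
    )


class TestProfilesAndDirections:
    def test_single_sample_profile_equals_column(self):
        m = make_matrix({"s1": [2.0, 4.0]}, ["A", "B"], {"s1": "tumor"})
        prof = mean_profiles(m, ["tumor"])
        assert list(prof["tumor"]) == [2.0, 4.0]

    def test_group_mean(self, small_matrix):
        prof = mean_profiles(small_matrix, ["tumor", "normal"])
        assert prof.loc["G_UP", "tumor"] == 8.0
        assert prof.loc["G_UP", "normal"] == 2.0

    def test_unknown_group_rejected(self, small_matrix):
        with pytest.raises(ParameterError):
            mean_profiles(small_matrix, ["tumor", "stroma"])

    def test_direction_calls(self, small_matrix):
        prof = mean_profiles(small_matrix, ["tumor", "normal"])
        calls = direction_table(prof, "tumor", "normal")
        assert calls["G_UP"] == "higher"
        assert calls["G_FLAT"] == "equal"

    def test_direction_equal_within_tolerance(self):
        prof = pd.DataFrame({"a": [1.0], "b": [1.0 + 1e-12]}, index=["G"])
        assert direction_table(prof, "a", "b")["G"] == "equal"


class TestDESelection:
    def test_exact_arithmetic_up_call(self, small_matrix):
        fct = select_de_genes(small_matrix, "tumor", "normal")
        assert fct.table.loc["G_UP", "log2fc"] == pytest.approx(2.0)
        assert fct.table.loc["G_UP", "status"] == "up"
        assert fct.up == ["G_UP"]

    def test_subthreshold_ratio_is_unchanged(self, small_matrix):
        fct = select_de_genes(small_matrix, "tumor", "normal")
        assert fct.table.loc["G_MID", "log2fc"] == pytest.approx(np.log2(1.5))
        assert fct.table.loc["G_MID", "status"] == "unchanged"

    def test_zero_reference_mean_is_undefined_with_warning(self):
        m = make_matrix({"t": [4.0], "n": [0.0]}, ["G"], {"t": "tumor", "n": "normal"})
        with pytest.warns(UserWarning):
            fct = select_de_genes(m, "tumor", "normal")
        assert fct.table.loc["G", "status"] == "undefined"

    def test_pseudocount_rescues_zero_mean(self):
        m = make_matrix({"t": [4.0], "n": [0.0]}, ["G"], {"t": "tumor", "n": "normal"})
        fct = select_de_genes(m, "tumor", "normal", pseudocount=1.0)
        assert fct.table.loc["G", "status"] == "up"  # log2(5/1)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(1, 100, size=(20, 10))
        samples = [f"s{i}" for i in range(10)]
        groups = {s: ("a" if i < 5 else "b") for i, s in enumerate(samples)}
        m = ExpressionMatrix(pd.DataFrame(values, index=[f"G{i}" for i in range(20)], columns=samples), groups)
        fwd = select_de_genes(m, "a", "b").table["log2fc"]
        rev = select_de_genes(m, "b", "a").table["log2fc"]
        assert np.allclose(fwd, -rev)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(1, 100, size=(10, 6))
        samples = [f"s{i}" for i in range(6)]
        groups = {s: ("a" if i < 3 else "b") for i, s in enumerate(samples)}
        genes = [f"G{i}" for i in range(10)]
        m1 = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)
        m2 = ExpressionMatrix(pd.DataFrame(values * 37.5, index=genes, columns=samples), groups)
        assert np.allclose(
            select_de_genes(m1, "a", "b").table["log2fc"],
            select_de_genes(m2, "a", "b").table["log2fc"],
        )

    def test_noiseless_planted_study_recovered_exactly(self):
        planted = {f"UP{i}": 2.0 for i in range(10)} | {f"DN{i}": -2.0 for i in range(5)}
        m, _ = synthetic.simulate_expression_study(
            40, {"tumor": 4, "normal": 4}, planted, noise_sd=0.0, seed=3
        )
        fct = select_de_genes(m, "tumor", "normal")
        assert set(fct.up) == {g for g, v in planted.items() if v > 0}
        assert set(fct.down) == {g for g, v in planted.items() if v < 0}


class TestConsensus:
    def test_unanimous_up(self):
        tables = [{"SELENOS": "up"}] * 4
        assert consensus_direction(tables, 4)["SELENOS"] == "up"

    def test_opposition_is_discordant(self):
        tables = [{"G": "up"}] * 3 + [{"G": "down"}]
        assert consensus_direction(tables, 3)["G"] == "discordant"

    def test_single_table_passthrough(self):
        assert consensus_direction([{"G": "lower"}], 1)["G"] == "down"

    def test_below_quorum_is_insufficient(self):
        tables = [{"G": "up"}, {"G": "unchanged"}, {"G": "equal"}]
        assert consensus_direction(tables, 2)["G"] == "insufficient"

    def test_permutation_invariance(self):
        tables = [{"A": "up", "B": "down"}, {"A": "up"}, {"B": "down", "A": "equal"}]
        base = consensus_direction(tables, 2)
        assert consensus_direction(tables[::-1], 2) == base

    def test_min_agreement_cannot_exceed_tables(self):
        with pytest.raises(ParameterError):
            consensus_direction([{"G": "up"}], 2)


def make_cq(rows) -> CqTable:
    return CqTable(pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "cq"]), housekeeping="ACTB")


class TestDdcq:
    def test_closed_form_fold_change_eight(self):
        rows = [
            ("c1", "case", "G", 1, 25.0),
            ("c1", "case", "ACTB", 1, 20.0),
            ("r1", "ref", "G", 1, 28.0),
            ("r1", "ref", "ACTB", 1, 20.0),
        ]
        out = ddcq_fold_change(make_cq(rows), "case", "ref")
        assert out.loc["G", "ddcq"] == pytest.approx(-3.0)
        assert out.loc["G", "fold_change"] == pytest.approx(8.0)
        assert bool(out.loc["G", "significant"])

    def test_self_reference_gives_unit_fold_change(self):
        rows = [
            ("c1", "case", "G", 1, 25.0),
            ("c1", "case", "ACTB", 1, 20.0),
        ]
        out = ddcq_fold_change(make_cq(rows), "case", "case")
        assert out.loc["G", "fold_change"] == pytest.approx(1.0)
        assert not bool(out.loc["G", "significant"])

    def test_replicates_averaged_before_group_mean(self):
        rows = [
            ("c1", "case", "G", 1, 24.0),
            ("c1", "case", "G", 2, 26.0),
            ("c1", "case", "ACTB", 1, 20.0),
            ("r1", "ref", "G", 1, 28.0),
            ("r1", "ref", "ACTB", 1, 20.0),
        ]
        out = ddcq_fold_change(make_cq(rows), "case", "ref")
        assert out.loc["G", "delta_cq_case"] == pytest.approx(5.0)

    def test_missing_housekeeping_names_the_sample(self):
        rows = [
            ("c1", "case", "G", 1, 25.0),
            ("c1", "case", "ACTB", 1, 20.0),
            ("r1", "ref", "G", 1, 28.0),
        ]
        with pytest.raises(DataError, match="r1"):
            ddcq_fold_change(make_cq(rows), "case", "ref")

    def test_generator_closure_without_jitter(self):
        cq, _ = synthetic.simulate_cq_table(
            ["GPX1", "SELENOS"], ["tnbc", "normal"], {"GPX1": 3.0}, replicates=3, seed=2, jitter_sd=0.0
        )
        out = ddcq_fold_change(cq, "tnbc", "normal")
        assert out.loc["GPX1", "fold_change"] == pytest.approx(8.0)
        assert out.loc["SELENOS", "fold_change"] == pytest.approx(1.0)
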