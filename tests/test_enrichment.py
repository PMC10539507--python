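"""ssGSEA scores, regulon collapse, quantile normalization, signatures."""

import numpy as np
import pandas as pd
import pytest

import invasiotype as iv
from invasiotype.enrichment import RegulonCollection
from invasiotype.errors import (
    DegenerateSetError,
    EmptyResultError,
    MappingError,
    MissingSetError,
    ParameterError,
)


def brute_force_es(values: pd.Series, gene_set, tau: float) -> float:
    """Independent oracle: materialize both ECDFs position by position."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    n = len(order)
    members = set(gene_set) & set(values.index)
    s = len(members)
    weights = {g: (n - i) ** tau for i, g in enumerate(order)}  # rank magnitude n-i
    w_total = sum(weights[g] for g in members)
    es = 0.0
    p_hit = p_miss = 0.0
    for i, g in enumerate(order):
        if g in members:
            p_hit += weights[g] / w_total
        else:
            p_miss += 1.0 / (n - s)
        es += p_hit - p_miss
    return es


class TestSsgseaScore:
    def test_hand_worked_top_gene(self):
        values = {"A": 3.0, "B": 2.0, "C": 1.0}
        assert iv.ssgsea_score(values, ["A"], tau=0) == pytest.approx(1.5)

    def test_hand_worked_bottom_gene_symmetric(self):
        values = {"A": 3.0, "B": 2.0, "C": 1.0}
        assert iv.ssgsea_score(values, ["C"], tau=0) == pytest.approx(-1.5)

    def test_degenerate_set_is_rejected(self):
        with pytest.raises(DegenerateSetError):
            iv.ssgsea_score({"A": 3.0, "B": 2.0}, ["A", "B"], tau=0)

    def test_missing_set_is_rejected(self):
        with pytest.raises(MissingSetError):
            iv.ssgsea_score({"A": 3.0, "B": 2.0}, ["Z"], tau=0)

    def test_negative_tau_is_rejected(self):
        with pytest.raises(ParameterError):
            iv.ssgsea_score({"A": 3.0, "B": 2.0, "C": 1.0}, ["A"], tau=-1)

    @pytest.mark.parametrize("tau", [0.0, 0.25, 1.0])
    def test_matches_brute_force_oracle(self, tau, rng):
        for _ in range(60):
            n = int(rng.integers(3, 11))
            values = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            size = int(rng.integers(1, min(5, n - 1) + 1))
            gene_set = list(rng.choice(values.index, size=size, replace=False))
            es = iv.ssgsea_score(values, gene_set, tau=tau)
            assert es == pytest.approx(brute_force_es(values, gene_set, tau), abs=1e-12)

    def test_rank_invariance_at_tau_zero(self, rng):
        values = pd.Series(rng.normal(size=9), index=[f"g{i}" for i in range(9)])
        gene_set = ["g1", "g4", "g7"]
        base = iv.ssgsea_score(values, gene_set, tau=0)
        for transform in (np.exp, lambda v: v**3, lambda v: 10 + 2 * v):
            assert iv.ssgsea_score(transform(values), gene_set, tau=0) == pytest.approx(
                base, abs=1e-12
            )

    def test_deterministic_tie_break_by_gene_id(self):
        values = {"b": 1.0, "a": 1.0, "c": 0.0}
        # tie between a and b resolved by id order: a precedes b
        assert iv.ssgsea_score(values, ["a"], tau=0) > iv.ssgsea_score(
            values, ["b"], tau=0
        )


class TestEnrichmentMatrix:
    def test_shape_and_row_names(self, tiny_expr):
        regs = RegulonCollection(
            sets={"s1": ["g0", "g1"], "s2": ["g3", "g4"]},
            tf_of={"s1": "tfA", "s2": "tfB"},
        )
        scores = iv.enrichment_matrix(tiny_expr, regs, tau=0.25)
        assert scores.shape == (2, 4)
        assert list(scores.index) == ["s1", "s2"]
        assert list(scores.columns) == list(tiny_expr.columns)

    def test_matches_single_sample_scorer(self, tiny_expr):
        regs = RegulonCollection(sets={"s1": ["g0", "g2"]}, tf_of={"s1": "tfA"})
        scores = iv.enrichment_matrix(tiny_expr, regs, tau=0.25)
        for sample in tiny_expr.columns:
            assert scores.loc["s1", sample] == pytest.approx(
                iv.ssgsea_score(tiny_expr[sample], ["g0", "g2"], tau=0.25), abs=1e-12
            )

    def test_duplicated_sample_column_duplicates_scores(self, tiny_expr):
        regs = RegulonCollection(sets={"s1": ["g0", "g2"]}, tf_of={"s1": "tfA"})
        doubled = tiny_expr.copy()
        doubled["s_dup"] = tiny_expr["s0"]
        scores = iv.enrichment_matrix(doubled, regs)
        assert scores["s_dup"].to_numpy() == pytest.approx(scores["s0"].to_numpy())

    def test_gene_row_permutation_invariance(self, tiny_expr, rng):
        regs = RegulonCollection(sets={"s1": ["g0", "g2"]}, tf_of={"s1": "tfA"})
        base = iv.enrichment_matrix(tiny_expr, regs)
        shuffled = tiny_expr.sample(frac=1.0, random_state=3)
        again = iv.enrichment_matrix(shuffled, regs)
        assert np.allclose(base.to_numpy(), again.to_numpy())

    def test_unmatched_sets_dropped_then_empty_error(self, tiny_expr):
        regs = RegulonCollection(
            sets={"s1": ["g0"], "ghost": ["zz"]}, tf_of={"s1": "tfA", "ghost": "tfB"}
        )
        scores = iv.enrichment_matrix(tiny_expr, regs)
        assert list(scores.index) == ["s1"]
        ghost_only = RegulonCollection(sets={"ghost": ["zz"]}, tf_of={"ghost": "tfB"})
        with pytest.raises(EmptyResultError):
            iv.enrichment_matrix(tiny_expr, ghost_only)


class TestCollapseByTf:
    def test_mean_of_set_scores(self):
        scores = pd.DataFrame(
            {"s0": [0.2, 0.4, 0.6], "s1": [0.1, 0.2, 0.6]},
            index=["a1", "a2", "b1"],
        )
        tf_of = {"a1": "A", "a2": "A", "b1": "B"}
        out = iv.collapse_by_tf(scores, tf_of)
        assert out.loc["A", "s0"] == pytest.approx(0.3)
        assert out.loc["A", "s1"] == pytest.approx(0.15)
        assert out.loc["B", "s0"] == pytest.approx(0.6)  # single set unchanged

    def test_unmapped_set_raises(self):
        scores = pd.DataFrame({"s0": [0.2]}, index=["orphan"])
        with pytest.raises(MappingError):
            iv.collapse_by_tf(scores, {})

    def test_commutes_with_scaling(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(4, 3)),
            index=["a1", "a2", "b1", "b2"],
            columns=["s0", "s1", "s2"],
        )
        tf_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert np.allclose(
            iv.collapse_by_tf(3.5 * scores, tf_of).to_numpy(),
            3.5 * iv.collapse_by_tf(scores, tf_of).to_numpy(),
        )


class TestQuantileNormalize:
    def test_hand_worked_columns(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = iv.quantile_normalize(m)
        assert out["a"].tolist() == pytest.approx([2.5, 3.5, 4.5])
        assert out["b"].tolist() == pytest.approx([2.5, 3.5, 4.5])

    def test_identical_columns_keep_shared_distribution(self):
        col = [3.0, 1.0, 2.0]
        m = pd.DataFrame({"a": col, "b": col})
        out = iv.quantile_normalize(m)
        assert out["a"].tolist() == pytest.approx(col)

    def test_tied_ranks_get_mean_of_spanned_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [3.0, 4.0, 5.0]})
        out = iv.quantile_normalize(m)
        # reference = [2, 2.5, 3.5]; the tie spans ranks 1-2
        assert out["a"].tolist() == pytest.approx([2.25, 2.25, 3.5])
        assert out["b"].tolist() == pytest.approx([2.0, 2.5, 3.5])

    def test_contract_on_random_matrices(self, rng):
        for _ in range(25):
            m = pd.DataFrame(rng.normal(size=(12, 4)))
            out = iv.quantile_normalize(m)
            sorted_cols = np.sort(out.to_numpy(), axis=0)
            assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-12)
            assert np.ptp(out.to_numpy().mean(axis=0)) < 1e-12
            again = iv.quantile_normalize(out)
            assert np.allclose(again.to_numpy(), out.to_numpy(), atol=1e-12)

    def test_single_column_rejected(self):
        with pytest.raises(ParameterError):
            iv.quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSignatureScore:
    def test_top_expressed_signature_is_positive(self, tiny_expr):
        top = tiny_expr["s0"].nlargest(2).index.tolist()
        scores = iv.signature_score(tiny_expr, top, tau=0.25)
        assert scores["s0"] > 0

    def test_missing_signature_raises(self, tiny_expr):
        with pytest.raises(MissingSetError):
            iv.signature_score(tiny_expr, ["nope"])

    def test_identical_samples_identical_scores(self, tiny_expr):
        doubled = tiny_expr.copy()
        doubled["twin"] = tiny_expr["s1"]
        scores = iv.signature_score(doubled, ["g0", "g3"])
        assert scores["twin"] == pytest.approx(scores["s1"], abs=1e-12)


class TestGmtRoundTrip:
    def test_round_trip(self, tmp_path):
        regs = RegulonCollection(
            sets={"a1": ["g1", "g2"], "b1": ["g3"]}, tf_of={"a1": "A", "b1": "B"}
        )
        path = tmp_path / "sets.gmt"
        iv.write_gmt(regs, path)
        back = iv.read_gmt(path)
        assert back.sets == regs.sets
        assert back.tf_of == regs.tf_of
        assert back.tfs == ["A", "B"]
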