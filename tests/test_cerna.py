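"""Spearman filters and the hypergeometric shared-miRNA test."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from cernet.cerna import (
    assemble_triples,
    filter_lnc_mrna,
    filter_mirna_targets,
    hypergeometric_p,
    spearman,
)
from cernet.config import ThresholdConfig
from cernet.containers import ExpressionMatrix, TPM, FPKM
from cernet.errors import DegenerateInputError, MissingIdError, ParameterError

from oracles import hypergeom_upper_tail_by_enumeration, spearman_by_rank_pearson


def expr(rows: dict, unit=TPM, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    if samples is not None:
        df.columns = samples
    df.index.name = "gene_id"
    return ExpressionMatrix(df.astype(float), unit)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12]) == 1.0

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4, 5, 6], [12, 10, 8, 6, 4, 2]) == -1.0

    def test_ties_match_rank_pearson_oracle(self):
        x, y = [1, 2, 2, 3], [3, 1, 4, 2]
        assert spearman(x, y) == pytest.approx(spearman_by_rank_pearson(x, y), abs=1e-12)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            x = rng.integers(0, 8, size=n).astype(float)  # integer draws force ties
            y = rng.normal(size=n)
            if np.all(x == x[0]):
                continue
            assert spearman(x, y) == pytest.approx(
                spearman_by_rank_pearson(x, y), abs=1e-12
            )

    def test_symmetry_and_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert spearman(x, y) == pytest.approx(spearman(y, x), abs=1e-15)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y), abs=1e-12)
        assert spearman(x**3, y) == pytest.approx(spearman(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_short_or_ragged_input_rejected(self):
        with pytest.raises(ParameterError):
            spearman([1, 2], [3, 4])
        with pytest.raises(ParameterError):
            spearman([1, 2, 3], [1, 2, 3, 4])


class TestHypergeometricP:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_p(0, 4, 5, 10) == 1.0

    def test_enumerated_example(self):
        """U=10, M=4, N=5, n=2: brute-force enumeration of all 252 draws
        gives 186/252."""
        expected = hypergeom_upper_tail_by_enumeration(2, 4, 5, 10)
        assert expected == pytest.approx(186 / 252, abs=1e-15)
        assert hypergeometric_p(2, 4, 5, 10) == pytest.approx(expected, abs=1e-15)
        assert hypergeometric_p(2, 4, 5, 10) == pytest.approx(float(Fraction(186, 252)))

    def test_saturated_universe_is_certain(self):
        assert hypergeometric_p(6, 6, 6, 6) == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_monotone_nonincreasing_in_n(self, data):
        u = data.draw(st.integers(2, 40))
        m = data.draw(st.integers(1, u))
        nn = data.draw(st.integers(1, u))
        ps = [hypergeometric_p(i, m, nn, u) for i in range(min(m, nn) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_agrees_with_scipy_survival_function(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            u = int(rng.integers(2, 500))
            m = int(rng.integers(0, u + 1))
            nn = int(rng.integers(0, u + 1))
            n = int(rng.integers(0, min(m, nn) + 1))
            assert hypergeometric_p(n, m, nn, u) == pytest.approx(
                float(hypergeom.sf(n - 1, u, m, nn)), abs=1e-12
            )

    @pytest.mark.parametrize("args", [(1, 5, 3, 4), (1, 3, 5, 4), (4, 3, 5, 10), (-1, 2, 2, 4)])
    def test_invalid_counts_rejected(self, args):
        with pytest.raises(ParameterError):
            hypergeometric_p(*args)


class TestCorrelationFilters:
    def test_exact_negative_boundary_not_passed(self):
        """A pair at Spearman exactly -0.7 (rank pattern with sum d^2 = 34,
        n = 5) fails the strict < -0.7 gate."""
        mi = expr({"m1": [1, 2, 3, 4, 5]})
        tg = expr({"t1": [5, 3, 2, 4, 1]})
        pairs = pd.DataFrame({"mirna_id": ["m1"], "target_id": ["t1"]})
        rec = filter_mirna_targets(pairs, mi, tg)
        assert rec.loc[0, "scc"] == pytest.approx(-0.7, abs=1e-15)
        assert not rec.loc[0, "passed"]

    def test_below_negative_boundary_passed(self):
        mi = expr({"m1": [1, 2, 3, 4, 5, 6]})
        tg = expr({"t1": [6, 5, 4, 3, 2, 1]})
        pairs = pd.DataFrame({"mirna_id": ["m1"], "target_id": ["t1"]})
        assert filter_mirna_targets(pairs, mi, tg).loc[0, "passed"]

    def test_exact_positive_boundary_not_passed(self):
        """Spearman exactly 0.9 (one adjacent transposition, n = 5) fails
        the strict > 0.9 gate; identical vectors pass at 1."""
        lnc = expr({"l1": [1, 2, 3, 4, 5], "l2": [1, 2, 3, 4, 5]}, unit=FPKM)
        mr = expr({"g1": [2, 1, 3, 4, 5], "g2": [1, 2, 3, 4, 5]}, unit=FPKM)
        rec = filter_lnc_mrna(["l1", "l2"], ["g1", "g2"], lnc, mr)
        rec = rec.set_index(["lncrna_id", "mrna_id"])
        assert rec.loc[("l1", "g1"), "scc"] == pytest.approx(0.9, abs=1e-15)
        assert not rec.loc[("l1", "g1"), "passed"]
        assert rec.loc[("l1", "g2"), "scc"] == 1.0
        assert rec.loc[("l1", "g2"), "passed"]

    def test_missing_id_named(self):
        mi = expr({"m1": [1, 2, 3, 4]})
        tg = expr({"t1": [1, 2, 3, 4]})
        pairs = pd.DataFrame({"mirna_id": ["m2"], "target_id": ["t1"]})
        with pytest.raises(MissingIdError, match="m2"):
            filter_mirna_targets(pairs, mi, tg)


class TestAssembleTriples:
    def _records(self, rows, a="mirna_id", b="target_id"):
        return pd.DataFrame(rows, columns=[a, b, "scc", "n_samples", "passed"])

    def test_no_passing_pairs_gives_empty(self):
        empty = self._records([])
        out = assemble_triples(empty, empty, self._records([], a="lncrna_id", b="mrna_id"), 10)
        assert out.empty

    def test_shared_mirnas_expand_to_triples_with_common_p(self):
        """One lncRNA and one mRNA sharing two passing miRNAs yield two
        triples carrying the same pair-level p."""
        mi_lnc = self._records([("m1", "l1", -0.9, 6, True), ("m2", "l1", -0.8, 6, True)])
        mi_mrna = self._records([("m1", "g1", -0.95, 6, True), ("m2", "g1", -0.85, 6, True)])
        lnc_mrna = self._records([("l1", "g1", 0.99, 6, True)], a="lncrna_id", b="mrna_id")
        out = assemble_triples(mi_lnc, mi_mrna, lnc_mrna, universe_size=10)
        assert len(out) == 2
        assert out["p_hyper"].nunique() == 1
        assert set(out["mirna_id"]) == {"m1", "m2"}
        # n=M=N=2, U=10: p = P(overlap >= 2) with both sets of size 2
        assert out.loc[0, "p_hyper"] == pytest.approx(
            hypergeom_upper_tail_by_enumeration(2, 2, 2, 10), abs=1e-12
        )
        assert out["accepted"].all()

    def test_failed_correlations_do_not_count(self):
        mi_lnc = self._records([("m1", "l1", -0.9, 6, True), ("m2", "l1", -0.5, 6, False)])
        mi_mrna = self._records([("m1", "g1", -0.9, 6, True), ("m2", "g1", -0.9, 6, True)])
        lnc_mrna = self._records([("l1", "g1", 0.95, 6, True)], a="lncrna_id", b="mrna_id")
        out = assemble_triples(mi_lnc, mi_mrna, lnc_mrna, universe_size=20)
        assert set(out["mirna_id"]) == {"m1"}
        assert out.loc[0, ["n", "M", "N"]].tolist() == [1, 1, 2]

    def test_acceptance_boundary_is_strict(self):
        """A pair-level p of exactly 0.05 (n=M=N=1, U=20 gives p=1/20) is
        not accepted under the strict < 0.05 gate."""
        mi_lnc = self._records([("m1", "l1", -0.9, 6, True)])
        mi_mrna = self._records([("m1", "g1", -0.9, 6, True)])
        lnc_mrna = self._records([("l1", "g1", 0.95, 6, True)], a="lncrna_id", b="mrna_id")
        out = assemble_triples(mi_lnc, mi_mrna, lnc_mrna, universe_size=20)
        assert out.loc[0, "p_hyper"] == pytest.approx(0.05, abs=1e-15)
        assert not out.loc[0, "accepted"]
        out2 = assemble_triples(mi_lnc, mi_mrna, lnc_mrna, universe_size=21)
        assert out2.loc[0, "accepted"]
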