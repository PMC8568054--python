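"""Stress-response calling and Venn decomposition."""

import pandas as pd
import pytest

from conftest import brute_force_venn_cells

from ringsurvey.errors import ValidationError
from ringsurvey.io import ExpressionMatrix
from ringsurvey.simulate import VennSpec, generate_expression, paper_expression_spec
from ringsurvey.stress import (
    StressCall,
    call_matrix,
    call_responsive,
    log2_ratio,
    select_candidates,
    venn_decompose,
)


class TestLog2Ratio:
    def test_simple_doubling(self):
        assert log2_ratio(4, 2, 0) == 1.0

    @pytest.mark.parametrize("x, p", [(0.0, 0.1), (3.5, 0.1), (7, 2)])
    def test_identity_gives_zero(self, x, p):
        assert log2_ratio(x, x, p) == 0.0

    def test_antisymmetry(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 100, 2)
            p = rng.uniform(0.01, 1)
            assert log2_ratio(a, b, p) == pytest.approx(-log2_ratio(b, a, p))

    def test_zero_values_need_pseudocount(self):
        with pytest.raises(ValidationError):
            log2_ratio(0, 0, 0)
        with pytest.raises(ValidationError):
            log2_ratio(0, 5, 0)


def matrix_from_ratios(ratios, gene="g1", stress="cold"):
    """Expression matrix realizing the given log2 ratios exactly (control 8)."""
    rows = [
        {
            "gene": gene,
            "stress": stress,
            "timepoint": f"t{i}",
            "control": 8.0,
            "treatment": 8.0 * 2.0 ** r,
        }
        for i, r in enumerate(ratios)
    ]
    return ExpressionMatrix(pd.DataFrame(rows))


class TestCallResponsive:
    def test_any_timepoint_rule_up(self):
        call = call_responsive(matrix_from_ratios([0.2, 1.3, 0.5]), "g1", "cold", 1.0, 0.0)
        assert call.responsive
        assert call.direction == "up"
        assert call.max_abs_log2 == pytest.approx(1.3)

    def test_flat_gene_not_responsive(self):
        call = call_responsive(matrix_from_ratios([0.0, 0.0]), "g1", "cold", 1.0, 0.0)
        assert not call.responsive
        assert call.direction == "none"

    def test_threshold_boundary_is_inclusive(self):
        call = call_responsive(matrix_from_ratios([1.0]), "g1", "cold", 1.0, 0.0)
        assert call.responsive

    def test_mixed_direction(self):
        call = call_responsive(matrix_from_ratios([1.5, -2.0]), "g1", "cold", 1.0, 0.0)
        assert call.direction == "mixed"

    def test_down_direction(self):
        call = call_responsive(matrix_from_ratios([-1.5, 0.2]), "g1", "cold", 1.0, 0.0)
        assert call.direction == "down"

    def test_raising_threshold_never_adds_responsive_genes(self, rng):
        spec = VennSpec(n_genes=12, cells={("cold", "salt"): 4, ("MeJA",): 2}, seed=4)
        matrix, _ = generate_expression(spec)
        for lo, hi in [(0.5, 1.0), (1.0, 2.0)]:
            low = {
                (c.gene, c.stress)
                for c in call_matrix(matrix, threshold_log2=lo)
                if c.responsive
            }
            high = {
                (c.gene, c.stress)
                for c in call_matrix(matrix, threshold_log2=hi)
                if c.responsive
            }
            assert high <= low

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            call_responsive(matrix_from_ratios([1.0]), "nope", "cold")


def _calls_from_membership(membership, stresses, genes):
    calls = []
    for g in genes:
        for s in stresses:
            responsive = g in membership[s]
            calls.append(
                StressCall(g, s, (("t0", 2.0 if responsive else 0.0),),
                           responsive, "up" if responsive else "none",
                           2.0 if responsive else 0.0)
            )
    return calls


class TestVennDecompose:
    STRESSES = ("cold", "salt", "drought", "MeJA")

    def test_single_gene_responsive_to_all(self):
        membership = {s: {"g1"} for s in self.STRESSES}
        summary = venn_decompose(
            _calls_from_membership(membership, self.STRESSES, ["g1"])
        )
        assert summary.all_intersection_count == 1
        assert summary.single_stress_total == 0

    def test_cells_match_brute_force_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 65))
            genes = [f"g{i}" for i in range(n)]
            picks = rng.random((n, 4)) < 0.4
            membership = {
                s: {genes[i] for i in range(n) if picks[i, j]}
                for j, s in enumerate(self.STRESSES)
            }
            summary = venn_decompose(
                _calls_from_membership(membership, self.STRESSES, genes)
            )
            expected = brute_force_venn_cells(membership, self.STRESSES)
            assert {k: set(v) for k, v in summary.cells.items()} == expected

    def test_cell_conservation(self, rng):
        n = 40
        genes = [f"g{i}" for i in range(n)]
        picks = rng.random((n, 4)) < 0.5
        membership = {
            s: {genes[i] for i in range(n) if picks[i, j]}
            for j, s in enumerate(self.STRESSES)
        }
        summary = venn_decompose(
            _calls_from_membership(membership, self.STRESSES, genes)
        )
        union = set().union(*membership.values())
        assert summary.union_size == len(union)
        for s in self.STRESSES:
            assert summary.per_stress_counts[s] == len(membership[s])

    def test_gene_missing_from_one_stress_rejected(self):
        calls = [
            StressCall("g1", "cold", (("t0", 0.0),), False, "none", 0.0),
            StressCall("g1", "salt", (("t0", 0.0),), False, "none", 0.0),
            StressCall("g2", "cold", (("t0", 0.0),), False, "none", 0.0),
        ]
        with pytest.raises(ValidationError, match="identical coverage"):
            venn_decompose(calls, stresses=("cold", "salt"))


class TestPlantedVennRecovery:
    def test_preset_configuration_reproduced_exactly(self):
        matrix, truth = generate_expression(paper_expression_spec(seed=42))
        calls = call_matrix(matrix, threshold_log2=1.0)
        summary = venn_decompose(calls)
        assert summary.per_stress_counts == {
            "cold": 128, "salt": 134, "drought": 121, "MeJA": 82
        }
        assert summary.all_intersection_count == 53
        assert summary.exclusive_counts == {
            "cold": 5, "salt": 26, "drought": 0, "MeJA": 0
        }
        assert summary.single_stress_total == 31
        # per-gene membership equals the planted truth
        planted = {
            row.gene: row.cell if isinstance(row.cell, str) else ""
            for row in truth.itertuples()
        }
        for gene in matrix.genes:
            realized = next(
                ("+".join(sub) for sub, gs in summary.cells.items() if gene in gs),
                "",
            )
            assert realized == planted[gene]

    def test_select_candidates_modes(self):
        matrix, truth = generate_expression(paper_expression_spec(seed=42))
        calls = call_matrix(matrix, threshold_log2=1.0)
        summary = venn_decompose(calls)
        all_four = select_candidates(summary, "all_four")
        assert len(all_four) == 53
        planted_all_four = sorted(
            truth.loc[truth["cell"] == "cold+salt+drought+MeJA", "gene"]
        )
        assert all_four == planted_all_four
        assert select_candidates(summary, "exclusive:drought") == []
        assert select_candidates(summary, "exclusive:MeJA") == []
        assert len(select_candidates(summary, "exclusive:salt")) == 26
        assert len(select_candidates(summary, "union")) == summary.union_size

    def test_union_on_empty_summary(self):
        summary = venn_decompose([])
        assert select_candidates(summary, "union") == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError, match="unknown selection mode"):
            select_candidates(venn_decompose([]), "sideways")
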