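"""Synthetic-data generators: determinism, self-consistency, margin guards."""

import numpy as np
import pytest

from ringsurvey.errors import ValidationError
from ringsurvey.motif import scan_proteome
from ringsurvey.simulate import (
    CtSpec,
    PAPER_SUBTYPE_COUNTS,
    PAPER_VENN_CELLS,
    ProteomeSpec,
    VennSpec,
    generate_ct,
    generate_expression,
    generate_proteome,
    paper_expression_spec,
    paper_proteome_spec,
)
from ringsurvey.stress import log2_ratio
from ringsurvey.subtypes import classify_proteome


class TestProteomeGenerator:
    def test_single_motif_no_decoys_self_consistent(self):
        records, truth = generate_proteome(
            ProteomeSpec(subtype_counts={"RING-H2": 1}, seed=1)
        )
        assert len(records) == 1
        matches = scan_proteome(records)
        (m,) = matches[records[0].id]
        assert ",".join(map(str, m.positions)) == truth.iloc[0]["positions"]

    def test_same_seed_identical_output(self):
        spec = ProteomeSpec(
            subtype_counts={"RING-H2": 3, "RING-v": 1}, n_decoys=5, seed=17
        )
        r1, t1 = generate_proteome(spec)
        r2, t2 = generate_proteome(spec)
        assert r1 == r2
        assert t1.equals(t2)

    def test_different_seed_different_sequences(self):
        base = dict(subtype_counts={"RING-H2": 2}, n_decoys=0)
        r1, _ = generate_proteome(ProteomeSpec(**base, seed=1))
        r2, _ = generate_proteome(ProteomeSpec(**base, seed=2))
        assert [r.sequence for r in r1] != [r.sequence for r in r2]

    def test_confusion_matrix_is_diagonal_at_family_scale(self):
        """Scanner + classifier recover every planted subtype; decoys stay clean."""
        records, truth = generate_proteome(paper_proteome_spec(seed=42, n_decoys=100))
        matches = scan_proteome(records)
        decoys = set(truth.loc[truth["kind"] != "planted", "protein_id"])
        assert not decoys & set(matches)
        annotated, summary = classify_proteome(matches)
        assert summary.protein_counts == PAPER_SUBTYPE_COUNTS
        planted = truth[truth["kind"] == "planted"]
        for row in planted.itertuples():
            labels = [label for _, label in annotated[row.protein_id]]
            assert labels == [row.subtype]

    def test_realistic_background_still_clean(self):
        spec = ProteomeSpec(
            subtype_counts={"RING-H2": 3}, n_decoys=10, background="realistic", seed=3
        )
        records, truth = generate_proteome(spec)
        matches = scan_proteome(records)
        planted = set(truth.loc[truth["kind"] == "planted", "protein_id"])
        assert set(matches) == planted

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValidationError, match="not in signature table"):
            generate_proteome(ProteomeSpec(subtype_counts={"RING-Z9": 1}, seed=0))


class TestExpressionGenerator:
    def test_member_of_all_four_called_responsive_everywhere(self):
        spec = VennSpec(
            n_genes=1, cells={("cold", "salt", "drought", "MeJA"): 1}, seed=8
        )
        matrix, truth = generate_expression(spec)
        assert truth.iloc[0]["cell"] == "cold+salt+drought+MeJA"
        for stress in spec.stresses:
            cells = matrix.cell_values(truth.iloc[0]["gene"], stress)
            ratios = [
                log2_ratio(row.treatment, row.control) for row in cells.itertuples()
            ]
            assert any(abs(r) >= 1.0 for r in ratios)

    def test_zero_noise_ratios_equal_planted_effects(self):
        spec = VennSpec(n_genes=3, cells={("salt",): 1}, noise_sd=0.0, seed=5)
        matrix, truth = generate_expression(spec)
        member = truth.loc[truth["cell"] == "salt", "gene"].iloc[0]
        cells = matrix.cell_values(member, "salt")
        # zero pseudocount: ratio is exactly the planted effect
        ratios = [
            log2_ratio(row.treatment, row.control, 0) for row in cells.itertuples()
        ]
        strong = [r for r in ratios if abs(r) >= spec.member_low - 1e-6]
        assert len(strong) == 1
        weak = [r for r in ratios if abs(r) <= spec.nonmember_high + 1e-6]
        assert len(weak) == len(ratios) - 1

    def test_margin_smaller_than_4sd_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            VennSpec(n_genes=4, cells={("cold",): 1}, noise_sd=0.2, seed=0)

    def test_cells_exceeding_gene_count_rejected(self):
        with pytest.raises(ValidationError, match="plant"):
            VennSpec(n_genes=2, cells={("cold",): 3}, seed=0)

    def test_seed_determinism(self):
        spec = paper_expression_spec(seed=42)
        m1, t1 = generate_expression(spec)
        m2, t2 = generate_expression(spec)
        assert m1 == m2
        assert t1.equals(t2)

    def test_preset_cell_sizes_planted_exactly(self):
        _, truth = generate_expression(paper_expression_spec(seed=42))
        planted = truth["cell"].replace("", np.nan).dropna().value_counts().to_dict()
        expected = {"+".join(k): v for k, v in PAPER_VENN_CELLS.items()}
        assert planted == expected


class TestCtGenerator:
    def test_fold_one_zero_noise_gives_flat_ddct(self):
        spec = CtSpec(
            samples=(("a", 1.0), ("b", 1.0)), calibrator="a", noise_sd=0.0, seed=0
        )
        table, _ = generate_ct(spec)
        dct = table.frame.pivot_table(
            index=["sample", "replicate"], columns="gene", values="ct"
        )
        deltas = dct[spec.target_gene] - dct[spec.housekeeping]
        assert np.allclose(deltas, deltas.iloc[0])

    def test_seed_determinism(self):
        spec = CtSpec(samples=(("a", 1.0), ("b", 2.0)), calibrator="a", seed=33)
        t1, _ = generate_ct(spec)
        t2, _ = generate_ct(spec)
        assert t1 == t2

    def test_calibrator_fold_must_be_one(self):
        with pytest.raises(ValidationError, match="calibrator"):
            CtSpec(samples=(("a", 2.0), ("b", 1.0)), calibrator="a", seed=0)

    def test_replicate_count_layout(self):
        spec = CtSpec(
            samples=(("a", 1.0),), calibrator="a", n_biological=2, n_technical=3, seed=0
        )
        table, _ = generate_ct(spec)
        assert list(table.replicate_cts("a", spec.target_gene).index) == [1, 2, 3, 4, 5, 6]
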