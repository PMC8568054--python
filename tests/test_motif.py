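"""motif scanner: constructed examples, oracle equivalence, properties."""

import pytest

from conftest import brute_force_octets, random_achg_sequence

from ringsurvey.errors import ValidationError
from ringsurvey.io import DomainHit, ProteinRecord
from ringsurvey.motif import (
    DEFAULT_GRAMMAR,
    OctetGrammar,
    filter_by_hits,
    scan_octets,
    scan_proteome,
)
from ringsurvey.simulate import ProteomeSpec, generate_proteome


class TestScanOctets:
    def test_constructed_octet_found_exactly(self, octet_record):
        (match,) = scan_octets(octet_record)
        assert match.positions == (4, 7, 17, 19, 22, 25, 30, 33)
        assert match.residues == "CCCHHCCC"
        assert match.spacers == (2, 9, 1, 2, 2, 4, 2)
        # the enumerator agrees that this is the only octet
        assert brute_force_octets(octet_record.sequence, DEFAULT_GRAMMAR) == {
            match.positions
        }

    def test_no_ligand_residues_gives_empty(self):
        assert scan_octets(ProteinRecord("p", "", "A" * 80)) == []

    def test_sequence_too_short_gives_empty(self):
        assert scan_octets(ProteinRecord("p", "", "CC")) == []

    def test_ligand_positions_point_at_allowed_residues(self, octet_record):
        for m in scan_octets(octet_record):
            for pos, allowed in zip(m.positions, DEFAULT_GRAMMAR.residues):
                assert octet_record.sequence[pos - 1] in allowed

    def test_x_never_matches_a_ligand_position(self, octet_record):
        # replace ligand M1 (position 4, Cys) with X: the octet must vanish
        seq = octet_record.sequence
        mutated = seq[:3] + "X" + seq[4:]
        assert scan_octets(ProteinRecord("p", "", mutated)) == []


class TestOracleEquivalence:
    def test_raw_matches_equal_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            seq = random_achg_sequence(rng)
            record = ProteinRecord("r", "", seq)
            raw = {m.positions for m in scan_octets(record, resolve=False)}
            assert raw == brute_force_octets(seq, DEFAULT_GRAMMAR)

    def test_widening_a_spacer_never_removes_a_raw_match(self, rng):
        widened = OctetGrammar(
            residues=DEFAULT_GRAMMAR.residues,
            spacers=tuple(
                (max(0, lo - 1), hi + 2) for lo, hi in DEFAULT_GRAMMAR.spacers
            ),
        )
        for _ in range(60):
            seq = random_achg_sequence(rng, max_len=120)
            record = ProteinRecord("r", "", seq)
            narrow = {m.positions for m in scan_octets(record, resolve=False)}
            wide = {m.positions for m in scan_octets(record, widened, resolve=False)}
            assert narrow <= wide

    def test_determinism(self, rng):
        seq = random_achg_sequence(rng)
        record = ProteinRecord("r", "", seq)
        assert scan_octets(record) == scan_octets(record)


class TestScanProteome:
    def test_planted_motifs_recovered_no_decoy_matched(self):
        spec = ProteomeSpec(
            subtype_counts={"RING-H2": 5, "RING-HCa": 3, "RING-C2": 2},
            n_decoys=20,
            seed=9,
        )
        records, truth = generate_proteome(spec)
        matches = scan_proteome(records)
        planted = truth[truth["kind"] == "planted"]
        assert set(matches) == set(planted["protein_id"])
        for row in planted.itertuples():
            (m,) = matches[row.protein_id]
            assert ",".join(map(str, m.positions)) == row.positions

    def test_two_disjoint_octets_in_one_protein(self, octet_record):
        double = ProteinRecord(
            "d", "", octet_record.sequence + "GGGG" + octet_record.sequence
        )
        matches = scan_octets(double)
        assert len(matches) == 2
        assert matches[0].span[1] < matches[1].span[0]
        # both verified by the enumerator (raw set may be larger pre-resolution)
        raw = brute_force_octets(double.sequence, DEFAULT_GRAMMAR)
        assert {m.positions for m in matches} <= raw

    def test_empty_proteome(self):
        assert scan_proteome([]) == {}

    def test_duplicate_ids_rejected(self, octet_record):
        with pytest.raises(ValidationError, match="duplicate"):
            scan_proteome([octet_record, octet_record])


class TestFilterByHits:
    def _hit(self, pid, start, end):
        return DomainHit(pid, "RING-HMM", start, end, 1e-10, 50.0)

    def test_hit_spanning_motif_reproduces_full_scan(self, octet_record):
        full = scan_octets(octet_record)
        hits = [self._hit("p1", 4, 33)]
        restricted = scan_proteome([octet_record], hits=hits, flank=10)
        assert restricted["p1"] == full

    def test_hit_disjoint_from_motif_finds_nothing(self, octet_record):
        # window confined to the tail, far from the octet span
        hits = [self._hit("p1", 34, 35)]
        assert scan_proteome([octet_record], hits=hits, flank=0) == {}

    def test_empty_hit_list_skips_scanning(self, octet_record, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ringsurvey.motif"):
            assert scan_proteome([octet_record], hits=[], flank=10) == {}
        assert any("no domain hits" in r.message for r in caplog.records)

    def test_unknown_protein_hit_skipped_with_warning(self, octet_record, caplog):
        import logging

        hits = [self._hit("nope", 1, 10), self._hit("p1", 4, 33)]
        with caplog.at_level(logging.WARNING, logger="ringsurvey.motif"):
            windows = filter_by_hits([octet_record], hits, flank=5)
        assert [w.protein_id for w in windows] == ["p1"]
        assert any("unknown protein" in r.message for r in caplog.records)

    def test_overlapping_hits_merge_into_one_window(self, octet_record):
        hits = [self._hit("p1", 2, 12), self._hit("p1", 10, 30)]
        windows = filter_by_hits([octet_record], hits, flank=0)
        assert len(windows) == 1
        assert windows[0].sequence == octet_record.sequence[1:30]
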