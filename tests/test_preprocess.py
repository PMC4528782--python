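"""Universal-tag trimming and barcode extraction."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umiamp.panel import revcomp
from umiamp.preprocess import (SequencedRead, assign_and_extract,
                               extract_from_alignment, process_reads,
                               trim_universal)
from umiamp.simulate import SimConfig, simulate_library
from conftest import TAG_BC, make_panel, random_seq


def read_of(seq, q=30, rid="r1"):
    return SequencedRead(rid, seq, [q] * len(seq))


class TestTrimUniversal:
    def test_exact_tag_trimmed(self, small_panel):
        amp = small_panel.amplicons[0]
        payload = "ACGTACGTAC" + amp.bc_primer.sequence + amp.insert_sequence
        res = trim_universal(read_of(TAG_BC + payload), TAG_BC)
        assert res.trimmed5 and not res.untrimmed
        assert res.read.sequence == payload

    def test_one_mismatch_in_tag_still_trimmed(self):
        tag = "AATGTACAGTATTGCGTTTTGC"  # 22 nt; 1 error rate 0.045 < 0.1
        mutated = tag[:5] + ("A" if tag[5] != "A" else "C") + tag[6:]
        payload = "ACGTACGTACGTACGTACGT"
        res = trim_universal(read_of(mutated + payload), tag)
        assert res.trimmed5
        assert res.read.sequence == payload

    def test_missing_tag_flagged_untrimmed(self):
        res = trim_universal(read_of("ACGTACGTACGTACGTACGTACGT"), TAG_BC)
        assert res.untrimmed
        assert res.read.sequence == "ACGTACGTACGTACGTACGTACGT"

    def test_three_prime_readthrough_trimmed(self):
        payload = "ACGTACGTACGTACGTACGT"
        res = trim_universal(read_of(TAG_BC + payload + revcomp(TAG_BC)), TAG_BC)
        assert res.trimmed5 and res.trimmed3
        assert res.read.sequence == payload

    def test_empty_read_flagged(self):
        res = trim_universal(read_of(""), TAG_BC)
        assert res.untrimmed and len(res.read) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60), st.integers(0, 2**32 - 1))
    def test_kept_bases_are_contiguous_substring(self, payload, seed):
        rng = np.random.default_rng(seed)
        seq = TAG_BC + payload
        quals = list(rng.integers(2, 41, len(seq)))
        quals = [int(q) for q in quals]
        res = trim_universal(SequencedRead("r", seq, quals), TAG_BC)
        out = res.read
        n = len(out.sequence)
        assert any(
            seq[i : i + n] == out.sequence and quals[i : i + n] == out.qualities
            for i in range(len(seq) - n + 1)
        )


class TestAssignAndExtract:
    def test_exact_layout(self, small_panel):
        amp = small_panel.amplicons[0]
        umi = "ACGTACGTAC"
        t = assign_and_extract(
            read_of(umi + amp.bc_primer.sequence + amp.insert_sequence), small_panel
        )
        assert t is not None
        assert (t.amplicon_id, t.barcode, t.primer_offset) == (amp.amplicon_id, umi, 10)
        assert t.is_expected_length

    def test_short_barcode_routed_off_length(self, small_panel):
        amp = small_panel.amplicons[0]
        primer = amp.bc_primer.sequence
        mutated = ("T" if primer[3] != "T" else "G").join([primer[:3], primer[4:]])
        t = assign_and_extract(
            read_of("ACGTACGTA" + mutated + amp.insert_sequence), small_panel
        )
        assert t is not None
        assert len(t.barcode) == 9
        assert not t.is_expected_length

    def test_no_primer_hit_is_off_target(self, small_panel, rng):
        assert assign_and_extract(read_of(random_seq(rng, 60)), small_panel) is None

    def test_ambiguous_hit_is_off_target(self, small_panel):
        # a panel whose two amplicons share the same primer sequence
        from umiamp.panel import Amplicon, Panel, Primer

        primer = "ACGTTGCAACGTTGCAACGT"
        amps = [
            Amplicon(f"dup{i}", Primer(f"d{i}b", primer, "barcoded", TAG_BC),
                     Primer(f"d{i}n", "ACGTACGTACGTACGTACGT", "non_barcoded"), 10)
            for i in range(2)
        ]
        panel = Panel(amps, universal_tag_bc=TAG_BC)
        assert assign_and_extract(read_of("ACGTACGTAC" + primer + "ACGT" * 5), panel) is None

    def test_noise_free_simulation_recovers_every_barcode(self):
        panel = make_panel(n_amplicons=3, seed=11)
        cfg = SimConfig(panel=panel, molecules_per_amplicon=50,
                        mean_reads_per_molecule=3.0, amplification_dispersion=0.0,
                        pcr_error_rate=0.0, seq_error_rate=0.0, seed=5)
        sim = simulate_library(cfg)
        truth = {t.molecule_id: t for t in sim.truth}
        tagged, acct = process_reads(sim.reads1, panel)
        assert acct.tagged == acct.total and acct.off_target == 0
        for t in tagged:
            mol_id = t.read.read_id.rsplit(".r", 1)[0]
            rec = truth[mol_id]
            assert (t.amplicon_id, t.barcode) == (rec.amplicon_id, rec.true_barcode)

    def test_count_conservation(self):
        panel = make_panel(n_amplicons=2, seed=11)
        cfg = SimConfig(panel=panel, molecules_per_amplicon=60,
                        mean_reads_per_molecule=4.0, amplification_dispersion=0.5,
                        seq_error_rate=5e-3, seed=8)
        sim = simulate_library(cfg)
        rng = np.random.default_rng(2)
        junk = [read_of(random_seq(rng, 70), rid=f"junk{i}") for i in range(25)]
        _, acct = process_reads(sim.reads1 + junk, panel)
        assert acct.tagged + acct.off_length + acct.off_target + acct.untrimmed == acct.total
        assert acct.total == len(sim.reads1) + 25
        assert acct.untrimmed >= 25  # junk lacks the universal tag


class TestExtractFromAlignment:
    def _segment(self, header, seq, ref_id, soft_clip):
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.reference_id = ref_id
        a.reference_start = 0
        a.cigartuples = [(4, soft_clip), (0, len(seq) - soft_clip)]
        a.flag = 0
        return a

    def _header(self, panel):
        names = [a.amplicon_id for a in panel]
        lengths = [a.reference_interval.end for a in panel]
        return pysam.AlignmentHeader.from_references(names, lengths)

    def test_primer_start_at_base_ten(self):
        panel = make_panel(n_amplicons=2, with_intervals=True)
        amp = panel.amplicons[0]
        umi = "TTTTTGGGGG"
        seq = umi + amp.bc_primer.sequence + amp.insert_sequence
        aln = self._segment(self._header(panel), seq, 0, 10)
        t = extract_from_alignment(aln, panel)
        assert t is not None and t.barcode == umi and t.primer_offset == 10

    def test_outside_panel_is_off_target(self):
        panel = make_panel(n_amplicons=2, with_intervals=True)
        header = pysam.AlignmentHeader.from_references(["chrX"], [1000])
        aln = self._segment(header, "ACGT" * 20, 0, 10)
        assert extract_from_alignment(aln, panel) is None

    def test_unmapped_read_raises(self):
        panel = make_panel(n_amplicons=1, with_intervals=True)
        a = pysam.AlignedSegment(self._header(panel))
        a.query_name = "r"
        a.query_sequence = "ACGT" * 10
        a.flag = 4  # unmapped
        with pytest.raises(ValueError, match="assign_and_extract"):
            extract_from_alignment(a, panel)

    def test_agrees_with_sequence_extraction_on_simulated_reads(self):
        """Position-based and primer-search extraction give identical tags."""
        panel = make_panel(n_amplicons=3, with_intervals=True, seed=3)
        cfg = SimConfig(panel=panel, molecules_per_amplicon=34,
                        mean_reads_per_molecule=1.0, amplification_dispersion=0.0,
                        pcr_error_rate=0.0, seq_error_rate=0.0, seed=21,
                        deterministic=True)
        sim = simulate_library(cfg)
        header = self._header(panel)
        ref_index = {a.amplicon_id: i for i, a in enumerate(panel)}
        tagged_aln = []
        for r in sim.reads1[:100]:
            trimmed = r.sequence[len(TAG_BC):]
            amp_id = r.read_id.split(".")[0]
            aln = self._segment(header, trimmed, ref_index[amp_id], 10)
            tagged_aln.append(extract_from_alignment(aln, panel))
        for r, ta in zip(sim.reads1[:100], tagged_aln):
            trimmed = SequencedRead(r.read_id, r.sequence[len(TAG_BC):],
                                    r.qualities[len(TAG_BC):])
            ts = assign_and_extract(trimmed, panel)
            assert ta is not None and ts is not None
            assert (ta.amplicon_id, ta.barcode, ta.primer_offset) == (
                ts.amplicon_id, ts.barcode, ts.primer_offset)
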