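import numpy as np
import pytest

from spliceshift import (
    Genome,
    Intron,
    ScreenResult,
    SpliceEvent,
    ValidationError,
    build_pfm,
    classify_shift,
    intron_length_summary,
    overlap_counts,
    shift_histogram,
    splice_site_window,
)
from spliceshift.io_formats import reverse_complement


def _result(event_id="ev", mean_delta=0.3):
    return ScreenResult(
        event_id=event_id,
        deltas=[mean_delta] * 9,
        pair_sum=9,
        mean_delta=mean_delta,
        direction="up" if mean_delta > 0 else "down",
        passes=True,
    )


def _a_event(j_form1, j_form2, event_type="A5"):
    return SpliceEvent(
        event_id="ev",
        event_type=event_type,
        chrom=j_form1.chrom,
        strand=j_form1.strand,
        form1_junctions=frozenset([j_form1]),
        form2_junctions=frozenset([j_form2]),
    )


def slip_fixture(strand="+"):
    """Genome with a GTTAAG donor context: intron 101..160 (plus-strand coords)."""
    seq = list("A" * 220)
    if strand == "+":
        seq[100:106] = "GTTAAG"
        seq[158:160] = "AG"
        predominant = Intron("c", 101, 160, "+")
        promoted = Intron("c", 102, 160, "+")
    else:
        seq[154:160] = reverse_complement("GTTAAG")
        seq[100:102] = reverse_complement("AG")
        predominant = Intron("c", 101, 160, "-")
        promoted = Intron("c", 101, 159, "-")
    return Genome({"c": "".join(seq)}), predominant, promoted


class TestClassifyShift:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_slip_uu(self, strand):
        genome, predominant, promoted = slip_fixture(strand)
        event = _a_event(promoted, predominant)  # form1 = promoted cryptic form
        call = classify_shift(event, _result(), genome, control_psi=[0.05] * 3)
        assert call.shift_class == "SLIP_UU"
        assert call.offset_nt == 1
        assert call.promoted_start_dinucleotide == "TT"
        assert call.predominant_start_kmer.startswith("GTT")
        assert not call.in_frame

    def test_gu_shift_plus_two(self):
        seq = list("A" * 220)
        seq[100:106] = "GTGTAA"
        seq[158:160] = "AG"
        genome = Genome({"c": "".join(seq)})
        predominant = Intron("c", 101, 160, "+")
        promoted = Intron("c", 103, 160, "+")
        event = _a_event(promoted, predominant)
        call = classify_shift(event, _result(), genome, control_psi=[0.1] * 3)
        assert call.shift_class == "GU_SHIFT"
        assert call.offset_nt == 2

    def test_inframe_upstream_3p(self):
        seq = list("A" * 220)
        seq[100:102] = "GT"
        seq[152:154] = "AG"  # promoted acceptor at 154 (-6)
        seq[158:160] = "AG"  # predominant acceptor at 160
        genome = Genome({"c": "".join(seq)})
        predominant = Intron("c", 101, 160, "+")
        promoted = Intron("c", 101, 154, "+")
        event = _a_event(promoted, predominant, event_type="A3")
        call = classify_shift(event, _result(), genome, control_psi=[0.1] * 3)
        assert call.shift_class == "INFRAME_UPSTREAM_3P"
        assert call.offset_nt == -6
        assert call.in_frame

    def test_plus_one_without_gtt_context_is_other(self):
        seq = list("A" * 220)
        seq[100:106] = "GTCAAG"  # promoted +1 starts TC, not TT
        seq[158:160] = "AG"
        genome = Genome({"c": "".join(seq)})
        event = _a_event(Intron("c", 102, 160, "+"), Intron("c", 101, 160, "+"))
        call = classify_shift(event, _result(), genome, control_psi=[0.05] * 3)
        assert call.shift_class == "OTHER"

    def test_invariant_to_form_labelling(self):
        """Swapping form1/form2 (with PSI accordingly reflected) gives the same call."""
        genome, predominant, promoted = slip_fixture("+")
        ev_a = _a_event(promoted, predominant)
        call_a = classify_shift(ev_a, _result(mean_delta=0.3), genome, [0.05] * 3)
        ev_b = _a_event(predominant, promoted)  # form1 = predominant form
        call_b = classify_shift(ev_b, _result(mean_delta=-0.3), genome, [0.95] * 3)
        assert (call_a.offset_nt, call_a.shift_class) == (call_b.offset_nt, call_b.shift_class)

    def test_strand_undefined_rejected(self):
        genome, predominant, promoted = slip_fixture("+")
        bad = _a_event(
            Intron("c", 102, 160, "."), Intron("c", 101, 160, ".")
        )
        with pytest.raises(ValidationError):
            classify_shift(bad, _result(), genome, [0.05] * 3)

    def test_non_alt_event_rejected(self):
        genome, predominant, promoted = slip_fixture("+")
        ev = _a_event(promoted, predominant, event_type="A5")
        ev.event_type = "SE"
        with pytest.raises(ValidationError):
            classify_shift(ev, _result(), genome, [0.05] * 3)


class TestShiftHistogram:
    def test_counts(self):
        calls = []
        for offset in (1, 1, 2):
            genome, predominant, promoted = slip_fixture("+")
            from spliceshift import ShiftCall

            calls.append(
                ShiftCall("e", offset, "GTTA", "TT" if offset == 1 else "GT",
                          "SLIP_UU" if offset == 1 else "GU_SHIFT", False)
            )
        assert shift_histogram(calls) == {1: 2, 2: 1}

    def test_empty(self):
        assert shift_histogram([]) == {}

    def test_total_conserved(self, small_run):
        hist = shift_histogram(small_run.shift_calls)
        assert sum(hist.values()) == len(small_run.shift_calls)


class TestPfm:
    def _genome_with_donors(self, donor_seqs):
        """Each donor sequence becomes one intron 21..60 on its own chromosome."""
        genomes = {}
        introns = []
        for i, donor in enumerate(donor_seqs):
            seq = "C" * 20 + donor + "C" * (60 - 20 - len(donor)) + "C" * 20
            name = f"chr{i}"
            genomes[name] = seq
            introns.append(Intron(name, 21, 60, "+"))
        return Genome(genomes), introns

    def test_identical_sites_full_information(self):
        genome, introns = self._genome_with_donors(["GTAAGTAA"] * 5)
        pfm = build_pfm(introns, genome, side="donor", window=(0, 8))
        assert np.allclose(pfm.information_content().to_numpy(), 2.0)

    def test_uniform_column_zero_bits(self):
        genome, introns = self._genome_with_donors(["A", "C", "G", "T"])
        pfm = build_pfm(introns, genome, side="donor", window=(0, 1))
        assert pfm.information_content().iloc[0] == pytest.approx(0.0)

    def test_half_half_column_one_bit(self):
        genome, introns = self._genome_with_donors(["A", "A", "C", "C"])
        pfm = build_pfm(introns, genome, side="donor", window=(0, 1))
        assert pfm.information_content().iloc[0] == pytest.approx(1.0)

    def test_information_bounds_and_counts(self, toy_reference):
        constitutive = toy_reference.constitutive_introns()[:200]
        pfm = build_pfm(constitutive, toy_reference.genome, side="donor")
        ic = pfm.information_content()
        assert ((ic >= 0) & (ic <= 2.0 + 1e-12)).all()
        assert pfm.counts.sum(axis=1).nunique() == 1  # equal column totals
        # the first two intronic positions are the written GT dinucleotide
        freqs = pfm.frequencies()
        assert freqs.loc["I1", "G"] == pytest.approx(1.0)
        assert freqs.loc["I2", "T"] == pytest.approx(1.0)

    def test_window_off_chromosome_excluded(self):
        genome = Genome({"c": "GTAAGTACAG" * 3})
        ok = Intron("c", 11, 26, "+")
        off_end = Intron("c", 5, 29, "+")  # acceptor window would run past the end
        pfm = build_pfm([ok, off_end], genome, side="acceptor", window=(3, 5))
        assert pfm.n_sites == 1

    def test_acceptor_window_orientation(self):
        genome = Genome({"c": "C" * 20 + "GTAAA" + "T" * 10 + "TCAG" + "GGG" + "C" * 20})
        intron = Intron("c", 21, 39, "+")
        window = splice_site_window(genome, intron, "acceptor", n_exonic=3, n_intronic=4)
        assert window == "TCAG" + "GGG"


class TestLengthSummary:
    def test_singleton(self):
        df = intron_length_summary({"g": [47]})
        assert df.loc[0, "median"] == 47

    def test_even_interpolation(self):
        df = intron_length_summary({"g": [40, 50, 60, 500]})
        assert df.loc[0, "median"] == pytest.approx(55.0)

    def test_accepts_introns_and_omits_empty(self):
        introns = [Intron("c", 1, 47, "+"), Intron("c", 1, 51, "+")]
        df = intron_length_summary({"short": introns, "empty": []})
        assert list(df["group"]) == ["short"]
        assert df.loc[0, "median"] == pytest.approx(49.0)

    def test_mixture_medians_recovered(self):
        """Sampled medians of the two length modes land near their targets."""
        from spliceshift import SimulationConfig
        from spliceshift.synthetic_data import _intron_length

        rng = np.random.default_rng(17)
        cfg = SimulationConfig(seed=0, short_weight=1.0)
        short = [_intron_length(rng, cfg, minimum=4) for _ in range(2000)]
        cfg_long = SimulationConfig(seed=0, short_weight=0.0)
        long = [_intron_length(rng, cfg_long, minimum=4) for _ in range(2000)]
        assert abs(np.median(short) - 47) <= 2
        assert abs(np.median(long) - 500) <= 30


class TestOverlapCounts:
    def test_two_set_example(self):
        out = overlap_counts({"a", "b", "c"}, {"b", "c", "d"})
        assert (out["only_A"], out["A_and_B"], out["only_B"]) == (1, 2, 1)
        assert out["overlap_fraction"] == pytest.approx(2 / 3)

    def test_identical_sets(self):
        out = overlap_counts({"x", "y"}, {"x", "y"})
        assert out["overlap_fraction"] == 1.0

    def test_three_set_matches_brute_force(self):
        rng = np.random.default_rng(3)
        universe = [f"e{i}" for i in range(40)]
        a = {e for e in universe if rng.random() < 0.5}
        b = {e for e in universe if rng.random() < 0.5}
        c = {e for e in universe if rng.random() < 0.5}
        out = overlap_counts(a, b, c)
        regions = {k: 0 for k in out if k != "overlap_fraction"}
        for e in universe:
            ina, inb, inc = e in a, e in b, e in c
            if not (ina or inb or inc):
                continue
            name = (
                "A_and_B_and_C" if ina and inb and inc
                else "A_and_B" if ina and inb
                else "A_and_C" if ina and inc
                else "B_and_C" if inb and inc
                else "only_A" if ina
                else "only_B" if inb
                else "only_C"
            )
            regions[name] += 1
        for k, v in regions.items():
            assert out[k] == v
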