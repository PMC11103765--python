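"""Primer thermodynamics, screening cascade, and mix formulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtpanel.primer_screen import (
    PrimerSet,
    ScreenConfig,
    conversion_rate,
    find_internal_binding,
    formulate_primer_mix,
    hairpin_tm,
    heterodimer_tm,
    panel_ledger,
    screen_panel,
)
from gtpanel.thermo import melting_temperature, revcomp, stem_tm

dna = st.text(alphabet="ACGT", min_size=18, max_size=24)


class TestMeltingTemperature:
    def test_against_independent_nearest_neighbor_calculator(self):
        # oracle: Biopython's unified-parameter NN model, same salt/conc
        from Bio.SeqUtils import MeltingTemp as mt

        seq = "ACGTTGCAACGTTGCAACGT"
        expected = mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=250, saltcorr=5)
        assert melting_temperature(seq) == pytest.approx(expected, abs=0.5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(revcomp(seq)), abs=1e-9
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(dna)
    def test_matches_library_oracle_for_random_primers(self, seq):
        from Bio.SeqUtils import MeltingTemp as mt

        expected = mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=250, saltcorr=5)
        assert melting_temperature(seq) == pytest.approx(expected, abs=0.5)

    def test_gc_raises_tm(self):
        assert melting_temperature("AT" * 9) < melting_temperature("GC" * 9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")  # < 8 bases
        with pytest.raises(ValueError):
            melting_temperature("ACGTACGNACGTACGT")


class TestHairpin:
    def test_constructed_stem_detected(self):
        stem = "ACGTACGT"
        seq = stem + "T" * 10 + revcomp(stem)
        assert hairpin_tm(seq) is not None

    def test_poly_a_has_no_hairpin(self):
        assert hairpin_tm("A" * 18) is None

    def test_gc_stem_beats_short_at_stem(self):
        gc_stem = "GCGCGCGCGCGC"  # 12 bp GC
        at_stem = "ATATATAT"  # 8 bp AT
        hp_gc = hairpin_tm(gc_stem + "TTTT" + revcomp(gc_stem))
        hp_at = hairpin_tm(at_stem + "TTTT" + revcomp(at_stem))
        # same NN oracle applied to the stems directly
        assert hp_gc > hp_at
        assert hp_gc == pytest.approx(stem_tm(gc_stem), abs=1e-9)

    def test_min_loop_respected(self):
        seq = "GGGG" + "T" + "CCCC"  # 4 bp stem, 1-base loop
        assert hairpin_tm(seq, min_loop=3) is None
        assert hairpin_tm(seq, min_loop=1) is not None


class TestHeterodimer:
    def test_full_reverse_complement_equals_duplex_tm(self):
        a = "ACGTTGCAACGTTGCAACGT"
        assert heterodimer_tm(a, revcomp(a)) == pytest.approx(
            melting_temperature(a), abs=1e-9
        )

    def test_poly_a_pair_has_no_dimer(self):
        assert heterodimer_tm("A" * 20, "A" * 20) is None

    def test_partial_overlap_matches_bruteforce_window_oracle(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        core = "GCATTGCAGC"  # 10 bp shared complementary window
        a = "".join(rng.choice(bases, 5)) + core + "".join(rng.choice(bases, 5))
        b = "".join(rng.choice(bases, 6)) + revcomp(core) + "".join(rng.choice(bases, 4))

        # oracle: enumerate all antiparallel offsets with plain loops
        comp = dict(zip("ACGT", "TGCA"))
        best = None
        for const in range(len(a) + len(b) - 1):
            run = ""
            for i in range(len(a)):
                j = const - i
                if 0 <= j < len(b) and comp[a[i]] == b[j]:
                    run += a[i]
                else:
                    if len(run) >= 4:
                        tm = stem_tm(run)
                        best = tm if best is None else max(best, tm)
                    run = ""
            if len(run) >= 4:
                tm = stem_tm(run)
                best = tm if best is None else max(best, tm)
        assert heterodimer_tm(a, b) == pytest.approx(best, abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        ta, tb = heterodimer_tm(a, b), heterodimer_tm(b, a)
        if ta is None:
            assert tb is None
        else:
            assert ta == pytest.approx(tb, abs=1e-6)


class TestInternalBinding:
    def test_verbatim_seed_in_foreign_amplicon(self):
        primer = "ACGTTGCAACGTTGCAACGT"
        seed = primer[-15:]
        amplicons = {"ampX": "T" * 10 + seed + "G" * 10}
        hits = find_internal_binding(primer, amplicons)
        assert hits == [("ampX", 10, "+")]

    def test_absent_seed_no_hits(self):
        assert find_internal_binding("ACGTTGCAACGTTGCAACGT", {"a": "T" * 60}) == []

    def test_reverse_strand_hit(self):
        primer = "ACGTTGCAACGTTGCAACGT"
        rc_seed = revcomp(primer[-15:])
        amplicons = {"a": "G" * 7 + rc_seed + "C" * 8}
        assert find_internal_binding(primer, amplicons) == [("a", 7, "-")]

    def test_own_site_excluded(self):
        primer = "ATCGGATTACAGCTGTACGT"
        amp = primer + "T" * 40
        assert find_internal_binding(primer, {"self": amp}, own_site=("self", 5, "+")) == []


def _passing_primer(rng, existing, cfg):
    """Search for a primer that passes every rule against `existing`."""
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(rng.choice(bases, 20))
        if not 58 <= melting_temperature(seq) <= 63:
            continue
        hp = hairpin_tm(seq)
        if hp is not None and hp > cfg.hairpin_tm_max:
            continue
        if any(
            (heterodimer_tm(seq, o) or -999) >= cfg.heterodimer_tm_max for o in existing
        ):
            continue
        return seq


@pytest.fixture(scope="module")
def screened_panel():
    cfg = ScreenConfig()
    rng = np.random.default_rng(20240501)
    seqs: list[str] = []
    for _ in range(16):  # fwd+rev for 8 clean loci (7 passing + 1 dimer locus replaced)
        seqs.append(_passing_primer(rng, seqs, cfg))
    primers = [
        PrimerSet(f"loc{i + 1}", seqs[2 * i], seqs[2 * i + 1]) for i in range(7)
    ]
    # LENGTH failure: 16-mer forward primer
    primers.append(PrimerSet("len_fail", seqs[14][:16], seqs[15]))
    # HAIRPIN failure: strong 10 bp GC stem (stem Tm ~55 degC > 50)
    hp_seq = "GCGCGCGCGC" + "TTT" + revcomp("GCGCGCGCGC")
    primers.append(PrimerSet("hairpin_fail", hp_seq, _passing_primer(rng, seqs, cfg)))
    # HETERODIMER failure: fwd and rev are exact complements of each other
    d = _passing_primer(rng, seqs, cfg)
    primers.append(PrimerSet("dimer_fail", d, revcomp(d)))
    amplicons = {
        p.locus_id: p.fwd + "".join(rng.choice(np.array(list("ACGT")), 40)) + revcomp(p.rev)
        for p in primers
    }
    return primers, amplicons, cfg


class TestScreenPanel:
    def test_constructed_failures_get_expected_codes(self, screened_panel):
        primers, amplicons, cfg = screened_panel
        report = screen_panel(primers, amplicons, cfg)
        fails = dict(zip(report.results["locus_id"], report.results["failures"]))
        assert "LENGTH" in fails["len_fail"]
        assert "HAIRPIN" in fails["hairpin_fail"]
        assert "HETERODIMER" in fails["dimer_fail"]
        assert set(report.retained) == {f"loc{i + 1}" for i in range(7)}

    def test_conservation(self, screened_panel):
        primers, amplicons, cfg = screened_panel
        report = screen_panel(primers, amplicons, cfg)
        s = report.summary()
        assert s["retained"] + s["removed"] == s["candidates"] == len(primers)
        assert set(report.retained) | set(report.removed) == {p.locus_id for p in primers}

    def test_all_passing_panel_removes_nothing(self, screened_panel):
        primers, amplicons, cfg = screened_panel
        clean = [p for p in primers if p.locus_id.startswith("loc")]
        amps = {p.locus_id: amplicons[p.locus_id] for p in clean}
        report = screen_panel(clean, amps, cfg)
        assert report.removed == []

    def test_internal_site_failure(self, screened_panel):
        primers, amplicons, cfg = screened_panel
        clean = [p for p in primers if p.locus_id.startswith("loc")]
        amps = {p.locus_id: amplicons[p.locus_id] for p in clean}
        # embed loc1's forward seed inside loc2's amplicon
        amps["loc2"] = amps["loc2"][:25] + clean[0].fwd[-15:] + amps["loc2"][25:]
        report = screen_panel(clean, amps, cfg)
        fails = dict(zip(report.results["locus_id"], report.results["failures"]))
        assert "INTERNAL_SITE" in fails["loc1"]

    def test_duplicate_locus_rejected(self, screened_panel):
        primers, amplicons, cfg = screened_panel
        with pytest.raises(ValueError, match="duplicate"):
            screen_panel([primers[0], primers[0]], amplicons, cfg)

    def test_raising_hairpin_bound_is_monotone(self, screened_panel):
        primers, amplicons, _ = screened_panel
        counts = []
        for bound in (20.0, 50.0, 90.0):
            cfg = ScreenConfig(hairpin_tm_max=bound)
            report = screen_panel(primers, amplicons, cfg)
            counts.append(report.results["failures"].map(lambda f: "HAIRPIN" in f).sum())
        assert counts[0] >= counts[1] >= counts[2]


class TestPrimerMix:
    def test_eight_distinct_shares(self):
        perf = {f"l{i}": float(i) for i in range(8)}
        conc = formulate_primer_mix(perf)
        vals = sorted(conc.values())
        assert vals == [80.0, 80.0, 160.0, 160.0, 160.0, 160.0, 320.0, 320.0]
        assert conc["l7"] == 80.0 and conc["l0"] == 320.0

    def test_four_distinct_shares(self):
        conc = formulate_primer_mix({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        assert conc == {"a": 80.0, "b": 160.0, "c": 160.0, "d": 320.0}

    def test_all_tied_stays_uniform(self):
        conc = formulate_primer_mix({f"l{i}": 0.5 for i in range(8)})
        assert set(conc.values()) == {160.0}

    def test_fewer_than_four_warns_and_defaults(self):
        with pytest.warns(UserWarning):
            conc = formulate_primer_mix({"a": 1.0, "b": 2.0})
        assert set(conc.values()) == {160.0}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=4, max_size=20))
    def test_quartile_counts_bounded(self, shares):
        perf = {f"l{i:02d}": s for i, s in enumerate(shares)}
        conc = formulate_primer_mix(perf)
        n = len(shares)
        assert set(conc.values()) <= {80.0, 160.0, 320.0}
        assert sum(v == 80.0 for v in conc.values()) <= -(-n // 4)
        assert sum(v == 320.0 for v in conc.values()) <= -(-n // 4)


class TestPanelBookkeeping:
    def test_ledger_conservation(self):
        ledger = panel_ledger({"neutral": 10, "adaptive": 5}, [{"neutral": 3, "adaptive": 1}])
        assert ledger.loc["final_panel", "total"] == 11
        assert ledger.loc["round1_candidates", "total"] == 15

    def test_over_removal_rejected(self):
        with pytest.raises(ValueError):
            panel_ledger({"neutral": 2}, [{"neutral": 5}])

    def test_conversion_rate(self):
        assert conversion_rate(100, 25) == pytest.approx(75.0)
        with pytest.raises(ValueError):
            conversion_rate(0, 0)
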