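"""Oligo model: Tm, GC, hybridization-site search, in-silico PCR, design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdnafinish.iupac import IUPAC_SETS, revcomp
from rdnafinish.primers import (
    Primer,
    PrimerConstraints,
    Undesignable,
    UniquenessScope,
    design_primer,
    find_primer_sites,
    gc_content,
    melting_temp,
    purity_check,
    simulate_pcr,
    wallace_tm,
)

U1 = "TGGGATACCACCCTGATCGT"
EIGHT_F = "AGAGTTTGATCCTGGCTCAG"


def _random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


class TestMeltingTemp:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temp("GC" * 10) > melting_temp("AT" * 10)

    def test_operon_walk_primer_close_to_wallace_rule(self):
        # 2(A+T)+4(G+C) = 62 C for this 20-mer; NN must land within 8 C
        assert wallace_tm(U1) == 62.0
        assert abs(melting_temp(U1) - 62.0) <= 8.0

    def test_reverse_complement_same_duplex(self):
        seq = "ATGCCGTTAGGCATCGATCC"
        assert melting_temp(seq) == pytest.approx(melting_temp(revcomp(seq)), abs=1e-6)

    def test_degenerate_primer_uses_minimum_expansion(self):
        # the degenerate Tm can never exceed any concrete disambiguation
        degen = "CYGAATGGGRVAACCGGCCA"
        concrete = degen.replace("Y", "C").replace("R", "G").replace("V", "G")
        assert melting_temp(degen) <= melting_temp(concrete) + 1e-9

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACGT")  # too short
        with pytest.raises(ValueError):
            melting_temp("ACGTACGTAZ")


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 100.0), (EIGHT_F, 50.0), ("AT", 0.0), ("RRRR", 50.0), ("SSSS", 100.0)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


def _brute_sites(template, primer, max_mm=2, run3=3):
    """Independent sliding-window site search with explicit IUPAC sets."""
    out = set()
    L = len(primer)
    for strand in "+-":
        p = primer if strand == "+" else revcomp(primer)
        for i in range(len(template) - L + 1):
            mm = 0
            tail_ok = True
            for j in range(L):
                tc, pc = template[i + j], p[j]
                good = tc != "N" and IUPAC_SETS[tc] <= IUPAC_SETS[pc]
                if not good:
                    mm += 1
                    at_3prime = (j >= L - run3) if strand == "+" else (j < run3)
                    if at_3prime:
                        tail_ok = False
            if mm <= max_mm and tail_ok:
                out.add((i, i + L, strand, mm))
    return out


class TestFindPrimerSites:
    def test_exact_site(self):
        template = "T" * 50 + EIGHT_F + "T" * 50
        sites = find_primer_sites(template, Primer("8F", EIGHT_F))
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1 and plus[0].start == 50 and plus[0].mismatches == 0

    def test_degenerate_iupac_expansion(self):
        sites = find_primer_sites("CTGAATGGGAGAACC", Primer("127F", "CYGAATGGGRVAACC"))
        assert any(s.mismatches == 0 and s.strand == "+" for s in sites)

    def test_three_scattered_mismatches_rejected(self):
        primer = "ACGTACGTACGTACGTACGT"
        template = "T" * 30 + "AGGTACCTACGTACGAACGT" + "T" * 30  # 3 mismatches
        assert find_primer_sites(template, Primer("p", primer)) == []

    def test_template_n_never_matches(self):
        template = "T" * 30 + EIGHT_F.replace("G", "N", 3) + "T" * 30
        sites = find_primer_sites(template, Primer("8F", EIGHT_F))
        assert all(s.mismatches > 0 or s.start != 30 for s in sites)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for i in range(300):
            template = _random_dna(rng, int(rng.integers(40, 160)), "ACGT" + "N" * (i % 2))
            plen = int(rng.integers(10, 16))
            alphabet = "ACGT" if i % 3 else "ACGTRYSW"
            primer = _random_dna(rng, plen, alphabet)
            got = {
                (s.start, s.end, s.strand, s.mismatches)
                for s in find_primer_sites(template, Primer("p", primer))
            }
            assert got == _brute_sites(template, primer), (template, primer)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_reverse_complement_template_mirrors_sites(self, data):
        template = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=80))
        primer = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=14))
        fwd = {
            (s.start, s.end, s.strand)
            for s in find_primer_sites(template, Primer("p", primer))
        }
        n = len(template)
        mirrored = {
            (n - e, n - s, "+" if strand == "-" else "-")
            for s, e, strand in fwd
        }
        rev = {
            (s.start, s.end, s.strand)
            for s in find_primer_sites(revcomp(template), Primer("p", primer))
        }
        assert rev == mirrored


class TestSimulatePcr:
    def _template(self):
        rng = np.random.default_rng(4)
        fwd = "ATGCCGTTAGGCATCGATCC"
        rev = "GGATTACCGGATGCATCGAA"
        t = _random_dna(rng, 100) + fwd + _random_dna(rng, 760) + revcomp(rev) + _random_dna(rng, 100)
        return t, fwd, rev

    def test_product_arithmetic(self):
        t, fwd, rev = self._template()
        (amp,) = simulate_pcr(t, Primer("f", fwd), Primer("r", rev))
        assert (amp.start, amp.end, amp.length) == (100, 900, 800)
        assert amp.seq == t[100:900]

    def test_convergence_required(self):
        rng = np.random.default_rng(5)
        fwd = "ATGCCGTTAGGCATCGATCC"
        rev = "GGATTACCGGATGCATCGAA"
        t = _random_dna(rng, 100) + fwd + _random_dna(rng, 300) + rev + _random_dna(rng, 100)
        assert simulate_pcr(t, Primer("f", fwd), Primer("r", rev)) == []

    def test_multiple_forward_sites_give_multiple_products(self):
        rng = np.random.default_rng(6)
        fwd = "ATGCCGTTAGGCATCGATCC"
        rev = "GGATTACCGGATGCATCGAA"
        t = fwd + _random_dna(rng, 200) + fwd + _random_dna(rng, 200) + revcomp(rev)
        assert len(simulate_pcr(t, Primer("f", fwd), Primer("r", rev))) == 2

    def test_primer_order_irrelevant(self):
        t, fwd, rev = self._template()
        a = simulate_pcr(t, Primer("f", fwd), Primer("r", rev))
        b = simulate_pcr(t, Primer("r", rev), Primer("f", fwd))
        assert [(x.start, x.end) for x in a] == [(x.start, x.end) for x in b]

    def test_max_product_cap(self):
        t, fwd, rev = self._template()
        assert simulate_pcr(t, Primer("f", fwd), Primer("r", rev), max_product=500) == []


class TestDesignPrimer:
    def test_deterministic_and_self_consistent(self):
        rng = np.random.default_rng(7)
        template = _random_dna(rng, 1000)
        c = PrimerConstraints()
        a = design_primer(template, (0, 400), "+", c, name="p")
        b = design_primer(template, (0, 400), "+", c, name="p")
        assert not isinstance(a, Undesignable)
        assert a.seq == b.seq
        assert c.min_len <= len(a.seq) <= c.max_len
        assert c.gc_range[0] <= gc_content(a.seq) <= c.gc_range[1]
        assert c.tm_range[0] <= melting_temp(a.seq) <= c.tm_range[1]

    def test_poly_a_window_undesignable(self):
        res = design_primer("A" * 200, (0, 200), "+")
        assert isinstance(res, Undesignable)
        assert res.failures["gc"] > 0

    def test_duplicated_window_fails_uniqueness(self):
        rng = np.random.default_rng(8)
        block = _random_dna(rng, 120)
        template = block + _random_dna(rng, 200) + block
        scope = UniquenessScope([template])
        res = design_primer(template, (0, 120), "+", scope=scope, name="p")
        assert isinstance(res, Undesignable)
        assert res.failures["uniqueness"] > 0

    def test_minus_direction_reads_leftward(self):
        rng = np.random.default_rng(9)
        template = _random_dna(rng, 500)
        p = design_primer(template, (300, 500), "-", name="p")
        assert not isinstance(p, Undesignable)
        assert revcomp(p.seq) in template[300:500]


class TestPurityCheck:
    def test_clean_template_passes(self):
        rng = np.random.default_rng(10)
        genome = _random_dna(rng, 2000)
        pair = (Primer("df", genome[500:520]), Primer("dr", revcomp(genome[900:920])))
        assert purity_check(_random_dna(rng, 800), [pair])["pass"]

    def test_contaminated_template_fails(self):
        rng = np.random.default_rng(11)
        genome = _random_dna(rng, 2000)
        pair = (Primer("df", genome[500:520]), Primer("dr", revcomp(genome[900:920])))
        rep = purity_check(genome, [pair])
        assert not rep["pass"] and rep["offending_pairs"]

    def test_empty_template_vacuously_passes(self):
        assert purity_check("", [(Primer("a", "ACGTACGTACGTACGTACGT"),
                                  Primer("b", "TGCATGCATGCATGCATGCA"))])["pass"]
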