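"""Inheritance-state classification, read-based re-genotyping, retention."""

import itertools
import math

import pytest

from triomut.inheritance import (
    Origin,
    ReadGenotypeConfig,
    State,
    apply_support_filters,
    classify_by_genotype,
    genotype_from_reads,
    reconcile_trio,
    run_trio_classification,
)
from triomut.site_filter import FilterConfig, filter_pipeline

from conftest import make_record

CFG = ReadGenotypeConfig()


def oracle_classify(gm, gf, gc):
    """Independent oracle: exhaustive enumeration of the four possible
    one-allele-from-each-parent transmissions."""
    if gm is None or gf is None or gc is None:
        return State.UNCLASSIFIED, Origin.NA
    parental = set(gm) | set(gf)
    if any(a not in parental for a in gc):
        return State.DENOVO, Origin.NA
    child = sorted(gc)
    transmissions = {tuple(sorted((a, b))) for a in gm for b in gf}
    if tuple(child) in transmissions:
        return State.MENDELIAN, Origin.NA
    owners = [
        o
        for o, g in ((Origin.MOTHER, gm), (Origin.FATHER, gf))
        if set(gc) <= set(g)
    ]
    return State.MIE, owners[0] if len(owners) == 1 else Origin.UNDETERMINED


class TestClassifyByGenotype:
    def test_het_offspring_from_opposite_homozygotes(self):
        # mother A/A, father G/G, offspring A/G
        assert classify_by_genotype((0, 0), (1, 1), (0, 1)) == (
            State.MENDELIAN,
            Origin.NA,
        )

    def test_pair_of_alleles_from_one_parent_is_mie(self):
        # mother A/A, father G/G, offspring G/G
        assert classify_by_genotype((0, 0), (1, 1), (1, 1)) == (
            State.MIE,
            Origin.FATHER,
        )

    def test_novel_allele_is_denovo(self):
        # mother A/A, father A/A, offspring A/T
        assert classify_by_genotype((0, 0), (0, 0), (0, 1)) == (
            State.DENOVO,
            Origin.NA,
        )

    def test_missing_genotype_unclassified(self):
        assert classify_by_genotype(None, (0, 0), (0, 0)) == (
            State.UNCLASSIFIED,
            Origin.NA,
        )

    def test_exhaustive_biallelic_agreement_with_oracle(self):
        gts = [(a, b) for a in range(2) for b in range(a, 2)]
        for gm, gf, gc in itertools.product(gts, repeat=3):
            assert classify_by_genotype(gm, gf, gc) == oracle_classify(gm, gf, gc)

    def test_exhaustive_triallelic_agreement_with_oracle(self):
        gts = [(a, b) for a in range(3) for b in range(a, 3)]
        for gm, gf, gc in itertools.product(gts, repeat=3):
            assert classify_by_genotype(gm, gf, gc) == oracle_classify(gm, gf, gc)

    def test_parent_swap_symmetry(self):
        gts = [(a, b) for a in range(3) for b in range(a, 3)]
        swap = {
            Origin.MOTHER: Origin.FATHER,
            Origin.FATHER: Origin.MOTHER,
            Origin.UNDETERMINED: Origin.UNDETERMINED,
            Origin.NA: Origin.NA,
        }
        for gm, gf, gc in itertools.product(gts, repeat=3):
            state, origin = classify_by_genotype(gm, gf, gc)
            state2, origin2 = classify_by_genotype(gf, gm, gc)
            assert state2 == state
            assert origin2 == swap[origin]

    def test_biallelic_mie_origin_always_determined(self):
        gts = [(a, b) for a in range(2) for b in range(a, 2)]
        for gm, gf, gc in itertools.product(gts, repeat=3):
            state, origin = classify_by_genotype(gm, gf, gc)
            if state == State.MIE:
                assert origin in (Origin.MOTHER, Origin.FATHER)

    def test_denovo_takes_precedence_over_mie(self):
        gts = [(a, b) for a in range(3) for b in range(a, 3)]
        for gm, gf, gc in itertools.product(gts, repeat=3):
            parental = set(gm) | set(gf)
            if any(a not in parental for a in gc):
                state, _ = classify_by_genotype(gm, gf, gc)
                assert state == State.DENOVO

    def test_mie_origin_determined_up_to_three_alleles(self):
        # any two-owner or zero-owner configuration turns out Mendelian or
        # de novo instead, so the UNDETERMINED category stays defensive
        gts = [(a, b) for a in range(3) for b in range(a, 3)]
        for gm, gf, gc in itertools.product(gts, repeat=3):
            state, origin = classify_by_genotype(gm, gf, gc)
            if state == State.MIE:
                assert origin in (Origin.MOTHER, Origin.FATHER)


def exact_binom_sf(k, n, p):
    """Independent exact tail P(X >= k) via math.comb."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestGenotypeFromReads:
    def test_hom_ref_without_alt_evidence(self):
        assert genotype_from_reads((18, 0), CFG) == (0, 0)

    def test_balanced_het(self):
        # freq 0.5 >= 0.20 and exact binomial tail far below 0.05
        assert exact_binom_sf(9, 18, 0.01) < 1e-10
        assert genotype_from_reads((9, 9), CFG) == (0, 1)

    def test_below_min_coverage_missing(self):
        assert genotype_from_reads((9, 0), CFG) is None

    def test_all_zero_depths_missing(self):
        assert genotype_from_reads((0, 0), CFG) is None

    def test_low_frequency_allele_not_called(self):
        # 2/20 = 0.10 < 0.20 under default thresholds
        assert genotype_from_reads((18, 2), CFG) == (0, 0)

    def test_relaxed_thresholds_rescue_low_frequency(self):
        # 2/20 = 0.10 >= adj_var_freq 0.05; P(X>=2 | 20, 0.01) ~= 0.017 <= 0.15
        assert 0.015 < exact_binom_sf(2, 20, 0.01) < 0.02
        assert genotype_from_reads((18, 2), CFG, relaxed=True) == (0, 1)

    def test_single_read_called_only_under_relaxed_thresholds(self):
        # 1/12 reads: freq 0.083 and P(X>=1 | 12, 0.01) ~= 0.114 fail the
        # strict gates (0.20 / 0.05) but pass the relaxed ones (0.05 / 0.15)
        assert 0.11 < exact_binom_sf(1, 12, 0.01) < 0.12
        assert genotype_from_reads((11, 1), CFG) == (0, 0)
        assert genotype_from_reads((11, 1), CFG, relaxed=True) == (0, 1)

    def test_hom_alt(self):
        assert genotype_from_reads((0, 25), CFG) == (1, 1)

    def test_significance_gate_matches_exact_binomial(self):
        # counts straddling the p-value threshold at n=400, e=0.01
        # P(X>=9 | 400, 0.01) ~ 0.0285 <= 0.05 ; P(X>=8) ~ 0.068 > 0.05
        assert exact_binom_sf(9, 400, 0.01) < 0.05 < exact_binom_sf(8, 400, 0.01)
        cfg = ReadGenotypeConfig(min_var_freq=0.01)
        assert genotype_from_reads((391, 9), cfg) == (0, 1)
        assert genotype_from_reads((392, 8), cfg) == (0, 0)

    def test_tie_break_toward_reference(self):
        # three alleles, ref ties with one alt for the second slot
        cfg = ReadGenotypeConfig(min_var_freq=0.1)
        ad = (10, 10, 20)
        assert genotype_from_reads(ad, cfg, alleles=("A", "C", "G")) == (0, 2)


def trio_record(gm, gf, gc, ads=None, alts=("G",), dps=None):
    return make_record(gts=(gm, gf, gc), ads=ads, alts=alts, dps=dps)


class TestReconcileTrio:
    def test_concordant_mie_retained(self):
        rec = trio_record((0, 0), (1, 1), (1, 1))
        call = reconcile_trio(rec, CFG)
        assert call.state == State.MIE
        assert call.origin == Origin.FATHER
        assert call.method_agreement == "both"

    def test_concordant_denovo(self):
        rec = trio_record((0, 0), (0, 0), (0, 1))
        call = reconcile_trio(rec, CFG)
        assert call.state == State.DENOVO

    def test_low_frequency_novel_allele_demoted(self):
        # GT claims de novo but the "novel" allele has 1/31 reads (freq 0.03,
        # below even the relaxed 0.05): the read re-call is hom-ref, so the
        # offspring re-classifies as Mendelian, not de novo.
        rec = trio_record(
            (0, 0), (0, 0), (0, 1), ads=[(30, 0), (30, 0), (30, 1)]
        )
        call = reconcile_trio(rec, CFG)
        assert call.state == State.MENDELIAN

    def test_read_evidence_of_parent_allele_demotes_denovo(self):
        # GT says de novo (parents hom-ref) but the father's reads carry the
        # alt at 6/20: the read classifier sees a het father (Mendelian
        # site), the disagreement survives re-call, and the site is demoted.
        rec = trio_record(
            (0, 0), (0, 0), (0, 1), ads=[(30, 0), (14, 6), (15, 15)]
        )
        call = reconcile_trio(rec, CFG)
        assert call.state == State.MENDELIAN
        assert call.reason == "read_recall_mendelian"

    def test_missing_ad_unclassified(self):
        rec = make_record(
            gts=((0, 0), (1, 1), (1, 1)),
            ads=[None, (0, 30), (0, 30)],
            dps=[30, 30, 30],
        )
        call = reconcile_trio(rec, CFG)
        assert call.state == State.UNCLASSIFIED
        assert call.reason == "missing_allele_depths"

    def test_reported_set_is_method_intersection(self, small_sim):
        """Non-Mendelian report == (method A non-Mendelian) AND (method B or
        relaxed re-call agreeing), computed independently per site."""
        fp = filter_pipeline(small_sim.records, small_sim.masks, FilterConfig())
        passing = [r for r, v in fp if v.passed]
        for rec in passing[:500]:
            call = reconcile_trio(rec, CFG)
            state_a, _ = classify_by_genotype(*(s.genotype for s in rec.samples))
            strict = [
                genotype_from_reads(s.allele_depths, CFG, rec.alleles)
                for s in rec.samples
            ]
            state_b, _ = classify_by_genotype(*strict)
            relaxed = [
                genotype_from_reads(s.allele_depths, CFG, rec.alleles, relaxed=True)
                if rg != s.genotype
                else rg
                for s, rg in zip(rec.samples, strict)
            ]
            state_c, _ = classify_by_genotype(*relaxed)
            expected_nm = state_a in (State.MIE, State.DENOVO) and (
                state_b == state_a or state_c == state_a
            )
            got_nm = call.state in (State.MIE, State.DENOVO)
            assert got_nm == expected_nm, (rec.chrom, rec.pos)
            if got_nm:
                assert call.state == state_a


class TestSupportFilters:
    def mk_call(self, rec):
        return reconcile_trio(rec, CFG)

    def test_het_offspring_both_alleles_supported(self):
        rec = trio_record((0, 0), (0, 0), (0, 1), ads=[(20, 0), (20, 0), (6, 7)])
        call = self.mk_call(rec)
        assert call.state == State.DENOVO
        assert apply_support_filters(call, rec, CFG)

    def test_het_offspring_weak_allele_dropped(self):
        rec = trio_record((0, 0), (0, 0), (0, 1), ads=[(20, 0), (20, 0), (12, 4)])
        call = self.mk_call(rec)
        assert call.state == State.DENOVO
        assert not apply_support_filters(call, rec, CFG)

    def test_hom_offspring_boundary_retained(self):
        rec = trio_record((0, 0), (1, 1), (1, 1), ads=[(20, 0), (0, 20), (0, 10)])
        call = self.mk_call(rec)
        assert call.state == State.MIE
        assert apply_support_filters(call, rec, CFG)

    @staticmethod
    def force_call(rec, state=State.MIE, origin=Origin.FATHER):
        from triomut.inheritance import InheritanceCall

        return InheritanceCall(
            chrom=rec.chrom, pos=rec.pos, state=state, origin=origin,
            method_agreement="both",
            offspring_allele_depths=rec.offspring.allele_depths,
            mother_depth=rec.mother.total_depth,
            father_depth=rec.father.total_depth,
            offspring_depth=rec.offspring.total_depth,
        )

    def test_hom_offspring_nine_reads_dropped(self):
        rec = trio_record(
            (0, 0), (1, 1), (1, 1), ads=[(20, 0), (0, 20), (0, 9)], dps=[20, 20, 10]
        )
        assert not apply_support_filters(self.force_call(rec), rec, CFG)

    def test_shallow_parent_dropped(self):
        rec = trio_record(
            (0, 0), (1, 1), (1, 1), ads=[(9, 0), (0, 20), (0, 20)]
        )
        assert not apply_support_filters(self.force_call(rec), rec, CFG)

    def test_only_non_mendelian_calls_accepted(self):
        rec = trio_record((0, 0), (1, 1), (0, 1))
        call = self.mk_call(rec)
        with pytest.raises(ValueError):
            apply_support_filters(call, rec, CFG)


class TestRunTrioClassification:
    def test_empty_input_zero_tallies(self):
        calls, tallies = run_trio_classification([], CFG)
        assert calls == []
        assert all(v == 0 for v in tallies.values())

    def test_tallies_partition_input(self, small_sim):
        fp = filter_pipeline(small_sim.records, small_sim.masks, FilterConfig())
        passing = [r for r, v in fp if v.passed]
        calls, t = run_trio_classification(passing, CFG)
        assert len(calls) == t["n_input"] == len(passing)
        assert (
            t["n_mendelian"] + t["n_mie"] + t["n_denovo"] + t["n_unclassified"]
            == t["n_input"]
        )
        assert (
            t["n_mie"]
            == t["n_mie_from_mother"]
            + t["n_mie_from_father"]
            + t["n_mie_undetermined"]
        )

    def test_planted_events_recovered(self, small_sim):
        """Planted MIE/de novo events surviving the filters are recovered
        (high-coverage exact-logic regime) with no false non-Mendelian calls
        at truthful sites."""
        fp = filter_pipeline(small_sim.records, small_sim.masks, FilterConfig())
        passing = [r for r, v in fp if v.passed]
        calls, t = run_trio_classification(passing, CFG)
        truth = small_sim.truth_by_key()
        planted_passing = {
            (r.chrom, r.pos): truth[(r.chrom, r.pos)].event
            for r in passing
            if truth[(r.chrom, r.pos)].event != "none"
        }
        recovered = {
            (c.chrom, c.pos): c.state.value
            for c in calls
            if c.retained and c.state in (State.MIE, State.DENOVO)
        }
        false_calls = set(recovered) - set(planted_passing)
        assert not false_calls
        hits = sum(
            1 for k, ev in planted_passing.items() if recovered.get(k) == ev
        )
        assert hits >= 0.95 * len(planted_passing)
        # origins match truth for recovered MIEs
        for c in calls:
            if c.retained and c.state == State.MIE:
                assert c.origin.value == truth[(c.chrom, c.pos)].event_origin
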