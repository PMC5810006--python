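import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairedmet.somatic_filtering import (
    FilterConfig,
    PatientCase,
    filter_somatic,
    fold_substitution,
    mutation_load_summary,
    pooled_t_test,
    select_shared_positions,
    substitution_spectrum,
)

from conftest import make_variant


class TestFilterSomatic:
    def test_passing_record_is_exome_wide(self):
        # germline VAF 0.005, tumor_alt 8/40 = 0.20, both strands
        rec = make_variant(germline_ref=199, germline_alt=1,
                           tumor_ref=32, tumor_alt=8, tumor_alt_fwd=4, tumor_alt_rev=4)
        verdict = filter_somatic(rec)
        assert verdict.kept and verdict.tier == "exome_wide"
        assert verdict.reasons == ()

    def test_germline_vaf_rule(self):
        rec = make_variant(germline_ref=49, germline_alt=1)  # VAF 0.02
        verdict = filter_somatic(rec)
        assert not verdict.kept
        assert verdict.reasons == ("germline_vaf",)

    def test_single_strand_rule(self):
        rec = make_variant(tumor_ref=34, tumor_alt=6, tumor_alt_fwd=6, tumor_alt_rev=0)
        verdict = filter_somatic(rec)
        assert not verdict.kept
        assert "single_strand" in verdict.reasons

    def test_low_alt_reads(self):
        rec = make_variant(tumor_ref=37, tumor_alt=3, tumor_alt_fwd=2, tumor_alt_rev=1)
        verdict = filter_somatic(rec)
        assert "low_alt_reads" in verdict.reasons

    def test_coverage_bound_is_exclusive(self):
        rec = make_variant(tumor_ref=22, tumor_alt=8, tumor_alt_fwd=4, tumor_alt_rev=4)
        assert "low_coverage" in filter_somatic(rec).reasons  # coverage == 30
        rec31 = make_variant(tumor_ref=23, tumor_alt=8, tumor_alt_fwd=4, tumor_alt_rev=4)
        assert "low_coverage" not in filter_somatic(rec31).reasons

    def test_vaf_bound_is_exclusive(self):
        # 8/50 = 0.16 exactly: must fail the strict bound
        rec = make_variant(tumor_ref=42, tumor_alt=8, tumor_alt_fwd=4, tumor_alt_rev=4)
        assert "low_vaf" in filter_somatic(rec).reasons

    def test_zero_tumor_coverage_is_not_evaluable(self):
        rec = make_variant(tumor_ref=0, tumor_alt=0, tumor_alt_fwd=0, tumor_alt_rev=0)
        verdict = filter_somatic(rec)
        assert not verdict.kept
        assert verdict.reasons == ("not_evaluable",)

    def test_normal_support_flag(self):
        # germline 2/400 = 0.5% passes the VAF cap but carries real support
        rec = make_variant(germline_ref=398, germline_alt=2)
        assert "normal_support" in filter_somatic(rec).reasons

    def test_missing_strand_reported_not_evaluable_but_kept(self):
        rec = make_variant(tumor_alt_fwd=None, tumor_alt_rev=None)
        verdict = filter_somatic(rec)
        assert verdict.kept
        assert not verdict.strand_evaluable

    def test_disabled_rules_keep_any_record_with_alt_reads(self):
        # floors at zero; the germline cap is a maximum so its neutral
        # element is 1; QC flags off
        config = FilterConfig(max_germline_vaf=1.0, min_tumor_alt_reads=0,
                              min_coverage=0, min_exomewide_vaf=0.0,
                              enable_qc_flags=False)
        rec = make_variant(germline_ref=10, germline_alt=5, tumor_ref=0, tumor_alt=1,
                           tumor_alt_fwd=1, tumor_alt_rev=0)
        assert filter_somatic(rec, config).kept


TIGHTENABLE = ("min_tumor_alt_reads", "min_coverage")


@settings(max_examples=200, deadline=None)
@given(
    germline_ref=st.integers(0, 200),
    germline_alt=st.integers(0, 20),
    tumor_ref=st.integers(0, 200),
    tumor_alt=st.integers(0, 60),
    bump_alt=st.integers(0, 10),
    bump_cov=st.integers(0, 40),
    bump_vaf=st.floats(0, 0.5),
    cut_germline=st.floats(0, 0.01),
)
def test_tightening_thresholds_never_rescues_a_rejected_record(
    germline_ref, germline_alt, tumor_ref, tumor_alt,
    bump_alt, bump_cov, bump_vaf, cut_germline,
):
    fwd = tumor_alt // 2
    rec = make_variant(germline_ref=germline_ref, germline_alt=germline_alt,
                       tumor_ref=tumor_ref, tumor_alt=tumor_alt,
                       tumor_alt_fwd=fwd, tumor_alt_rev=tumor_alt - fwd)
    base = FilterConfig()
    tighter = FilterConfig(
        max_germline_vaf=max(base.max_germline_vaf - cut_germline, 0.0),
        min_tumor_alt_reads=base.min_tumor_alt_reads + bump_alt,
        min_coverage=base.min_coverage + bump_cov,
        min_exomewide_vaf=min(base.min_exomewide_vaf + bump_vaf, 1.0),
    )
    if not filter_somatic(rec, base).kept:
        assert not filter_somatic(rec, tighter).kept


class TestSelectSharedPositions:
    def test_panel_gene_low_reads_retained_as_shared(self):
        p = make_variant(gene="AKAP9", tumor_ref=47, tumor_alt=3,
                         tumor_alt_fwd=2, tumor_alt_rev=1, compartment="primary")
        m = make_variant(gene="AKAP9", tumor_ref=38, tumor_alt=12,
                         tumor_alt_fwd=6, tumor_alt_rev=6, compartment="metastasis")
        (entry,) = select_shared_positions([p], [m], {"AKAP9"})
        assert entry.label == "shared"

    def test_metastasis_only_when_primary_has_no_alt_reads(self):
        p = make_variant(gene="AKAP9", tumor_ref=50, tumor_alt=0,
                         tumor_alt_fwd=0, tumor_alt_rev=0, compartment="primary")
        m = make_variant(gene="AKAP9", tumor_ref=30, tumor_alt=12,
                         tumor_alt_fwd=6, tumor_alt_rev=6, compartment="metastasis")
        (entry,) = select_shared_positions([p], [m], {"AKAP9"})
        assert entry.label == "metastasis_only"

    def test_non_panel_low_read_variant_not_retained(self):
        p = make_variant(gene="OTHER", tumor_ref=47, tumor_alt=3,
                         tumor_alt_fwd=2, tumor_alt_rev=1)
        assert select_shared_positions([p], [], {"AKAP9"}) == []

    def test_empty_panel_reports_all_genes_with_warning(self):
        p = make_variant(gene="OTHER")
        with pytest.warns(UserWarning, match="empty gene panel"):
            report = select_shared_positions([p], [], set())
        assert len(report) == 1

    def test_germline_rule_still_applies_to_panel_genes(self):
        p = make_variant(gene="AKAP9", germline_ref=45, germline_alt=5)
        assert select_shared_positions([p], [], {"AKAP9"}) == []


class TestSubstitutionSpectrum:
    def test_direct_counts(self):
        recs = [make_variant(ref_base=r, alt_base=a)
                for r, a in [("A", "G"), ("G", "A"), ("C", "T"), ("A", "C")]]
        spectrum = substitution_spectrum(recs)
        assert spectrum.transitions == 3
        assert spectrum.transversions == 1
        assert spectrum.titv_ratio == pytest.approx(3.0)

    def test_zero_transversions_undefined_ratio(self):
        spectrum = substitution_spectrum([make_variant(ref_base="A", alt_base="G")])
        assert spectrum.titv_ratio is None

    def test_strand_folding(self):
        recs = [make_variant(ref_base="C", alt_base="T"),
                make_variant(ref_base="G", alt_base="A")]
        spectrum = substitution_spectrum(recs)
        assert spectrum.per_substitution_counts["C>T"] == 2

    def test_titv_invariant_under_strand_complement(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        comp = dict(zip("ACGT", "TGCA"))
        pairs = [tuple(rng.choice(list(bases), 2, replace=False)) for _ in range(40)]
        closed = pairs + [(comp[r], comp[a]) for r, a in pairs]
        folded = substitution_spectrum([make_variant(ref_base=r, alt_base=a) for r, a in pairs])
        full = substitution_spectrum([make_variant(ref_base=r, alt_base=a) for r, a in closed])
        assert full.titv_ratio == pytest.approx(folded.titv_ratio)

    def test_non_snv_skipped(self):
        spectrum = substitution_spectrum([make_variant(ref_base="C", alt_base="C")])
        assert spectrum.n_skipped == 1
        assert spectrum.total == 0

    def test_fold_substitution_classes(self):
        assert fold_substitution("G", "A") == "C>T"
        assert fold_substitution("A", "C") == "T>G"
        assert fold_substitution("C", "G") == "C>G"


class TestMutationLoad:
    def test_identical_vectors_give_t0_p1(self):
        assert pooled_t_test([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_t_matches_textbook_oracle(self):
        # frozen from the pooled-variance formula on [3,5,7] vs [10,12,9,11]
        t, p = pooled_t_test([3, 5, 7], [10, 12, 9, 11])
        assert t == pytest.approx(-4.465988686176326, rel=1e-12)
        assert p == pytest.approx(0.006603732015562648, rel=1e-12)

    def test_group_means(self):
        cases = []
        for i, (np_, nm) in enumerate([(0, 10), (0, 10), (0, 10)]):
            variants = {
                "primary": [make_variant(pos=j + 1, gene=f"G{j}") for j in range(np_)],
                "metastasis": [make_variant(pos=j + 1, gene=f"G{j}",
                                            compartment="metastasis") for j in range(nm)],
            }
            cases.append(PatientCase(patient_id=f"P{i}", variants=variants))
        summary = mutation_load_summary(cases)
        assert summary.means["primary"] == 0.0
        assert summary.means["metastasis"] == 10.0
        assert summary.t_statistic == -math.inf

    def test_single_patient_compartment_omits_comparison(self):
        case = PatientCase(patient_id="P1", variants={"primary": [], "metastasis": []})
        summary = mutation_load_summary([case])
        assert summary.t_statistic is None
        assert summary.per_patient["primary"] == {"P1": 0}

    def test_simulated_enrichment_direction(self):
        from pairedmet.synthetic_data import SimulationParams, simulate_case

        cases = []
        for seed in range(4):
            params = SimulationParams(n_snps=10, somatic_rate_primary=10.0,
                                      somatic_rate_metastasis=40.0, seed=seed)
            sim = simulate_case(params)
            cases.append(PatientCase(
                patient_id=f"P{seed}",
                variants={"primary": sim.variants_primary,
                          "metastasis": sim.variants_metastasis}))
        summary = mutation_load_summary(cases)
        assert summary.means["metastasis"] > summary.means["primary"]
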