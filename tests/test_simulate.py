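"""Determinism, construction guarantees and truth-label fidelity of the
synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest

import poipanel as pp
from poipanel import cnv, filtering, simulate
from poipanel.types import PatientProfile


def to_profile(row) -> PatientProfile:
    return PatientProfile(
        patient_id=row.patient_id, age=row.age, amh=row.amh, fsh=row.fsh,
        e2=row.e2, afc=int(row.afc), fi=row.fi, vi=row.vi, vfi=row.vfi,
    )


class TestProfiles:
    def test_cases_and_controls_classify_as_constructed(self):
        cfg = simulate.SimConfig(seed=1, n_cases=10, n_controls=10)
        profiles = simulate.generate_profiles(cfg)
        for _, row in profiles.iterrows():
            profile = to_profile(row)
            status, _ = pp.classify_eligibility(profile, pp.compute_ovage(profile))
            assert status == row["status"]

    def test_same_seed_identical_tables(self):
        cfg = simulate.SimConfig(seed=5, n_cases=4, n_controls=4)
        a = simulate.generate_profiles(cfg)
        b = simulate.generate_profiles(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate.generate_profiles(simulate.SimConfig(seed=1, n_cases=4, n_controls=0))
        b = simulate.generate_profiles(simulate.SimConfig(seed=2, n_cases=4, n_controls=0))
        assert not a.drop(columns=["patient_id", "status"]).equals(
            b.drop(columns=["patient_id", "status"])
        )


class TestVariants:
    def test_zero_rates_give_empty_call_set(self, small_sim):
        profiles = simulate.generate_profiles(small_sim)
        cohort = simulate.plant_exact(small_sim, profiles, 0, 0, 0)
        assert cohort.case_variants.empty

    def test_truth_sidecar_covers_every_plant(self, small_sim):
        profiles = simulate.generate_profiles(small_sim)
        cohort = simulate.generate_variants(small_sim, profiles)
        assert len(cohort.truth) == len(cohort.case_variants)
        assert set(cohort.truth["truth_class"]) <= {
            "pathogenic", "vus", "shared", "common",
        }

    def test_planted_classes_behave_under_the_cascade(self, small_sim):
        profiles = simulate.generate_profiles(small_sim)
        cohort = simulate.generate_variants(small_sim, profiles)
        report = filtering.run_cascade(cohort.case_variants, cohort.control_keys)
        retained_classes = set(report.retained["truth_class"])
        assert retained_classes <= {"pathogenic", "vus"}
        excluded = cohort.case_variants.loc[
            ~cohort.case_variants.index.isin(report.retained.index)
        ]
        # every rare case-only plant survives; shared and common never do
        assert len(report.retained) == (
            cohort.case_variants["truth_class"].isin(["pathogenic", "vus"]).sum()
        )

    def test_planted_criteria_match_truth_class(self, small_sim):
        profiles = simulate.generate_profiles(small_sim)
        cohort = simulate.generate_variants(small_sim, profiles)
        classified = pp.classify_all(
            cohort.case_variants, pp.ConflictPolicy(mode="paper_concordant")
        )
        for _, row in classified.iterrows():
            if row["truth_class"] == "pathogenic":
                assert row["computed_classification"] in {"P", "LP"}
            elif row["truth_class"] in {"vus", "shared"}:
                assert row["computed_classification"] == "VUS"
            else:
                assert row["computed_classification"] in {"LB", "B"}

    def test_seeded_vcf_emission_is_deterministic(self, small_sim, tmp_path):
        a = simulate.write_outputs(small_sim, tmp_path / "a")
        b = simulate.write_outputs(small_sim, tmp_path / "b")
        for name in a:
            assert (
                open(a[name], "rb").read() == open(b[name], "rb").read()
            ), f"{name} not byte-identical"


class TestMarginals:
    def test_paper_like_rates_reproduce_cohort_marginals(self):
        """Default plant rates give ~60% mutated and ~37:23 monogenic:polygenic."""
        cfg = simulate.SimConfig(seed=11, n_cases=100, n_controls=0)
        profiles = simulate.generate_profiles(cfg)
        cohort = simulate.generate_variants(cfg, profiles)
        report = filtering.run_cascade(cohort.case_variants, cohort.control_keys)
        classified = pp.classify_all(
            report.retained, pp.ConflictPolicy(mode="paper_concordant")
        )
        classified = classified.rename(
            columns={"computed_classification": "classification"}
        )
        part = pp.summarize.partition_patients(classified)
        n_mutated = part["n_patients"]
        # binomial sampling bands around the published 60 / 37 / 23 split
        assert 45 <= n_mutated <= 75
        assert part["monogenic"] / n_mutated == pytest.approx(37 / 60, abs=0.17)


class TestCoverage:
    def test_no_plants_near_zero_log2_ratios(self):
        cfg = simulate.SimConfig(
            seed=2, n_cases=1, panel_genes=("G1", "G2"), amplicons_per_gene=30,
            coverage_sigma=0.01, n_coverage_controls=10,
        )
        cov = simulate.generate_coverage(cfg)
        baseline, _ = cnv.build_baseline(cov.control_matrix)
        gc = cov.panel.set_index("amplicon_id")["gc_fraction"]
        log2r = cnv.normalize_and_correct_gc(cov.case_matrix.iloc[:, 0], baseline, gc)
        assert np.abs(log2r.values).max() < 0.1

    def test_gc_coefficient_zero_correction_is_noop(self):
        cfg = simulate.SimConfig(
            seed=2, n_cases=1, panel_genes=("G1", "G2"), amplicons_per_gene=40,
            coverage_sigma=0.01, n_coverage_controls=10, gc_coef=0.0,
        )
        cov = simulate.generate_coverage(cfg)
        baseline, _ = cnv.build_baseline(cov.control_matrix)
        gc = cov.panel.set_index("amplicon_id")["gc_fraction"]
        sample = cov.case_matrix.iloc[:, 0]
        corrected = cnv.normalize_and_correct_gc(sample, baseline, gc)
        raw = np.log2((sample / sample.sum()) / baseline)
        # bin-median scaling only re-centres; with no bias the shift is tiny
        assert np.abs(corrected.values - raw.values).max() < 0.05

    def test_planted_cnv_recorded_in_truth_and_recovered(self):
        cfg0 = simulate.SimConfig(
            seed=4, n_cases=1, panel_genes=("G1", "G2", "G3", "G4"),
            amplicons_per_gene=50, coverage_sigma=0.1, n_coverage_controls=20,
        )
        panel = simulate.build_panel(cfg0)
        span = panel.iloc[80:100]
        plant = simulate.CNVPlant(
            chrom=span["chrom"].iloc[0],
            start=int(span["start"].min()),
            end=int(span["end"].max()),
            ploidy=3,
            carrier_fraction=1.0,
        )
        cfg = simulate.SimConfig(
            seed=4, n_cases=1, panel_genes=cfg0.panel_genes, amplicons_per_gene=50,
            coverage_sigma=0.1, n_coverage_controls=20, cnv_plants=(plant,),
        )
        cov = simulate.generate_coverage(cfg)
        assert len(cov.truth) == 1 and cov.truth["n_amplicons"].iloc[0] == 20
        baseline, _ = cnv.build_baseline(cov.control_matrix)
        gc = cov.panel.set_index("amplicon_id")["gc_fraction"]
        log2r = cnv.normalize_and_correct_gc(cov.case_matrix.iloc[:, 0], baseline, gc)
        segments = cnv.call_cnv_hmm(log2r, cov.panel, sample_id="s")
        gains = [s for s in segments if s.change == "gain"]
        assert len(gains) == 1 and gains[0].ploidy == 3
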