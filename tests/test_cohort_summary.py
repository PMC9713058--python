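import filecmp

import pytest

from germscreen.acmg import CriteriaSet, classify_table
from germscreen.cohort_summary import (
    ScreenConfig,
    build_report,
    carrier_frequency,
    cosegregation_summary,
    median_onset,
    recurrent_gene_screen,
    run_screen,
    summarize_by_inheritance,
)
from germscreen.io_formats import (
    Inheritance,
    PanelGene,
    PedigreeGraph,
    PedigreeMember,
    ValidationError,
    VariantRecord,
    Zygosity,
)
from germscreen.synthetic_data import SimulationConfig, simulate_cohort


class TestCarrierFrequency:
    @pytest.mark.parametrize(
        "count,n,expected",
        [(12, 128, 9.4), (5, 128, 3.9), (3, 128, 2.3), (27, 128, 21.1), (0, 128, 0.0)],
    )
    def test_published_percents(self, count, n, expected):
        assert carrier_frequency(count, n) == expected

    def test_half_up_rounding(self):
        assert carrier_frequency(1, 16) == 6.3  # 6.25 rounds up, not to even

    def test_scale_consistency_and_monotonicity(self):
        assert carrier_frequency(12, 128) == carrier_frequency(120, 1280)
        values = [carrier_frequency(k, 128) for k in range(129)]
        assert values == sorted(values)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValidationError):
            carrier_frequency(1, 0)


def _het_record(gene, carriers, pos):
    return VariantRecord(
        chrom="1",
        pos=pos,
        ref="A",
        alt="T",
        gene=gene,
        coding_impact="missense",
        carriers={pid: Zygosity.HET for pid in carriers},
    )


class TestInheritanceStrata:
    def test_table1_all_dominant_counts_patient_113_once(
        self, table1_bundle, table1_printed_classified
    ):
        # under the published tiers all 13 rows are P/LP: 12 unique
        # carriers (patient 113 carries two variants but counts once)
        summary = summarize_by_inheritance(
            table1_printed_classified, table1_bundle.panel, table1_bundle.cohort_n
        )
        assert (summary.carriers_ad, summary.percent_ad) == (12, 9.4)
        assert summary.cohort_n == 128

    def test_engine_tiers_drop_the_discrepant_carrier(
        self, table1_bundle, table1_engine_classified
    ):
        # the rule engine calls one published LP row VUS, whose carrier
        # (patient 82) carries nothing else
        summary = summarize_by_inheritance(
            table1_engine_classified, table1_bundle.panel, table1_bundle.cohort_n
        )
        assert summary.carriers_ad == 11

    def test_ar_het_carriers_extend_the_stratum(self):
        panel = [PanelGene("POT1", Inheritance.AD), PanelGene("MUTYH", Inheritance.AR)]
        ad = [_het_record("POT1", [f"A{i}" for i in range(12)], 100)]
        ar = [_het_record("MUTYH", [f"R{i}" for i in range(15)], 200)]
        classified = classify_table(
            [(r, CriteriaSet(["PVS1", "PM2", "PP3"])) for r in ad + ar]
        )
        summary = summarize_by_inheritance(classified, panel, 128)
        assert (summary.carriers_ad, summary.percent_ad) == (12, 9.4)
        assert summary.carriers_ad_plus_ar_het == 27
        assert summary.percent_ad_plus_ar_het == 21.1

    def test_ar_homozygotes_not_in_het_stratum(self):
        panel = [PanelGene("MUTYH", Inheritance.AR)]
        rec = _het_record("MUTYH", [], 100)
        rec.carriers = {"P1": Zygosity.HOM, "P2": Zygosity.HET}
        classified = classify_table([(rec, CriteriaSet(["PVS1", "PM2", "PP3"]))])
        summary = summarize_by_inheritance(classified, panel, 100)
        assert summary.carriers_ad_plus_ar_het == 1

    def test_gene_missing_from_panel_named(self, table1_printed_classified):
        with pytest.raises(ValidationError, match="ATM"):
            summarize_by_inheritance(
                table1_printed_classified, [PanelGene("POT1", Inheritance.AD)], 128
            )

    def test_empty_records_give_zeros(self, table1_bundle):
        summary = summarize_by_inheritance([], table1_bundle.panel, 128)
        assert (summary.carriers_ad, summary.carriers_ad_plus_ar_het) == (0, 0)


class TestRecurrenceScreen:
    def test_table1_recurrent_genes(self, table1_printed_classified):
        assert recurrent_gene_screen(table1_printed_classified) == [
            ("CHEK2", 5),
            ("POT1", 3),
            ("BRCA2", 2),
        ]

    def test_min_one_lists_every_gene(self, table1_printed_classified):
        hits = dict(recurrent_gene_screen(table1_printed_classified, min_patients=1))
        assert set(hits) == {"ATM", "ATR", "BRCA2", "CHEK2", "POT1", "PALB2"}

    def test_empty_input(self):
        assert recurrent_gene_screen([]) == []

    def test_order_invariance(self, table1_printed_classified):
        reversed_output = recurrent_gene_screen(
            list(reversed(table1_printed_classified))
        )
        assert reversed_output == recurrent_gene_screen(table1_printed_classified)

    def test_duplicate_row_does_not_change_patient_counts(
        self, table1_printed_classified
    ):
        chek2 = next(
            cv for cv in table1_printed_classified if cv.record.gene == "CHEK2"
        )
        assert recurrent_gene_screen(
            list(table1_printed_classified) + [chek2]
        ) == recurrent_gene_screen(table1_printed_classified)


class TestMedianOnset:
    def test_four_carriers(self):
        median, (low, high) = median_onset([50, 66, 55, 77])
        assert median == 60.5
        assert (low, high) == (50, 77)

    @pytest.mark.parametrize("ages,expected", [([63], 63), ([1, 2, 3], 2)])
    def test_small_lists(self, ages, expected):
        assert median_onset(ages)[0] == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            median_onset([])


class TestCosegregation:
    def test_family2_confirmed_affected_carrier(self, table1_bundle):
        fam2 = next(p for p in table1_bundle.pedigrees if p.family_id == "2")
        variant_id = next(iter(fam2.members["II.2"].genotypes))
        summary = cosegregation_summary(fam2, variant_id)
        assert summary.affected_carriers >= 1
        assert fam2.members["II.2"].genotypes[variant_id] == "carrier"
        assert summary.untested_affected == 1  # deceased affected parent

    def test_family3_father_is_affected_noncarrier(self, table1_bundle):
        fam3 = next(p for p in table1_bundle.pedigrees if p.family_id == "3")
        pot1 = next(
            vid
            for vid, status in fam3.members["I.1"].genotypes.items()
            if status == "noncarrier"
        )
        summary = cosegregation_summary(fam3, pot1)
        assert summary.affected_noncarriers == 1
        assert summary.affected_carriers == 1  # the index

    def test_untyped_pedigree_counts_all_untested(self):
        graph = PedigreeGraph("9")
        graph.add_member(PedigreeMember("a", None, None, "M", True))
        graph.add_member(PedigreeMember("b", None, None, "F", True))
        with pytest.warns(UserWarning, match="no tested genotypes"):
            summary = cosegregation_summary(graph, "1:1:A:T")
        assert (summary.tested_affected, summary.untested_affected) == (0, 2)


class TestRunScreen:
    def _config(self, bundle_dir, out_dir):
        return ScreenConfig(
            variants_path=str(bundle_dir / "variants.tsv"),
            variants_format="tsv",
            panel_path=str(bundle_dir / "panel.tsv"),
            phenotypes_path=str(bundle_dir / "phenotypes.tsv"),
            ref_counts_path=str(bundle_dir / "ref_counts.tsv"),
            criteria_path=str(bundle_dir / "criteria.tsv"),
            ped_path=str(bundle_dir / "pedigrees.ped"),
            out_dir=str(out_dir),
        )

    def test_table1_bundle_reports_published_carrier_percent(
        self, tmp_path, table1_bundle
    ):
        bundle_dir = table1_bundle.write(tmp_path / "bundle")
        result = run_screen(self._config(bundle_dir, tmp_path / "out"))
        # 11 of 12 published carriers classify P/LP under the standard
        # rules (one known-discrepancy row is VUS here)
        assert result.report.inheritance.carriers_ad == 11
        assert result.report.inheritance.percent_ad == 8.6
        assert dict(result.report.recurrent_genes)["CHEK2"] == 5
        assert (tmp_path / "out" / "cohort_report.json").exists()

    def test_synthetic_bundle_recovers_planted_counts(self, tmp_path):
        bundle = simulate_cohort(
            SimulationConfig(seed=7), out_dir=tmp_path / "bundle"
        )
        result = run_screen(self._config(tmp_path / "bundle", tmp_path / "out"))
        assert result.report.inheritance.carriers_ad == 12
        assert result.report.inheritance.percent_ad == 9.4
        assert result.report.inheritance.carriers_ad_plus_ar_het == 27
        planted = {p["variant_id"] for p in bundle.manifest["planted"]}
        assert {cv.record.variant_id for cv in result.classified} == planted

    def test_rerun_is_byte_identical(self, tmp_path, table1_bundle):
        bundle_dir = table1_bundle.write(tmp_path / "bundle")
        run_screen(self._config(bundle_dir, tmp_path / "out1"))
        run_screen(self._config(bundle_dir, tmp_path / "out2"))
        for name in (
            "filter_report.tsv",
            "classified.tsv",
            "associations.tsv",
            "cohort_report.json",
            "cohort_report.txt",
        ):
            assert filecmp.cmp(
                tmp_path / "out1" / name, tmp_path / "out2" / name, shallow=False
            ), name

    def test_stage_error_names_stage(self, tmp_path, table1_bundle):
        bundle_dir = table1_bundle.write(tmp_path / "bundle")
        config = self._config(bundle_dir, tmp_path / "out")
        config.ref_counts_path = str(bundle_dir / "missing.tsv")
        with pytest.raises(RuntimeError, match="read_inputs"):
            run_screen(config)


class TestBuildReport:
    def test_onset_summary_merges_external_ages(
        self, table1_bundle, table1_printed_classified
    ):
        external = table1_bundle.manifest["pot1_external_carrier"]
        report = build_report(
            table1_printed_classified,
            table1_bundle.panel,
            table1_bundle.phenotypes,
            cohort_n=128,
            extra_onset_ages={"POT1": [external["age"]]},
        )
        onset = report.onset_by_gene["POT1"]
        assert onset["median"] == 60.5
        assert (onset["min"], onset["max"]) == (50, 77)

    def test_carrier_without_age_warns_and_is_excluded(
        self, table1_bundle, table1_printed_classified
    ):
        kept = [p for p in table1_bundle.phenotypes if p.patient_id != "53"]
        with pytest.warns(UserWarning, match="53"):
            report = build_report(
                table1_printed_classified, table1_bundle.panel, kept, cohort_n=128
            )
        assert report.per_gene_carriers["CHEK2"] == 5
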