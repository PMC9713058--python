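import itertools

import pytest

from germscreen.filtering import (
    FilterConfig,
    apply_impact_filter,
    apply_panel_filter,
    apply_quality_filter,
    apply_rarity_filter,
    run_cascade,
)
from germscreen.io_formats import (
    CodingImpact,
    GenotypeMetrics,
    Inheritance,
    PanelGene,
    ReferenceCountTable,
    VariantRecord,
    Zygosity,
)
from germscreen.synthetic_data import SimulationConfig, simulate_cohort


def _record(gene="CHEK2", impact=CodingImpact.MISSENSE, pos=100, carriers=("P1",)):
    return VariantRecord(
        chrom="22",
        pos=pos,
        ref="A",
        alt="T",
        gene=gene,
        coding_impact=impact,
        carriers={pid: Zygosity.HET for pid in carriers},
    )


PANEL = [PanelGene("CHEK2", Inheritance.AD), PanelGene("POT1", Inheritance.AD)]


class TestQualityFilter:
    def test_low_depth_carrier_removed(self):
        rec = _record(carriers=("P1", "P2"))
        metrics = {(rec.variant_id, "P1"): GenotypeMetrics(dp=5, gq=99)}
        (out,) = apply_quality_filter([rec], metrics, FilterConfig())
        assert out.carrier_ids == {"P2"}

    def test_all_carriers_passing_leaves_record_unchanged(self):
        rec = _record(carriers=("P1",))
        metrics = {(rec.variant_id, "P1"): GenotypeMetrics(dp=30, gq=60, ab=0.5)}
        (out,) = apply_quality_filter([rec], metrics, FilterConfig())
        assert out.carriers == rec.carriers

    def test_skewed_allele_balance_fails_het(self):
        rec = _record(carriers=("P1",))
        metrics = {(rec.variant_id, "P1"): GenotypeMetrics(dp=30, gq=60, ab=0.1)}
        assert apply_quality_filter([rec], metrics, FilterConfig()) == []

    def test_no_metrics_is_warning_noop(self):
        rec = _record()
        with pytest.warns(UserWarning, match="no-op"):
            out = apply_quality_filter([rec], None, FilterConfig())
        assert [r.variant_id for r in out] == [rec.variant_id]

    def test_record_dropped_when_only_carrier_fails_and_counts_telescope(self):
        records = [
            _record(pos=100, carriers=("P1",)),
            _record(pos=200, carriers=("P2", "P3")),
            _record(pos=300, carriers=("P4",)),
        ]
        metrics = {
            (records[0].variant_id, "P1"): GenotypeMetrics(dp=2),
            (records[1].variant_id, "P2"): GenotypeMetrics(dp=2),
        }
        ref = {"global": ReferenceCountTable("global", 1000)}
        survivors, report = run_cascade(
            records, PANEL, ref, FilterConfig(), genotype_metrics=metrics
        )
        quality = report.steps[0]
        assert (quality.n_in, quality.n_out) == (3, 2)
        assert quality.removed == [records[0].variant_id]
        for before, after in itertools.pairwise(report.steps):
            assert before.n_out == after.n_in


class TestPanelFilter:
    def test_non_panel_gene_removed(self):
        kept = apply_panel_filter(
            [_record(gene="CHEK2"), _record(gene="TTN", pos=200)], PANEL
        )
        assert [r.gene for r in kept] == ["CHEK2"]

    def test_survivors_annotated_with_inheritance(self):
        (rec,) = apply_panel_filter([_record(gene="CHEK2")], PANEL)
        assert rec.inheritance is Inheritance.AD

    def test_table1_fixture_all_pass_default_panel(self, table1_bundle):
        kept = apply_panel_filter(table1_bundle.records, table1_bundle.panel)
        assert len(kept) == len(table1_bundle.records)

    def test_empty_records(self):
        assert apply_panel_filter([], PANEL) == []

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            apply_panel_filter([_record()], [])


class TestRarityFilter:
    def _tables(self, global_counts=None, finns_counts=None):
        g = ReferenceCountTable("global", 118477)
        f = ReferenceCountTable("finns", 10816)
        if global_counts:
            g.add(*global_counts)
        if finns_counts:
            f.add(*finns_counts)
        return {"global": g, "finns": f}

    def test_ultra_rare_variant_survives(self):
        # global MAF 3.19e-5, absent from the Finnish subset
        rec = _record(gene="POT1")
        tables = self._tables(global_counts=(rec.variant_id, 6, 188088, 0))
        assert apply_rarity_filter([rec], tables, FilterConfig()) == [rec]

    def test_common_variant_removed(self):
        rec = _record()
        tables = self._tables(global_counts=(rec.variant_id, 2370, 236954, 0))
        assert apply_rarity_filter([rec], tables, FilterConfig()) == []

    def test_rare_globally_but_common_in_subpopulation_removed(self):
        rec = _record()
        tables = self._tables(
            global_counts=(rec.variant_id, 6, 236954, 0),
            finns_counts=(rec.variant_id, 200, 21632, 0),
        )
        assert apply_rarity_filter([rec], tables, FilterConfig()) == []

    def test_zero_threshold_keeps_only_unobserved(self):
        seen = _record(pos=100)
        unseen = _record(pos=200)
        tables = self._tables(global_counts=(seen.variant_id, 1, 236954, 0))
        config = FilterConfig(max_global_maf=0.0, max_subpop_maf=0.0)
        assert apply_rarity_filter([seen, unseen], tables, config) == [unseen]

    def test_an_zero_treated_as_unobserved_with_warning(self):
        rec = _record()
        tables = self._tables(global_counts=(rec.variant_id, 0, 0, 0))
        with pytest.warns(UserWarning, match="AN=0"):
            assert apply_rarity_filter([rec], tables, FilterConfig()) == [rec]


class TestImpactFilter:
    @pytest.mark.parametrize(
        "impact,survives",
        [
            (CodingImpact.SYNONYMOUS, False),
            (CodingImpact.OTHER, False),
            (CodingImpact.FRAMESHIFT, True),
            (CodingImpact.START_LOST, True),  # initiation-codon loss class
            (CodingImpact.MISSENSE, True),
        ],
    )
    def test_default_allowed_classes(self, impact, survives):
        out = apply_impact_filter([_record(impact=impact)], FilterConfig())
        assert bool(out) is survives


class TestCascade:
    def test_planted_rare_panel_variants_survive_common_background(self):
        # background sits in panel genes at MAFs above threshold, planted
        # variants below: the cascade must recover exactly the planted set
        config = SimulationConfig(
            seed=2,
            n_background=100,
            background_in_panel=True,
            background_maf_range=(2.5e-3, 0.2),
        )
        bundle = simulate_cohort(config)
        survivors, report = run_cascade(
            bundle.records, bundle.panel, bundle.reference_tables
        )
        planted = {p["variant_id"] for p in bundle.manifest["planted"]}
        assert {r.variant_id for r in survivors} == planted
        assert report.steps[-1].n_out == len(planted)

    def test_empty_cohort_gives_four_zero_steps(self):
        _, report = run_cascade(
            [], PANEL, {"global": ReferenceCountTable("global", 10)}
        )
        assert [s.name for s in report.steps] == ["quality", "panel", "rarity", "impact"]
        assert all((s.n_in, s.n_out) == (0, 0) for s in report.steps)

    def test_disabled_filters_are_identity(self, table1_bundle):
        config = FilterConfig(
            max_global_maf=1.0,
            max_subpop_maf=1.0,
            allowed_impacts=frozenset(CodingImpact),
        )
        survivors, _ = run_cascade(
            table1_bundle.records,
            table1_bundle.panel,
            table1_bundle.reference_tables,
            config,
        )
        assert {r.variant_id for r in survivors} == {
            r.variant_id for r in table1_bundle.records
        }

    def test_pure_steps_commute(self, sim_bundle):
        config = FilterConfig()
        steps = {
            "panel": lambda recs: apply_panel_filter(recs, sim_bundle.panel),
            "rarity": lambda recs: apply_rarity_filter(
                recs, sim_bundle.reference_tables, config
            ),
            "impact": lambda recs: apply_impact_filter(recs, config),
        }
        outcomes = set()
        for order in itertools.permutations(steps):
            records = list(sim_bundle.records)
            for name in order:
                records = steps[name](records)
            outcomes.add(frozenset(r.variant_id for r in records))
        assert len(outcomes) == 1

    def test_raising_maf_threshold_is_monotone(self, sim_bundle):
        sizes = []
        for maf in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            config = FilterConfig(max_global_maf=maf, max_subpop_maf=maf)
            kept = apply_rarity_filter(
                sim_bundle.records, sim_bundle.reference_tables, config
            )
            sizes.append(len(kept))
        assert sizes == sorted(sizes)

    def test_report_removed_sets_are_disjoint(self, sim_bundle):
        _, report = run_cascade(
            sim_bundle.records, sim_bundle.panel, sim_bundle.reference_tables
        )
        removed = [set(s.removed) for s in report.steps]
        for left, right in itertools.combinations(removed, 2):
            assert not left & right
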