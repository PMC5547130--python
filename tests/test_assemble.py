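"""Filtering, master-table assembly, EF-to-variance conversion, conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from plexde.assemble import (
    ExperimentDesign,
    FilterRules,
    apply_filters,
    build_master_table,
    read_designs,
    read_master_table,
    write_designs,
    write_master_table,
)
from plexde.errors import DesignError
from plexde.quantify import rollup_experiment
from plexde.synthetic import generate_cohort

from conftest import analyze_cohort, small_config


class TestApplyFilters:
    def test_decoy_prefix_removed(self):
        retained, removed = apply_filters(["REV_P12345", "P12345"], FilterRules())
        assert retained == ["P12345"]
        assert removed.iloc[0].tolist() == ["REV_P12345", "decoy"]

    def test_mixed_fixture_counts(self):
        rules = FilterRules(
            decoy_prefix="REV_",
            contaminant_accessions=frozenset({"CONTAM1"}),
            depletion_targets=frozenset({"P01857"}),
        )
        accs = ["REV_A", "REV_B", "CONTAM1", "P01857"] + [f"P{i}" for i in range(6)]
        retained, removed = apply_filters(accs, rules)
        assert len(retained) == 6
        assert removed["reason"].value_counts().to_dict() == {
            "decoy": 2, "contaminant": 1, "depletion_target": 1,
        }

    def test_empty_rules_identity(self):
        rules = FilterRules(decoy_prefix="", contaminant_accessions=frozenset(),
                            depletion_targets=frozenset(), manual_exclusions=frozenset())
        accs = [f"P{i}" for i in range(10)]
        retained, removed = apply_filters(accs, rules)
        assert retained == accs
        assert removed.empty

    def test_each_removal_has_one_reason(self):
        rules = FilterRules(manual_exclusions=frozenset({"P99999"}))
        retained, removed = apply_filters(["P99999", "REV_P99998"], rules)
        assert retained == []
        assert sorted(removed["reason"]) == ["decoy", "manual"]

    def test_overlapping_rule_sets_rejected(self):
        with pytest.raises(DesignError):
            FilterRules(contaminant_accessions=frozenset({"P1"}),
                        depletion_targets=frozenset({"P1"}))


def _two_experiment_records(ef_values, ratio=2.0):
    """One protein quantified in two plexes with prescribed error factors."""
    designs = []
    records = {}
    for i, ef in enumerate(ef_values, start=1):
        exp = f"EXP{i}"
        samples = {c: f"S{i}{j}" for j, c in enumerate(["114", "115", "116", "117", "118", "119"])}
        channel_map = {"113": "GIS", **samples, "121": "GIS"}
        group_map = {s: ("survivor" if int(s[-1]) % 2 else "nonsurvivor") for s in samples.values()}
        designs.append(ExperimentDesign(exp, channel_map, ("113", "121"), group_map))
        records[exp] = pd.DataFrame(
            {
                "experiment_id": exp,
                "accession": "P0001",
                "reference_channel": "113",
                "target_channel": list(samples),
                "ratio": ratio,
                "p_value": 0.5,
                "error_factor": ef,
                "n_peptides": 3,
            }
        )
    return designs, records


class TestBuildMasterTable:
    def test_error_factor_to_variance_arithmetic(self):
        designs, records = _two_experiment_records([1.772, 1.772])
        master = build_master_table(records, designs, "low")
        se = math.log10(1.772) / 1.96
        assert se == pytest.approx(0.1267, abs=5e-4)
        assert np.allclose(master.var.to_numpy(float), se**2)
        assert se**2 == pytest.approx(0.01607, abs=5e-5)
        assert np.allclose(master.lfc.to_numpy(float), math.log10(2.0))

    def test_unit_error_factor_hits_variance_floor(self):
        designs, records = _two_experiment_records([1.0, 1.0])
        master = build_master_table(records, designs, "low", variance_floor=1e-6)
        assert np.allclose(master.var.to_numpy(float), 1e-6)

    def test_single_experiment_protein_dropped(self):
        designs, records = _two_experiment_records([1.5, 1.5])
        records["EXP2"] = records["EXP2"].iloc[0:0]
        master = build_master_table(records, designs, "low")
        assert len(master.lfc) == 0
        assert master.dropped["reason"].tolist() == ["insufficient replication"]

    def test_undefined_ef_cells_do_not_count_as_replication(self):
        designs, records = _two_experiment_records([1.5, 1.5])
        records["EXP2"]["error_factor"] = np.nan
        master = build_master_table(records, designs, "low")
        assert len(master.lfc) == 0

    def test_duplicate_sample_across_experiments_rejected(self):
        designs, records = _two_experiment_records([1.5, 1.5])
        dup = dict(designs[1].channel_map)
        dup["114"] = designs[0].channel_map["114"]
        bad = ExperimentDesign(designs[1].experiment_id, dup, ("113", "121"),
                               {**designs[1].group_map,
                                designs[0].channel_map["114"]: "survivor"})
        with pytest.raises(DesignError, match="appears in"):
            build_master_table(records, [designs[0], bad], "low")

    def test_unknown_reference_choice_rejected(self):
        designs, records = _two_experiment_records([1.5, 1.5])
        with pytest.raises(DesignError, match="reference choice"):
            build_master_table(records, designs, "middle")

    def test_conservation_of_protein_counts(self):
        cfg = small_config(detect_prob=0.35, n_proteins=150)
        designs, tables, _ = generate_cohort(cfg)
        records = {
            d.experiment_id: rollup_experiment(t, d.reference_channel("low"))
            for d, t in zip(designs, tables)
        }
        master = build_master_table(records, designs, "low")
        seen = {a for r in records.values() for a in r["accession"].unique()}
        assert len(master.lfc) + len(master.dropped) == len(seen)

    def test_low_high_reference_shift_identity(self):
        # with full peptide coverage, switching GIS reference shifts every cell
        # of an experiment by -log10(ratio of high GIS vs low GIS), protein-wise
        cfg = small_config(n_proteins=40)
        designs, tables, _, records, masters, _ = analyze_cohort(cfg)
        for design, table in zip(designs, tables):
            low = records["low"][design.experiment_id]
            gis_ratio = low[low["target_channel"] == design.gis_channels[1]]
            gis_ratio = gis_ratio.set_index("accession")["ratio"]
            for ch, sample in design.sample_channels().items():
                merged = pd.concat(
                    [
                        masters["low"].lfc[sample].rename("lfc_low"),
                        masters["high"].lfc[sample].rename("lfc_high"),
                    ],
                    axis=1,
                ).dropna()
                shift = np.log10(gis_ratio.reindex(merged.index))
                assert np.allclose(
                    merged["lfc_high"] - merged["lfc_low"], -shift, atol=1e-9
                )


class TestDesignIO:
    def test_design_round_trip(self, tmp_path):
        designs, _, _ = generate_cohort(small_config(n_proteins=5))
        write_designs(designs, tmp_path / "design.tsv")
        back = read_designs(tmp_path / "design.tsv")
        assert [d.experiment_id for d in back] == [d.experiment_id for d in designs]
        for a, b in zip(designs, back):
            assert dict(a.channel_map) == dict(b.channel_map)
            assert a.gis_channels == b.gis_channels
            assert dict(a.group_map) == dict(b.group_map)

    def test_master_table_round_trip(self, tmp_path):
        cfg = small_config(n_proteins=25)
        designs, _, _, _, masters, _ = analyze_cohort(cfg)
        write_master_table(masters["low"], tmp_path / "master.tsv")
        back = read_master_table(tmp_path / "master.tsv", designs, "low")
        pd.testing.assert_frame_equal(masters["low"].lfc, back.lfc, check_names=False)
        pd.testing.assert_frame_equal(masters["low"].var, back.var, check_names=False)
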