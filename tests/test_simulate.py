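"""The synthetic-data generator: geometry, determinism, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from promtarget import (
    Motif,
    SimulationConfig,
    assign_genes_all,
    generate_array_design,
    generate_chip_signal,
    generate_expression,
    generate_promoters,
    plant_motifs,
    profile_expression,
    sample_truth,
    scan_motifs,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_seq_ids": 0},
            {"bound_fraction": 1.2},
            {"de_fraction": -0.1},
            {"probes_per_id": (4, 35)},   # below the 5-probe window
            {"probes_per_id": (10, 8)},   # empty range
            {"spike_probes": (3, 4)},
            {"n_wt": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_impossible_geometry_has_explanatory_message(self):
        with pytest.raises(ValueError, match="impossible geometry"):
            SimulationConfig(probes_per_id=(5, 50))  # 49*100+74 bp > 4500 bp


class TestArrayDesign:
    def test_config_echo(self):
        cfg = SimulationConfig(seed=1, n_seq_ids=100)
        design, annotation = generate_array_design(cfg)
        sizes = design.probes.groupby("seq_id").size()
        assert len(sizes) == 100
        assert (sizes >= 5).all() and (sizes <= 35).all()
        lengths = design.probes["end"] - design.probes["start"]
        assert lengths.between(49, 74).all()

    def test_probes_fit_promoter_span_with_valid_spacing(self):
        cfg = SimulationConfig(seed=3, n_seq_ids=80)
        design, _ = generate_array_design(cfg)
        for _, grp in design.probes.groupby("seq_id"):
            span = grp["end"].max() - grp["start"].min()
            assert span <= 4500
            spacing = np.diff(np.sort(grp["start"].to_numpy()))
            assert (spacing >= 100).all()

    def test_determinism_and_seed_sensitivity(self):
        cfg = SimulationConfig(seed=7, n_seq_ids=40)
        d1, a1 = generate_array_design(cfg)
        d2, a2 = generate_array_design(cfg)
        pd.testing.assert_frame_equal(d1.probes, d2.probes)
        pd.testing.assert_frame_equal(a1, a2)
        d3, _ = generate_array_design(SimulationConfig(seed=8, n_seq_ids=40))
        assert not d1.probes.equals(d3.probes)

    def test_intergenic_fraction_realised(self):
        cfg = SimulationConfig(seed=0, n_seq_ids=1000, intergenic_fraction=0.03)
        design, annotation = generate_array_design(cfg)
        assignment = assign_genes_all(design, annotation)
        # ids without any gene within 10 kb: exactly the configured 3%
        assert int(assignment["intergenic"].sum()) == 30

    def test_each_genic_id_is_within_flank_of_its_gene(self):
        cfg = SimulationConfig(seed=2, n_seq_ids=60)
        design, annotation = generate_array_design(cfg)
        assignment = assign_genes_all(design, annotation)
        genic = design.probes[design.probes["gene_symbol"] != ""]
        for seq_id, grp in genic.groupby("seq_id"):
            row = assignment.loc[assignment["seq_id"] == seq_id].iloc[0]
            assert grp["gene_symbol"].iloc[0] in row["genes"].split(";")


class TestChipSignal:
    def test_null_model_centers_on_zero(self):
        cfg = SimulationConfig(seed=0, n_seq_ids=1000, bound_fraction=0.0)
        design, ann = generate_array_design(cfg)
        truth = sample_truth(design, ann, cfg)
        signal = generate_chip_signal(design, truth, cfg)
        values = signal.to_numpy()
        id_means = (
            pd.DataFrame({"v": values.mean(axis=1)}, index=signal.index)
            .join(design.probes.set_index("probe_id")["seq_id"])
            .groupby("seq_id")["v"]
            .mean()
        )
        n_per_id = design.probes.groupby("seq_id").size() * cfg.n_replicates_chip
        bound = 4 * cfg.noise_sd_chip / np.sqrt(n_per_id.loc[id_means.index])
        assert (id_means.abs() < bound).all()

    def test_spiked_window_mean_matches_effect(self):
        """Law of large numbers over thousands of spiked probe draws."""
        cfg = SimulationConfig(
            seed=0, n_seq_ids=400, bound_fraction=1.0, chip_effect=1.0,
            noise_sd_chip=0.25,
        )
        design, ann = generate_array_design(cfg)
        truth = sample_truth(design, ann, cfg)
        signal = generate_chip_signal(design, truth, cfg)
        first = design.probes.reset_index().groupby("seq_id")["index"].min()
        spiked_rows = np.concatenate(
            [
                np.arange(first[r.seq_id] + r.spike_start,
                          first[r.seq_id] + r.spike_start + r.spike_len)
                for r in truth.bound.itertuples()
            ]
        )
        draws = signal.to_numpy()[spiked_rows].ravel()
        assert len(draws) >= 1000
        assert abs(draws.mean() - 1.0) < 4 * 0.25 / np.sqrt(len(draws))

    def test_determinism(self, small_dataset):
        cfg = small_dataset["config"]
        again = generate_chip_signal(
            small_dataset["design"], small_dataset["truth"], cfg
        )
        pd.testing.assert_frame_equal(small_dataset["signal"], again)

    def test_unknown_truth_ids_rejected(self, small_dataset):
        truth = small_dataset["truth"]
        bad = truth.bound.copy()
        bad.loc[0, "seq_id"] = "SEQ99999"
        truth2 = type(truth)(bound=bad, de=truth.de)
        with pytest.raises(ValueError, match="unknown sequence IDs"):
            generate_chip_signal(small_dataset["design"], truth2, small_dataset["config"])

    def test_short_spike_rejected(self, small_dataset):
        truth = small_dataset["truth"]
        bad = truth.bound.copy()
        bad.loc[0, "spike_len"] = 3
        truth2 = type(truth)(bound=bad, de=truth.de)
        with pytest.raises(ValueError, match="spiked spans"):
            generate_chip_signal(small_dataset["design"], truth2, small_dataset["config"])


class TestExpression:
    def test_emulated_effect_magnitude_recovered(self):
        cfg = SimulationConfig(
            seed=0, n_seq_ids=50, de_fraction=1.0, expr_effect=1.3139,
            noise_sd_expr=0.05, probe_sets_per_gene=(1, 1),
        )
        design, ann = generate_array_design(cfg)
        truth = sample_truth(design, ann, cfg)
        em = generate_expression(ann, truth, cfg)
        wt = em.values[em.group_columns("WT")].mean(axis=1)
        ko = em.values[em.group_columns("KO")].mean(axis=1)
        diffs = (wt - ko).groupby(em.probe_map).mean()
        for gene, eff in truth.de_genes.items():
            assert abs(diffs[gene] - eff) < 0.1

    def test_probe_sets_of_a_gene_share_effect_sign(self, small_dataset):
        em = small_dataset["matrix"]
        truth = small_dataset["truth"]
        wt = em.values[em.group_columns("WT")].mean(axis=1)
        ko = em.values[em.group_columns("KO")].mean(axis=1)
        diffs = wt - ko
        for gene, eff in truth.de_genes.items():
            sets = em.probe_map[em.probe_map == gene].index
            signs = set(np.sign(diffs[sets]).astype(int))
            assert signs == {int(np.sign(eff))}

    def test_ambiguous_injection_removed_downstream(self):
        cfg = SimulationConfig(
            seed=0, n_seq_ids=60, n_ambiguous=2, probe_sets_per_gene=(2, 3),
            noise_sd_expr=0.1,
        )
        design, ann = generate_array_design(cfg)
        truth = sample_truth(design, ann, cfg)
        em = generate_expression(ann, truth, cfg)
        assert len(truth.ambiguous) == 2
        result = profile_expression(em)
        for gene in truth.ambiguous:
            assert gene in result.removed_genes

    def test_too_few_replicates_rejected(self, small_dataset):
        cfg = small_dataset["config"].with_(n_ko=1)
        with pytest.raises(ValueError, match=">= 2"):
            generate_expression(
                small_dataset["annotation"], small_dataset["truth"], cfg
            )


class TestPromoters:
    def test_planted_motifs_recovered_at_exact_positions(self):
        cfg = SimulationConfig(
            seed=0, n_seq_ids=10,
            motif_plants=(("EKLF", -200), ("GATA", -150)),
        )
        design, ann = generate_array_design(cfg)
        truth = sample_truth(design, ann, cfg)
        promoters = generate_promoters(design, truth, cfg)
        assert set(truth.planted["seq_id"]) == set(promoters)
        for seq_id, (seq, tss) in promoters.items():
            hits = scan_motifs(seq, [Motif("EKLF", "CACCC")], tss_index=tss)
            assert -200 in set(hits["position"])

    def test_nearest_plant_layout_is_deterministic(self):
        cfg = SimulationConfig(seed=5, n_seq_ids=8)
        design, ann = generate_array_design(cfg)
        truth = sample_truth(design, ann, cfg)
        p1 = generate_promoters(design, truth, cfg)
        p2 = generate_promoters(design, truth, cfg)
        assert p1 == p2

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            plant_motifs("A" * 100, 90, [("CACCC", -50), ("CCAAT", -48)])

    def test_out_of_span_plant_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            plant_motifs("A" * 100, 90, [("CACCC", -95)])
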