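import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lncforge.diffexpr import run_de
from lncforge.network import build_network
from lncforge.simulate import (GroundTruth, SimulationConfig,
                               generate_clinical, generate_ct,
                               generate_expression, generate_gene_sets,
                               probe_annotation, write_bundle)
from lncforge.clinical import ddct, logrank
from lncforge.enrichment import fisher_enrichment


class TestConfigValidation:
    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_per_group=1)

    def test_rejects_too_many_planted(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_de_planted=500, n_mrna_probes=100)

    def test_rejects_negative_hazard(self):
        with pytest.raises(ValueError):
            SimulationConfig(survival_rate_g1=-1.0)

    def test_rejects_unknown_class(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_counts={"weird": 3})


class TestDeterminism:
    def test_identical_seed_identical_bundle(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_bundle(SimulationConfig(seed=123), a)
        write_bundle(SimulationConfig(seed=123), b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_differs(self, tmp_path):
        m1, _ = generate_expression(SimulationConfig(seed=1))
        m2, _ = generate_expression(SimulationConfig(seed=2))
        assert not np.allclose(m1.values.to_numpy(), m2.values.to_numpy())


class TestGroundTruthResolvable:
    def test_every_truth_id_exists_in_inputs(self, bundle):
        gt = bundle["truth"]
        d = bundle["dir"]
        expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col="probe_id")
        assert gt.de_probe_ids <= set(expr.index)
        for l, r in gt.coexpr_pairs:
            assert l in expr.index and r in expr.index
        bed = pd.read_csv(d / "lnc_loci.bed", sep="\t", header=None)
        assert set(gt.class_of) == set(bed[3])
        gmt_ids = {line.split("\t")[0] for line in
                   (d / "gene_sets.gmt").read_text().splitlines()}
        assert gt.enriched_pathways <= gmt_ids

    def test_ground_truth_json_round_trip(self, bundle):
        gt = bundle["truth"]
        back = GroundTruth.from_json(bundle["dir"] / "ground_truth.json")
        assert back.de_probe_ids == gt.de_probe_ids
        assert back.coexpr_pairs == gt.coexpr_pairs
        assert back.class_of == gt.class_of


class TestPlantedExpression:
    def test_no_signal_no_de_calls(self):
        config = SimulationConfig(seed=21, planted_log2fc=0.0, n_coexpr_pairs=0)
        m, _ = generate_expression(config)
        de = run_de(m, probe_annotation(config))
        assert int(de["significant"].sum()) == 0

    def test_zero_noise_pairs_perfect_correlation(self):
        config = SimulationConfig(seed=22, coexpr_noise_sd=0.0)
        m, gt = generate_expression(config)
        for l, r in gt.coexpr_pairs:
            rr = np.corrcoef(m.values.loc[l], m.values.loc[r])[0, 1]
            assert abs(rr) == pytest.approx(1.0, abs=1e-12)

    def test_calibrated_noise_recovers_planted_pairs(self):
        # closed form r = b*sx / sqrt(b^2 sx^2 + se^2); with b=1,
        # sx^2 = noise_sd^2 + planted_log2fc^2/4 = 2.5, se = 0.05 -> r ~ 0.9995
        config = SimulationConfig(seed=1, n_coexpr_pairs=20, coexpr_noise_sd=0.05)
        sx2 = config.noise_sd**2 + config.planted_log2fc**2 / 4
        r_theory = np.sqrt(sx2) / np.sqrt(sx2 + config.coexpr_noise_sd**2)
        assert r_theory == pytest.approx(0.9995, abs=2e-4)
        m, gt = generate_expression(config)
        lncs = sorted({l for l, _ in gt.coexpr_pairs})
        mrnas = sorted({r for _, r in gt.coexpr_pairs})
        edges = build_network(m, lncs, mrnas, threshold=0.998)
        got = set(zip(edges["lnc_id"], edges["mrna_id"]))
        assert len(got & gt.coexpr_pairs) >= 18

    def test_flag_fail_probes_fail_filter(self, bundle):
        from lncforge.matrix import ExpressionMatrix
        from lncforge.preprocess import filter_by_flags
        d = bundle["dir"]
        m = ExpressionMatrix.from_tsv(d / "expression.tsv", d / "samples.tsv",
                                      d / "flags.tsv")
        kept = set(filter_by_flags(m).probe_ids)
        gt = bundle["truth"]
        dropped = set(m.probe_ids) - kept
        # most designed-to-fail probes are dropped; planted probes all kept
        assert len(gt.flag_fail_probe_ids & dropped) >= \
            0.8 * len(gt.flag_fail_probe_ids)
        assert gt.de_probe_ids <= kept


class TestGeneSets:
    def test_planted_set_has_minimum_p(self):
        config = SimulationConfig(seed=30)
        sets, gt = generate_gene_sets(config)
        universe = set(config.mrna_symbols())
        de_genes = set(config.mrna_symbols()[: config.n_de_planted])
        ps = {s.set_id: fisher_enrichment(de_genes, s, universe)["p"]
              for s in sets}
        assert min(ps, key=ps.get) in gt.enriched_pathways


class TestClinicalGenerator:
    def test_null_logrank_p_median_near_half(self):
        ps = []
        for seed in range(200):
            config = SimulationConfig(seed=seed, survival_rate_g1=0.01,
                                      survival_rate_g2=0.01)
            rec = generate_clinical(config)
            if rec["event"].sum() == 0:
                continue
            _, p = logrank(rec)
            ps.append(p)
        assert 0.35 <= float(np.median(ps)) <= 0.65

    def test_times_positive_and_censoring_respected(self):
        rec = generate_clinical(SimulationConfig(seed=5, censor_time=50.0))
        assert (rec["time"] > 0).all()
        assert (rec["time"] <= 50.0).all()
        assert set(rec.loc[rec["time"] == 50.0, "event"]) <= {0}


class TestCtGenerator:
    def test_null_ddct_near_unity(self):
        means = []
        for seed in range(100):
            config = SimulationConfig(seed=seed, ct_ddct={"EGF": 0.0,
                                                          "ABCC6P1": 0.0})
            out = ddct(generate_ct(config), reference_group="group1")
            g2 = out[(out["group"] == "group2") & (out["target_gene"] == "EGF")]
            means.append(g2["rel_expr"].mean())
        assert 0.8 <= float(np.mean(means)) <= 1.25

    def test_planted_shift_recovered(self):
        config = SimulationConfig(seed=9)     # EGF ddCt -2 -> rel expr ~ 4
        out = ddct(generate_ct(config), reference_group="group1")
        g2 = out[(out["group"] == "group2") & (out["target_gene"] == "EGF")]
        assert g2["rel_expr"].mean() == pytest.approx(4.0, rel=0.25)
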