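"""Tests for the seeded synthetic multi-tissue epigenome generator."""

import numpy as np
import pandas as pd
import pytest

from regmap import hmm, synthetic
from regmap.errors import ConfigurationError, GenerationError
from regmap.synthetic import (
    ENHA_TRUE_STATE,
    TSSA_TRUE_STATE,
    UTERINE_TISSUES,
    SyntheticConfig,
)


def small_config(**kw):
    defaults = dict(
        seed=0, n_chromosomes=1, chrom_length_bp=400_000, n_genes=30,
        n_tads=8, planted_specific_enhancers_per_tissue=3,
        uterine_common_enhancers=2,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfig:
    def test_rejects_nonpositive_and_inconsistent_values(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_genes=0).validate()
        with pytest.raises(ConfigurationError):
            SyntheticConfig(chrom_length_bp=1001).validate()
        with pytest.raises(ConfigurationError):
            SyntheticConfig(background_rate=2.0, enriched_rate=1.0).validate()
        with pytest.raises(ConfigurationError):
            SyntheticConfig(
                tissues=("ovary", "oviduct"), uterine_common_enhancers=1
            ).validate()


class TestSimulateGenome:
    def test_tads_tile_chromosome(self):
        cfg = small_config(n_tads=10, chrom_length_bp=1_000_000)
        _, _, tads = synthetic.simulate_genome(cfg)
        assert len(tads) == 10
        assert tads.iloc[0]["Start"] == 0
        assert tads.iloc[-1]["End"] == 1_000_000
        assert (tads["Start"].to_numpy()[1:] == tads["End"].to_numpy()[:-1]).all()

    def test_same_seed_identical(self):
        cfg = small_config(seed=9)
        g1 = synthetic.simulate_genome(cfg)
        g2 = synthetic.simulate_genome(cfg)
        pd.testing.assert_frame_equal(g1[1], g2[1])
        pd.testing.assert_frame_equal(g1[2], g2[2])

    def test_gene_count_and_tss_bounds(self):
        cfg = small_config(n_genes=50)
        _, genes, _ = synthetic.simulate_genome(cfg)
        assert len(genes) == 50
        tss = synthetic.gene_tss(genes)
        assert ((tss["TSS"] >= 0) & (tss["TSS"] < cfg.chrom_length_bp)).all()

    def test_tss_strand_convention(self):
        genes = pd.DataFrame(
            {"Chromosome": ["chr1", "chr1"], "Start": [100, 100], "End": [200, 200],
             "Name": ["a", "b"], "Score": [0, 0], "Strand": ["+", "-"]}
        )
        tss = synthetic.gene_tss(genes)
        assert tss["TSS"].tolist() == [100, 199]


class TestStatePaths:
    def test_planted_block_overwrites_designated_tissue_only(self):
        cfg = small_config()
        genome, genes, tads = synthetic.simulate_genome(cfg)
        model = synthetic.default_true_model(cfg)
        gt = synthetic.simulate_state_paths(model, genome, cfg, genes, tads)
        bs = cfg.bin_size_bp
        for row in gt.planted_enhancers.itertuples(index=False):
            b0, b1 = row.Start // bs, row.End // bs
            expected = (
                set(UTERINE_TISSUES) if row.Module == "uterine_common"
                else {row.Module.removesuffix("_specific")}
            )
            for tissue in cfg.tissues:
                segment = gt.state_paths[tissue][row.Chromosome][b0:b1]
                if tissue in expected:
                    assert (segment == ENHA_TRUE_STATE).all()
                else:
                    assert not (segment == ENHA_TRUE_STATE).any()

    def test_each_planted_block_inside_exactly_one_tad(self):
        cfg = small_config()
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        for row in gt.planted_enhancers.itertuples(index=False):
            hosts = tads[
                (tads["Chromosome"] == row.Chromosome)
                & (tads["Start"] <= row.Start) & (tads["End"] >= row.End)
            ]
            assert len(hosts) == 1

    def test_path_lengths_and_module_bookkeeping(self):
        cfg = small_config()
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        nb = cfg.chrom_length_bp // cfg.bin_size_bp
        for tissue in cfg.tissues:
            assert gt.state_paths[tissue]["chr1"].size == nb
        counts = gt.planted_enhancers["Module"].value_counts()
        for t in cfg.tissues:
            assert counts[f"{t}_specific"] == 3
        assert counts["uterine_common"] == 2

    def test_identity_chain_is_absorbing(self):
        cfg = small_config(promoter_at_tss=False,
                           planted_specific_enhancers_per_tissue=0,
                           uterine_common_enhancers=0)
        genome, genes, tads = synthetic.simulate_genome(cfg)
        model = hmm.StateModel(
            [1, 0, 0, 0, 0], np.eye(5),
            synthetic.default_true_model(cfg).emissionprob, list(cfg.marks),
        )
        gt = synthetic.simulate_state_paths(model, genome, cfg, genes, tads)
        assert not gt.state_paths["ovary"]["chr1"].any()

    def test_empirical_transitions_match_chain(self):
        cfg = SyntheticConfig(
            seed=3, n_chromosomes=1, chrom_length_bp=20_000_000, n_genes=10,
            n_tads=10, planted_specific_enhancers_per_tissue=0,
            uterine_common_enhancers=0, promoter_at_tss=False,
            tissues=("ovary",),
        )
        genome, genes, tads = synthetic.simulate_genome(cfg)
        model = synthetic.default_true_model(cfg)
        gt = synthetic.simulate_state_paths(model, genome, cfg, genes, tads)
        path = gt.state_paths["ovary"]["chr1"]          # 1e5 bins
        A = model.transmat
        for i in range(model.n_states):
            sel = path[:-1] == i
            n = int(sel.sum())
            if n < 100:
                continue
            for j in range(model.n_states):
                freq = (path[1:][sel] == j).mean()
                se = np.sqrt(max(A[i, j] * (1 - A[i, j]), 1e-12) / n)
                assert abs(freq - A[i, j]) <= 3 * se + 1e-9

    def test_overfull_planting_raises(self):
        cfg = small_config(planted_specific_enhancers_per_tissue=200)
        genome, genes, tads = synthetic.simulate_genome(cfg)
        with pytest.raises(GenerationError):
            synthetic.simulate_state_paths(
                synthetic.default_true_model(cfg), genome, cfg, genes, tads
            )


class TestMarkCounts:
    def test_zero_emission_mark_is_pure_background(self):
        cfg = SyntheticConfig(
            seed=1, n_chromosomes=1, chrom_length_bp=20_000_000,
            tissues=("ovary",), n_replicates=1, n_genes=10, n_tads=10,
            planted_specific_enhancers_per_tissue=0, uterine_common_enhancers=0,
            promoter_at_tss=False,
        )
        genome, genes, tads = synthetic.simulate_genome(cfg)
        model = synthetic.default_true_model(cfg)
        model.emissionprob = np.zeros_like(model.emissionprob)
        gt = synthetic.simulate_state_paths(model, genome, cfg, genes, tads)
        tracks = synthetic.simulate_mark_counts(gt, cfg)
        counts = tracks[0].values                      # 1e5 bins
        se = np.sqrt(cfg.background_rate / counts.size)
        assert abs(counts.mean() - cfg.background_rate) <= 3 * se

    def test_mixture_marginal_mean(self):
        # lambda-bar = p*enriched + (1-p)*background per mark
        cfg = SyntheticConfig(
            seed=2, n_chromosomes=1, chrom_length_bp=20_000_000,
            tissues=("ovary",), n_replicates=1, n_genes=10, n_tads=10,
            planted_specific_enhancers_per_tissue=0, uterine_common_enhancers=0,
            promoter_at_tss=False,
        )
        genome, genes, tads = synthetic.simulate_genome(cfg)
        model = synthetic.default_true_model(cfg)
        gt = synthetic.simulate_state_paths(model, genome, cfg, genes, tads)
        tracks = synthetic.simulate_mark_counts(gt, cfg)
        path = gt.state_paths["ovary"]["chr1"]
        for m, mark in enumerate(cfg.marks):
            tr = next(t for t in tracks if t.mark == mark)
            p = model.emissionprob[path, m].mean()
            lam_bar = p * cfg.enriched_rate + (1 - p) * cfg.background_rate
            var = lam_bar + p * (1 - p) * (cfg.enriched_rate - cfg.background_rate) ** 2
            se = np.sqrt(var / path.size)
            assert abs(tr.values.mean() - lam_bar) <= 3 * se

    def test_empty_paths_give_empty_tracks(self):
        cfg = small_config()
        model = synthetic.default_true_model(cfg)
        gt = synthetic.GroundTruth(
            model, {t: {"chr1": np.zeros(0, dtype=int)} for t in cfg.tissues},
            pd.DataFrame(columns=["Chromosome", "Start", "End", "Module", "TargetGene"]),
        )
        tracks = synthetic.simulate_mark_counts(gt, cfg)
        assert all(t.values.size == 0 for t in tracks)

    def test_deterministic_given_seed(self):
        cfg = small_config()
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        t1 = synthetic.simulate_mark_counts(gt, cfg)
        t2 = synthetic.simulate_mark_counts(gt, cfg)
        assert all(np.array_equal(a.values, b.values) for a, b in zip(t1, t2))


class TestExpression:
    def test_noiseless_fold_exact(self):
        cfg = small_config(expression_noise_sd=0.0, expression_fold=8.0)
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        expr = synthetic.simulate_expression(genes, gt, cfg)
        row = gt.planted_enhancers[gt.planted_enhancers["Module"] == "ovary_specific"].iloc[0]
        assert expr.loc[row["TargetGene"], "ovary"] == pytest.approx(
            8.0 * cfg.expression_baseline
        )

    def test_no_planting_all_baseline(self):
        cfg = small_config(planted_specific_enhancers_per_tissue=0,
                           uterine_common_enhancers=0, expression_noise_sd=0.0)
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        expr = synthetic.simulate_expression(genes, gt, cfg)
        assert np.allclose(expr.to_numpy(), cfg.expression_baseline)

    def test_target_ranks_first_in_its_tissue(self):
        hits = trials = 0
        for seed in range(20):
            cfg = small_config(seed=seed, expression_noise_sd=0.2)
            genome, genes, tads = synthetic.simulate_genome(cfg)
            gt = synthetic.simulate_state_paths(
                synthetic.default_true_model(cfg), genome, cfg, genes, tads
            )
            expr = synthetic.simulate_expression(genes, gt, cfg)
            specific = gt.planted_enhancers[
                gt.planted_enhancers["Module"] != "uterine_common"
            ]
            for row in specific.itertuples(index=False):
                tissue = row.Module.removesuffix("_specific")
                trials += 1
                hits += expr.loc[row.TargetGene].idxmax() == tissue
        assert hits / trials >= 0.95

    def test_unknown_target_gene_raises(self):
        cfg = small_config()
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        gt.planted_enhancers.loc[0, "TargetGene"] = "nope"
        with pytest.raises(GenerationError):
            synthetic.simulate_expression(genes, gt, cfg)


class TestSequences:
    def _regions(self, n, length=1000):
        return pd.DataFrame(
            {"Chromosome": "chr1", "Start": np.arange(n) * length,
             "End": (np.arange(n) + 1) * length}
        )

    def test_plant_fraction_one_contains_consensus(self):
        from regmap.enrichment import sharp_pwm
        from Bio.Seq import Seq

        cfg = small_config()
        pwm = sharp_pwm("m", "TGACTCAT")
        recs, planted = synthetic.simulate_sequences_with_motifs(
            self._regions(30), pwm, 1.0, cfg
        )
        assert planted.size == 30
        rc = str(Seq("TGACTCAT").reverse_complement())
        assert all("TGACTCAT" in str(r.seq) or rc in str(r.seq) for r in recs)

    def test_background_consensus_rate_matches_closed_form(self):
        from regmap.enrichment import sharp_pwm, scan_pwm

        cfg = small_config(seed=5)
        w = 8
        pwm = sharp_pwm("m", "TGACTCAT")
        n, L = 3000, 1000
        recs, planted = synthetic.simulate_sequences_with_motifs(
            self._regions(n, L), pwm, 0.0, cfg
        )
        assert planted.size == 0
        total = sum(len(scan_pwm(str(r.seq), pwm, score_fraction=1.0)) for r in recs)
        expect = n * (L - w + 1) * 2 * 0.25**w
        se = np.sqrt(expect)                     # ~Poisson for rare hits
        assert abs(total - expect) <= 3 * se

    def test_region_shorter_than_motif_raises(self):
        from regmap.enrichment import sharp_pwm

        cfg = small_config()
        with pytest.raises(GenerationError):
            synthetic.simulate_sequences_with_motifs(
                pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [4]}),
                sharp_pwm("m", "TGACTCAT"), 0.0, cfg,
            )

    def test_same_seed_identical_fasta(self):
        from regmap.enrichment import sharp_pwm

        cfg = small_config(seed=8)
        pwm = sharp_pwm("m", "TGACTCAT")
        r1, _ = synthetic.simulate_sequences_with_motifs(self._regions(5), pwm, 0.5, cfg)
        r2, _ = synthetic.simulate_sequences_with_motifs(self._regions(5), pwm, 0.5, cfg)
        assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]
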