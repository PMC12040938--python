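"""Tests for the RRAT matrix, module classification, and TAD linking."""

import numpy as np
import pandas as pd
import pytest

from regmap import tsr
from regmap.errors import ConfigurationError, InputError

TISSUES = ["ovary", "oviduct", "cervix", "cornua_uteri", "corpus_uteri"]
UTERINE = {"cervix", "cornua_uteri", "corpus_uteri"}


def iv(rows):
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def empty():
    return iv([])


class TestBuildRrat:
    def test_overlap_union_merge(self):
        enh = {t: empty() for t in TISSUES}
        enh["ovary"] = iv([("chr1", 0, 200)])
        enh["oviduct"] = iv([("chr1", 100, 300)])
        rrat = tsr.build_rrat(enh)
        assert rrat.regions[["Start", "End"]].values.tolist() == [[0, 300]]
        assert rrat.matrix.tolist() == [[1, 1, 0, 0, 0]]

    def test_single_tissue_single_region(self):
        enh = {t: empty() for t in TISSUES}
        enh["cervix"] = iv([("chr2", 1000, 1400)])
        rrat = tsr.build_rrat(enh)
        assert rrat.n_regions == 1
        assert rrat.matrix.sum() == 1
        assert rrat.matrix[0][rrat.tissues.index("cervix")] == 1

    def test_random_sets_consistent_with_brute_force(self):
        rng = np.random.default_rng(0)
        enh = {}
        for t in TISSUES:
            starts = np.sort(rng.choice(10_000, size=60, replace=False)) * 10
            enh[t] = iv([("chr1", int(s), int(s + rng.integers(10, 400)))
                         for s in starts])
        rrat = tsr.build_rrat(enh)
        regions = rrat.regions
        # every input interval overlaps exactly one region
        for t in TISSUES:
            for _, r in enh[t].iterrows():
                hit = regions[(regions["Start"] < r["End"]) & (regions["End"] > r["Start"])]
                assert len(hit) == 1
        # matrix agrees with a brute-force overlap scan
        for j, t in enumerate(rrat.tissues):
            for i, reg in regions.iterrows():
                brute = (
                    (enh[t]["Start"] < reg["End"]) & (enh[t]["End"] > reg["Start"])
                ).any()
                assert bool(rrat.matrix[i, j]) == bool(brute)
        # no all-zero rows
        assert (rrat.matrix.sum(axis=1) > 0).all()

    def test_no_tissues_raises(self):
        with pytest.raises(ConfigurationError):
            tsr.build_rrat({})

    def test_malformed_interval_raises(self):
        enh = {t: empty() for t in TISSUES}
        enh["ovary"] = iv([("chr1", 200, 200)])
        with pytest.raises(InputError):
            tsr.build_rrat(enh)


def rrat_from_matrix(mat):
    n = len(mat)
    regions = iv([("chr1", i * 1000, i * 1000 + 500) for i in range(n)])
    return tsr.RRATMatrix(regions, list(TISSUES), np.asarray(mat))


class TestClassifyModules:
    def test_named_patterns(self):
        rrat = rrat_from_matrix([
            [1, 0, 0, 0, 0],          # ovary only
            [0, 0, 1, 1, 1],          # exactly the three uterine
            [1, 1, 1, 1, 1],          # everything -> unassigned
            [0, 1, 0, 0, 0],          # oviduct only
            [1, 0, 1, 1, 1],          # uterine + ovary -> unassigned
            [0, 0, 1, 1, 0],          # two of three uterine -> unassigned
        ])
        out = tsr.classify_modules(rrat, UTERINE)
        assert out["Module"].tolist() == [
            "ovary_specific", "uterine_common", "unassigned",
            "oviduct_specific", "unassigned", "unassigned",
        ]

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        mat = (rng.random((200, 5)) < 0.4).astype(int)
        mat = mat[mat.sum(axis=1) > 0]
        rrat = rrat_from_matrix(mat.tolist())
        out = tsr.classify_modules(rrat, UTERINE)
        assert len(out) == len(mat)
        counts = out["Module"].value_counts()
        assert counts.sum() == len(mat)
        names = set(tsr.module_names(TISSUES))
        assert set(counts.index) <= names

    def test_invariant_to_tissue_column_order(self):
        rng = np.random.default_rng(2)
        mat = (rng.random((50, 5)) < 0.5).astype(int)
        mat = mat[mat.sum(axis=1) > 0]
        rrat = rrat_from_matrix(mat.tolist())
        out1 = tsr.classify_modules(rrat, UTERINE)
        perm = [3, 0, 4, 1, 2]
        rrat2 = tsr.RRATMatrix(
            rrat.regions, [TISSUES[i] for i in perm], rrat.matrix[:, perm]
        )
        out2 = tsr.classify_modules(rrat2, UTERINE)
        assert out1["Module"].tolist() == out2["Module"].tolist()

    def test_unknown_uterine_name_raises(self):
        rrat = rrat_from_matrix([[1, 0, 0, 0, 0]])
        with pytest.raises(ConfigurationError):
            tsr.classify_modules(rrat, {"cervix", "cornua_uteri", "spleen"})


class TestLinkTargets:
    def tads(self):
        return iv([("chr1", 0, 100_000), ("chr1", 100_000, 200_000)])

    def genes(self, rows):
        return pd.DataFrame(
            [(c, s, e, n, 0, st) for c, s, e, n, st in rows],
            columns=["Chromosome", "Start", "End", "Name", "Score", "Strand"],
        )

    def modules(self, rows):
        df = iv([(c, s, e) for c, s, e, _ in rows])
        df["Module"] = [m for *_, m in rows]
        return df

    def test_same_tad_links_gene(self):
        mods = self.modules([("chr1", 49_000, 51_000, "ovary_specific")])
        genes = self.genes([("chr1", 60_000, 65_000, "g1", "+")])
        out = tsr.link_targets(mods, self.tads(), genes)
        assert out.iloc[0]["TargetGenes"] == ["g1"]
        assert bool(out.iloc[0]["InTad"])

    def test_different_tad_not_linked(self):
        mods = self.modules([("chr1", 49_000, 51_000, "ovary_specific")])
        genes = self.genes([("chr1", 150_000, 155_000, "g2", "+")])
        out = tsr.link_targets(mods, self.tads(), genes)
        assert out.iloc[0]["TargetGenes"] == []

    def test_region_outside_tads_flagged(self):
        mods = self.modules([("chr1", 250_000, 252_000, "ovary_specific")])
        out = tsr.link_targets(mods, self.tads(), self.genes([]))
        assert not bool(out.iloc[0]["InTad"])
        assert out.iloc[0]["TargetGenes"] == []

    def test_midpoint_decides_straddling_region(self):
        mods = self.modules([("chr1", 95_000, 103_000, "ovary_specific")])
        genes = self.genes([("chr1", 50_000, 55_000, "gA", "+"),
                            ("chr1", 150_000, 155_000, "gB", "+")])
        out = tsr.link_targets(mods, self.tads(), genes)
        # midpoint 99,000 -> first TAD
        assert out.iloc[0]["TargetGenes"] == ["gA"]

    def test_overlapping_tads_raise_listing_pair(self):
        bad = iv([("chr1", 0, 120_000), ("chr1", 100_000, 200_000)])
        mods = self.modules([("chr1", 10, 20, "ovary_specific")])
        with pytest.raises(InputError, match="overlapping TADs"):
            tsr.link_targets(mods, bad, self.genes([]))

    def test_planted_pairs_recovered_on_synthetic_truth(self):
        from regmap import synthetic

        cfg = synthetic.SyntheticConfig(seed=4)
        genome, genes, tads = synthetic.simulate_genome(cfg)
        gt = synthetic.simulate_state_paths(
            synthetic.default_true_model(cfg), genome, cfg, genes, tads
        )
        planted = gt.planted_enhancers.copy()
        planted = planted.rename(columns={"Module": "Module"})
        out = tsr.link_targets(
            planted[["Chromosome", "Start", "End", "Module"]], tads, genes
        )
        tss = synthetic.gene_tss(genes).set_index("Name")
        recovered = 0
        for (_, link), (_, truth) in zip(out.iterrows(), planted.iterrows()):
            assert truth["TargetGene"] in link["TargetGenes"]
            recovered += 1
            # no cross-TAD links: every linked gene's TSS shares the TAD
            mid = (link["Start"] + link["End"]) // 2
            tad = tads[(tads["Chromosome"] == link["Chromosome"])
                       & (tads["Start"] <= mid) & (tads["End"] > mid)].iloc[0]
            for g in link["TargetGenes"]:
                t = tss.loc[g]
                assert t["Chromosome"] == link["Chromosome"]
                assert tad["Start"] <= t["TSS"] < tad["End"]
        assert recovered == len(planted)


class TestModuleReport:
    def test_counts_and_empty_modules(self):
        linked = pd.DataFrame(
            {
                "Chromosome": ["chr1"] * 8,
                "Start": np.arange(8) * 1000,
                "End": np.arange(8) * 1000 + 500,
                "Module": ["ovary_specific"] * 5 + ["oviduct_specific"] * 3,
                "TargetGenes": [[] for _ in range(8)],
            }
        )
        rep = tsr.module_report(linked, None, TISSUES, UTERINE)
        c = rep["module_counts"]
        assert c["ovary_specific"] == 5
        assert c["oviduct_specific"] == 3
        assert c["cervix_specific"] == 0
        assert rep["tissue_specific_total"] == 8
        assert len(rep["gene_table"]) == 0

    def test_noiseless_targets_rank_first(self):
        linked = pd.DataFrame(
            {
                "Chromosome": ["chr1"],
                "Start": [0],
                "End": [500],
                "Module": ["ovary_specific"],
                "TargetGenes": [["g1"]],
            }
        )
        expr = pd.DataFrame(
            {"ovary": [80.0], "oviduct": [10.0], "cervix": [10.0],
             "cornua_uteri": [10.0], "corpus_uteri": [10.0]}, index=["g1"]
        )
        rep = tsr.module_report(linked, expr, TISSUES, UTERINE)
        assert rep["gene_table"].iloc[0]["TopMatchesModule"]
        assert rep["gene_table"].iloc[0]["ModuleTissueRank"] == 1.0

    def test_missing_expression_reported_not_fatal(self):
        linked = pd.DataFrame(
            {
                "Chromosome": ["chr1"], "Start": [0], "End": [500],
                "Module": ["ovary_specific"], "TargetGenes": [["ghost"]],
            }
        )
        expr = pd.DataFrame({"ovary": [1.0]}, index=["g1"])
        rep = tsr.module_report(linked, expr, TISSUES, UTERINE)
        assert rep["missing_expression"] == ["ghost"]
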