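"""End-to-end orchestration: simulate → QC → binarize → learn → decode →
label → summarize → modules → TAD linking → enrichment → report.

A single run configuration (YAML-loadable) drives every stage; each stage
logs its wall time and parameters, outputs are checksummed, and the JSON
run report collects the per-state summary, module counts (with the
five-tissue-specific sum), top-5 enrichment tables, and — when ground truth
is present — planted-module recovery scores.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, enrichment, hmm, signal, synthetic, tsr
from .errors import ConfigurationError
from .synthetic import SyntheticConfig, UTERINE_TISSUES

logger = logging.getLogger(__name__)

#: bundled motif library: one candidate per tissue-specific module + decoys
DEFAULT_MOTIFS = {
    "ovary_specific": "TGACTCAT",
    "oviduct_specific": "ACGTGACC",
    "cervix_specific": "GGATTACG",
    "cornua_uteri_specific": "CAGCTGAA",
    "corpus_uteri_specific": "TTCGCACT",
    "uterine_common": "GCCACGTA",
}
DECOY_MOTIFS = ["AGGTCAAC", "CTTGAGCA", "TACCGGAT", "GTAACGTC"]


@dataclass
class RunConfig:
    """All stage parameters and switches for one pipeline run."""

    outdir: str = "regmap_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    qc_bin_size_bp: int = 1000
    binarize_p: float = signal.DEFAULT_BINARIZE_P
    # over-parameterized relative to the generator's 5 emission patterns, as
    # is conventional for chromatin-state models (rare states each get one)
    n_states: int = 8
    learn_seed: int = 7
    n_restarts: int = hmm.DEFAULT_RESTARTS
    em_tol: float = hmm.DEFAULT_TOL
    em_max_iter: int = hmm.DEFAULT_MAX_ITER
    per_tissue_models: bool = False
    decode_method: str = "viterbi"
    tss_window_bp: int = 2000
    motif_plant_fraction: float = 0.9
    n_background_regions: int = 60
    score_fraction: float = enrichment.DEFAULT_SCORE_FRACTION
    alpha: float = enrichment.DEFAULT_ALPHA
    min_module_regions: int = 5            # skip enrichment below this
    run_qc: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=syn, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_pwm_library() -> list[enrichment.PWM]:
    pwms = [enrichment.sharp_pwm(f"motif_{m}", c) for m, c in DEFAULT_MOTIFS.items()]
    pwms += [enrichment.sharp_pwm(f"decoy{i}", c) for i, c in enumerate(DECOY_MOTIFS)]
    return pwms


# ---------------------------------------------------------------------------
# ground-truth scoring
# ---------------------------------------------------------------------------

def score_planted_recovery(
    ground_truth: synthetic.GroundTruth, modules: pd.DataFrame
) -> dict:
    """Fraction of planted blocks recovered in their intended module.

    A block is recovered iff at least one classified RRAT region overlapping
    it carries the intended module label.  Also counts planted
    uterine-common blocks that ended up in any single-tissue module (must
    be zero on clean data).
    """
    planted = ground_truth.planted_enhancers
    n_total = len(planted)
    n_recovered = 0
    uterine_as_single = 0
    per_module: dict[str, list[int]] = {}
    for block in planted.itertuples(index=False):
        over = modules[
            (modules["Chromosome"] == block.Chromosome)
            & (modules["Start"] < block.End)
            & (modules["End"] > block.Start)
        ]
        got = set(over["Module"])
        ok = block.Module in got
        n_recovered += ok
        per_module.setdefault(block.Module, []).append(int(ok))
        if block.Module == tsr.MODULE_UTERINE and any(
            m.endswith("_specific") for m in got
        ):
            uterine_as_single += 1
    return {
        "n_planted": n_total,
        "n_recovered": n_recovered,
        "recovery_fraction": n_recovered / n_total if n_total else float("nan"),
        "per_module_recovery": {
            m: float(np.mean(v)) for m, v in sorted(per_module.items())
        },
        "uterine_common_as_single_tissue": uterine_as_single,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def binarize_all(
    tracks: list[signal.BinnedTrack],
    tissues: list[str],
    marks: list[str],
    chromosomes: list[str],
    p_threshold: float,
) -> dict[str, dict[str, dict[str, signal.BinaryTrack]]]:
    """Pool replicates and binarize: returns calls[tissue][chrom][mark]."""
    calls: dict[str, dict[str, dict[str, signal.BinaryTrack]]] = {
        t: {c: {} for c in chromosomes} for t in tissues
    }
    for tissue in tissues:
        for mark in marks:
            pooled = {}
            for chrom in chromosomes:
                reps = [
                    t for t in tracks
                    if t.tissue == tissue and t.mark == mark and t.chromosome == chrom
                ]
                pooled[chrom] = signal.pool_replicates(reps)
            binary = signal.binarize_mark(pooled, p_threshold)
            for chrom, bt in binary.items():
                calls[tissue][chrom][mark] = bt
    return calls


def build_observations(
    calls, tissues: list[str], chromosomes: list[str], marks: list[str]
) -> list[hmm.ObservationMatrix]:
    return [
        signal.to_observation_matrix(calls[t][c], t, c, list(marks))
        for t in tissues
        for c in chromosomes
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages in dependency order; returns the run report.

    A stage failure aborts with the stage name; partial outputs are kept
    alongside a ``FAILED.<stage>`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = config.synthetic
    report: dict = {
        "seeds": {"synthetic": scfg.seed, "learn": config.learn_seed},
        "parameters": {
            "bin_size_bp": scfg.bin_size_bp,
            "qc_bin_size_bp": config.qc_bin_size_bp,
            "binarize_p": config.binarize_p,
            "n_states": config.n_states,
            "tss_window_bp": config.tss_window_bp,
            "alpha": config.alpha,
            "decode_method": config.decode_method,
        },
        "stages": {},
    }
    written: list[Path] = []
    stage_name = "setup"

    def stage(name):
        nonlocal stage_name
        stage_name = name
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(t0):
        dt = time.perf_counter() - t0
        report["stages"][stage_name] = round(dt, 3)
        logger.info("stage %s finished in %.2fs", stage_name, dt)

    try:
        # -- simulate -------------------------------------------------------
        t0 = stage("simulate")
        genome, genes, tads = synthetic.simulate_genome(scfg)
        truth_model = synthetic.default_true_model(scfg)
        truth = synthetic.simulate_state_paths(truth_model, genome, scfg, genes, tads)
        tracks = synthetic.simulate_mark_counts(truth, scfg)
        expression = synthetic.simulate_expression(genes, truth, scfg)
        term_map = synthetic.simulate_term_map(genes, truth, scfg)
        paths = synthetic.write_genome_files(outdir, genome, genes, tads)
        written += list(paths.values())
        expression.to_csv(outdir / "expression.tsv", sep="\t")
        term_map.to_csv(outdir / "term_map.tsv", sep="\t", index=False)
        synthetic.write_ground_truth(outdir / "ground_truth.json", truth)
        written += [outdir / "expression.tsv", outdir / "term_map.tsv",
                    outdir / "ground_truth.json"]
        done(t0)

        tissues = list(scfg.tissues)
        marks = list(scfg.marks)
        chromosomes = list(genome.chrom_sizes)

        # -- QC -------------------------------------------------------------
        if config.run_qc:
            t0 = stage("qc")
            factor = config.qc_bin_size_bp // scfg.bin_size_bp
            samples = []
            for tissue in tissues:
                for mark in marks:
                    per_chrom = []
                    for chrom in chromosomes:
                        reps = [t for t in tracks if t.tissue == tissue
                                and t.mark == mark and t.chromosome == chrom]
                        pooled = signal.pool_replicates(reps)
                        v = pooled.values
                        v = v[: len(v) - len(v) % factor].reshape(-1, factor).sum(axis=1)
                        per_chrom.append(
                            signal.zscore_track(
                                signal.BinnedTrack(chrom, config.qc_bin_size_bp, v,
                                                   mark, tissue)
                            )
                        )
                    samples.append(per_chrom)
            corr = signal.pairwise_correlation(samples)
            scores, evr = signal.pca_tracks(samples, n_components=2)
            corr.to_csv(outdir / "qc_correlation.tsv", sep="\t")
            scores.to_csv(outdir / "qc_pca_scores.tsv", sep="\t")
            written += [outdir / "qc_correlation.tsv", outdir / "qc_pca_scores.tsv"]
            report["qc"] = {
                "pca_explained_variance": [float(v) for v in evr],
                "min_correlation": float(np.asarray(corr).min()),
            }
            done(t0)

        # -- binarize -------------------------------------------------------
        t0 = stage("binarize")
        calls = binarize_all(tracks, tissues, marks, chromosomes, config.binarize_p)
        for tissue in tissues:
            for chrom in chromosomes:
                p = outdir / f"{tissue}_{chrom}_binary.txt"
                signal.write_binarized(p, tissue, chrom, calls[tissue][chrom], marks)
                written.append(p)
        done(t0)

        # -- learn ----------------------------------------------------------
        t0 = stage("learn")
        K = config.n_states
        obs_all = build_observations(calls, tissues, chromosomes, marks)
        if config.per_tissue_models:
            models = {
                t: hmm.learn_model(
                    [o for o in obs_all if o.tissue == t], K, config.learn_seed,
                    config.n_restarts, config.em_tol, config.em_max_iter,
                )[0]
                for t in tissues
            }
        else:
            model, trace = hmm.learn_model(
                obs_all, K, config.learn_seed, config.n_restarts,
                config.em_tol, config.em_max_iter,
            )
            models = {t: model for t in tissues}
            report["learn"] = {
                "final_loglik": trace[-1],
                "n_iterations": len(trace),
                "converged": model.converged,
            }
        hmm.save_model(models[tissues[0]], outdir / "model.json")
        hmm.write_emissions_table(models[tissues[0]], outdir / "emissions.tsv")
        written += [outdir / "model.json", outdir / "emissions.tsv"]
        done(t0)

        # -- decode ---------------------------------------------------------
        t0 = stage("decode")
        segmentations: dict[str, hmm.Segmentation] = {}
        for tissue in tissues:
            frames = []
            for obs in (o for o in obs_all if o.tissue == tissue):
                path = hmm.decode(models[tissue], obs, config.decode_method)
                frames.append(hmm.segment(path, scfg.bin_size_bp, obs.chromosome))
            seg = hmm.Segmentation(tissue, pd.concat(frames, ignore_index=True))
            segmentations[tissue] = seg
            hmm.write_segmentation_bed(seg, outdir / f"{tissue}_segments.bed")
            written.append(outdir / f"{tissue}_segments.bed")
        done(t0)

        # -- annotate -------------------------------------------------------
        t0 = stage("annotate")
        tss = synthetic.gene_tss(genes)
        ref_model = models[tissues[0]]
        folds = annotation.tss_enrichment(
            segmentations, tss, genome.chrom_sizes, config.tss_window_bp,
            n_states=K,
        )
        labels = annotation.label_states(ref_model, folds)
        summary = annotation.summarize_states(segmentations, labels, folds)
        annotation.write_state_summary(summary, outdir / "state_summary.tsv")
        annotation.write_rule_table(outdir / "rule_table.tsv")
        for tissue in tissues:
            p = outdir / f"{tissue}_states_browser.bed"
            annotation.write_state_browser_bed(segmentations[tissue], labels, p)
            written.append(p)
        written += [outdir / "state_summary.tsv", outdir / "rule_table.tsv"]
        report["states"] = {
            "labels": {lab.state_index: lab.name for lab in labels},
            "per_state": summary.per_state.to_dict("records"),
            "per_category": summary.per_category.to_dict("records"),
            "regulatory_element_total": summary.regulatory_element_total,
        }
        done(t0)

        # -- tsr ------------------------------------------------------------
        t0 = stage("tsr")
        enh = annotation.state_intervals(segmentations, labels, "EnhA")
        rrat = tsr.build_rrat(enh)
        modules = tsr.classify_modules(rrat, UTERINE_TISSUES)
        linked = tsr.link_targets(modules, tads, genes)
        mod_report = tsr.module_report(linked, expression, tissues, UTERINE_TISSUES)
        tsr.write_rrat(rrat, modules, outdir / "rrat_matrix.tsv")
        written.append(outdir / "rrat_matrix.tsv")
        bed_paths = tsr.write_module_beds(modules, outdir / "modules")
        written += [Path(p) for p in bed_paths.values()]
        tsr.write_region_genes(linked, outdir / "region_genes.tsv")
        written.append(outdir / "region_genes.tsv")
        report["modules"] = {
            "counts": mod_report["module_counts"],
            "tissue_specific_total": mod_report["tissue_specific_total"],
            "target_gene_top_match_fraction": (
                float(mod_report["gene_table"]["TopMatchesModule"].mean())
                if len(mod_report["gene_table"]) else None
            ),
        }
        report["recovery"] = score_planted_recovery(truth, modules)
        done(t0)

        # -- enrichment -----------------------------------------------------
        if config.run_enrichment:
            t0 = stage("enrichment")
            pwms = default_pwm_library()
            enrichment.write_pwms(pwms, outdir / "pwms.txt")
            written.append(outdir / "pwms.txt")
            rng = np.random.default_rng([scfg.seed, 17])
            bg_regions = _random_regions(
                genome, scfg.enhancer_length_bp, config.n_background_regions, rng
            )
            bg_seqs, _ = synthetic.simulate_sequences_with_motifs(
                bg_regions, pwms[0], 0.0, scfg, rng=rng
            )
            synthetic.write_fasta(bg_seqs, outdir / "background.fa")
            written.append(outdir / "background.fa")
            bg_str = [str(r.seq) for r in bg_seqs]
            motif_tables = {}
            term_tables = {}
            for module, sub in modules.groupby("Module"):
                if module == tsr.MODULE_UNASSIGNED or len(sub) < config.min_module_regions:
                    continue
                pwm = next(
                    (p for p in pwms if p.name == f"motif_{module}"), pwms[0]
                )
                fg_seqs, _ = synthetic.simulate_sequences_with_motifs(
                    sub[["Chromosome", "Start", "End"]],
                    pwm, config.motif_plant_fraction, scfg, rng=rng,
                )
                synthetic.write_fasta(fg_seqs, outdir / f"enhancers_{module}.fa")
                written.append(outdir / f"enhancers_{module}.fa")
                results, top = enrichment.motif_enrichment(
                    [str(r.seq) for r in fg_seqs], bg_str, pwms,
                    config.alpha, config.score_fraction,
                )
                motif_tables[module] = top.to_dict("records")
                results.to_csv(outdir / f"motifs_{module}.tsv", sep="\t", index=False)
                written.append(outdir / f"motifs_{module}.tsv")

                genes_in_module = sorted(
                    {g for gl in linked.loc[linked["Module"] == module, "TargetGenes"]
                     for g in gl}
                )
                if genes_in_module:
                    terms = enrichment.term_enrichment(
                        genes_in_module, list(genes["Name"]), term_map, config.alpha
                    )
                    term_tables[module] = terms.head(5).to_dict("records")
                    terms.to_csv(outdir / f"terms_{module}.tsv", sep="\t", index=False)
                    written.append(outdir / f"terms_{module}.tsv")
            report["enrichment"] = {"motifs_top5": motif_tables,
                                    "terms_top5": term_tables}
            done(t0)

        # -- report ---------------------------------------------------------
        t0 = stage("report")
        report["checksums"] = {p.name: _sha256(p) for p in sorted(set(written))}
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        _write_text_report(outdir / "report.txt", report)
        done(t0)
    except Exception:
        (outdir / f"FAILED.{stage_name}").touch()
        logger.exception("stage %s failed", stage_name)
        raise RuntimeError(f"pipeline stage {stage_name!r} failed") from None
    return report


def _random_regions(genome, length_bp: int, n: int, rng) -> pd.DataFrame:
    chroms = list(genome.chrom_sizes)
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, genome.chrom_sizes[c] - length_bp))
        rows.append((c, s, s + length_bp))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def _write_text_report(path, report: dict) -> None:
    lines = ["regmap run report", "=" * 40]
    lines.append(f"seeds: {report['seeds']}")
    if "learn" in report:
        lines.append(
            f"model: loglik={report['learn']['final_loglik']:.2f} "
            f"iters={report['learn']['n_iterations']} "
            f"converged={report['learn']['converged']}"
        )
    if "states" in report:
        lines.append("\nper-state summary:")
        for rec in report["states"]["per_state"]:
            lines.append(
                f"  E{rec['State'] + 1:<3d}{rec['Name']:<10s}"
                f"n={rec['ElementCount']:<7d}mean={rec['MeanSizeBp']:<9.1f}"
                f"cov={rec['GenomeCoverage']:.4f}"
            )
        lines.append(
            f"regulatory elements (non-Qui, summed over tissues): "
            f"{report['states']['regulatory_element_total']}"
        )
    if "modules" in report:
        lines.append("\nmodule counts:")
        for m, c in report["modules"]["counts"].items():
            lines.append(f"  {m:<28s}{c}")
        lines.append(
            f"five-module tissue-specific sum: "
            f"{report['modules']['tissue_specific_total']}"
        )
    if "recovery" in report:
        r = report["recovery"]
        lines.append(
            f"\nplanted recovery: {r['n_recovered']}/{r['n_planted']} "
            f"({100 * r['recovery_fraction']:.1f}%), "
            f"uterine-as-single={r['uterine_common_as_single_tissue']}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
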