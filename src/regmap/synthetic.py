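"""Seeded synthetic multi-tissue epigenome generator.

Emulates the structure of a five-tissue reproductive epigenome study:
5 tissues (ovary, oviduct, cervix, cornua uteri, corpus uteri) × 2
replicates × {H3K4me3, H3K4me1, H3K27ac, H3K27me3, ATAC} mark tracks plus
an expression table, with Poisson-distributed bin counts whose rate depends
on a hidden chromatin-state path.  Tissue-specific strong-enhancer (EnhA)
blocks are planted inside TADs, coupled to a target gene in the same TAD,
and recorded in a ground-truth object so every downstream stage (binarize →
learn → decode → label → module classification → enrichment) can be scored
against the planted truth.

Noise model: for each bin, mark presence is Bernoulli(emission prob of the
true state); the bin count is then Poisson(enriched_rate) if present and
Poisson(background_rate) otherwise, independently per replicate.  The
baseline Markov chain never *enters* the EnhA state — EnhA bins exist only
where planted — so each planted block's module label is unambiguous ground
truth rather than being confounded by chance baseline enhancers in other
tissues.

All outputs are pure functions of (config, seed): every operation derives
its RNG from the config seed and a fixed per-operation tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, GenerationError
from .hmm import StateModel
from .signal import BinnedTrack

DEFAULT_TISSUES = ("ovary", "oviduct", "cervix", "cornua_uteri", "corpus_uteri")
UTERINE_TISSUES = ("cervix", "cornua_uteri", "corpus_uteri")
DEFAULT_MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "ATAC")

# emission catalog for the bundled truth model (mark order as DEFAULT_MARKS);
# well-separated probabilities (every pair of states differs in >= 2 marks)
# so the clean-recovery regime is well defined
_HI, _LO = 0.95, 0.05
_STATE_CATALOG = [
    ("Qui", [_LO, _LO, _LO, _LO, _LO]),
    ("TssA", [_HI, _LO, _LO, _LO, _HI]),
    ("EnhA", [_LO, _HI, _HI, _LO, _HI]),
    ("Repr", [_LO, _LO, _LO, _HI, _LO]),
    ("EnhAHet", [_LO, _HI, _HI, _HI, _LO]),
]
TSSA_TRUE_STATE = 1
ENHA_TRUE_STATE = 2
#: states the baseline Markov chain moves through; promoters and strong
#: enhancers exist only where planted, so their locations are exact truth
_BASELINE_STATES = (0, 3, 4)

# fixed per-operation RNG stream tags (outputs are pure in (config, seed))
_TAG_GENOME, _TAG_PATHS, _TAG_COUNTS, _TAG_EXPR, _TAG_SEQS, _TAG_TERMS = range(6)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated epigenome.

    Defaults mirror the emulated design: five reproductive tissues, two
    replicates, four histone marks plus ATAC, 200 bp bins, and a clean
    enrichment regime (enriched_rate ≥ 5× background).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    bin_size_bp: int = 200
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 2
    marks: tuple[str, ...] = DEFAULT_MARKS
    n_states: int = 5
    background_rate: float = 0.25     # mean reads/bin/replicate, unenriched
    enriched_rate: float = 6.0        # mean reads/bin/replicate, mark present
    n_genes: int = 80
    n_tads: int = 12                  # per chromosome, contiguous tiling
    planted_specific_enhancers_per_tissue: int = 12
    uterine_common_enhancers: int = 6
    enhancer_length_bp: int = 2000
    planted_gap_bins: int = 5         # min bin gap between planted blocks
    promoter_at_tss: bool = True      # plant TssA blocks at gene TSSs
    promoter_halfwidth_bins: int = 2
    tss_margin_bp: int = 10_000       # TSS exclusion zone at chromosome ends
    expression_baseline: float = 10.0
    expression_fold: float = 8.0
    expression_noise_sd: float = 0.2  # log-normal sd on expression values

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.bin_size_bp,
               self.n_replicates, self.n_states, self.n_genes, self.n_tads) <= 0:
            raise ConfigurationError("lengths and counts must be positive")
        if self.chrom_length_bp % self.bin_size_bp != 0:
            raise ConfigurationError("chrom_length_bp must be divisible by bin_size_bp")
        if not self.enriched_rate > self.background_rate > 0:
            raise ConfigurationError("need enriched_rate > background_rate > 0")
        if self.planted_specific_enhancers_per_tissue < 0 or self.uterine_common_enhancers < 0:
            raise ConfigurationError("planted enhancer counts must be >= 0")
        if self.uterine_common_enhancers > 0 and not set(UTERINE_TISSUES) <= set(self.tissues):
            raise ConfigurationError(
                "uterine_common_enhancers > 0 requires the three uterine tissues"
            )
        if self.enhancer_length_bp % self.bin_size_bp != 0:
            raise ConfigurationError("enhancer_length_bp must be a bin multiple")

    @property
    def n_bins_per_chrom(self) -> int:
        return self.chrom_length_bp // self.bin_size_bp

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def _rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    bin_size_bp: int


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must rediscover."""

    true_model: StateModel
    state_paths: dict[str, dict[str, np.ndarray]] = field(repr=False)
    planted_enhancers: pd.DataFrame = field(repr=False)   # Chromosome Start End Module TargetGene
    planted_motif_regions: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# truth model
# ---------------------------------------------------------------------------

def default_true_model(config: SyntheticConfig) -> StateModel:
    """Bundled truth model: Qui-dominated sticky chain over the state
    catalog; the EnhA state has zero entry probability (planted only)."""
    config.validate()
    K = config.n_states
    if K < 3:
        raise ConfigurationError("bundled truth model needs n_states >= 3")
    rng = config._rng(_TAG_GENOME)
    names = [n for n, _ in _STATE_CATALOG[:K]]
    emis = np.array([e for _, e in _STATE_CATALOG[:K]], dtype=float)
    while len(names) < K:        # extend with distinct random on/off patterns
        pat = rng.choice([_LO, _HI], size=len(config.marks))
        if not any(np.allclose(pat, row) for row in emis):
            emis = np.vstack([emis, pat])
            names.append(f"extra{len(names)}")
    M = len(config.marks)
    if emis.shape[1] != M:
        raise ConfigurationError("bundled truth model expects the five default marks")

    A = np.zeros((K, K))
    planted_only = {TSSA_TRUE_STATE, ENHA_TRUE_STATE}
    baseline = [k for k in range(K) if k not in planted_only]
    for i in baseline:
        A[i, i] = 0.99 if i == 0 else 0.92
        others = [j for j in baseline if j != i]
        rest = 1.0 - A[i, i]
        if i == 0:
            A[i, others] = rest / len(others)
        else:
            A[i, 0] = rest * 0.8                       # exits fall back to Qui
            A[i, [j for j in others if j != 0]] = (
                rest * 0.2 / max(len(others) - 1, 1)
            )
    for k in planted_only:                             # rows for planted states
        A[k, k] = 0.9                                  # run length ~ block length
        A[k, 0] = 0.1
    pi = np.zeros(K)
    pi[0] = 1.0
    model = StateModel(pi, A, emis, list(config.marks))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# genome, genes, TADs
# ---------------------------------------------------------------------------

def simulate_genome(config: SyntheticConfig) -> tuple[Genome, pd.DataFrame, pd.DataFrame]:
    """Chromosome sizes, a BED6-style gene set with uniform TSS placement,
    and TADs tiling each chromosome contiguously."""
    config.validate()
    rng = config._rng(_TAG_GENOME)
    L = config.chrom_length_bp
    genome = Genome({c: L for c in config.chromosomes}, config.bin_size_bp)

    margin = min(config.tss_margin_bp, L // 4)
    chroms = rng.choice(config.chromosomes, size=config.n_genes)
    tss = rng.integers(margin, L - margin, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    body = 5000
    starts = np.where(strands == "+", tss, np.maximum(tss - body + 1, 0))
    ends = np.where(strands == "+", np.minimum(tss + body, L), tss + 1)
    genes = pd.DataFrame(
        {
            "Chromosome": chroms,
            "Start": starts.astype(int),
            "End": ends.astype(int),
            "Name": [f"gene{i:04d}" for i in range(config.n_genes)],
            "Score": 0,
            "Strand": strands,
        }
    ).sort_values(["Chromosome", "Start"], kind="stable").reset_index(drop=True)

    rows = []
    for chrom in config.chromosomes:
        bounds = np.linspace(0, L, config.n_tads + 1).round().astype(int)
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(s), int(e)))
    tads = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
    return genome, genes, tads


def gene_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """TSS per gene: BED start on the + strand, end-1 on the - strand."""
    tss = np.where(genes["Strand"] == "+", genes["Start"], genes["End"] - 1)
    return pd.DataFrame(
        {"Chromosome": genes["Chromosome"], "TSS": tss, "Name": genes["Name"]}
    )


# ---------------------------------------------------------------------------
# state paths with planted enhancer modules
# ---------------------------------------------------------------------------

def _sample_chain(model: StateModel, T: int, rng: np.random.Generator) -> np.ndarray:
    cum_pi = np.cumsum(model.startprob)
    cum_A = np.cumsum(model.transmat, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=int)
    path[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, T):
        path[t] = np.searchsorted(cum_A[path[t - 1]], u[t], side="right")
    return np.minimum(path, model.n_states - 1)


def simulate_state_paths(
    true_model: StateModel,
    genome: Genome,
    config: SyntheticConfig,
    genes: pd.DataFrame | None = None,
    tads: pd.DataFrame | None = None,
) -> GroundTruth:
    """Baseline Markov paths per tissue, then planted EnhA blocks.

    Tissue-specific blocks overwrite the path with the EnhA state in exactly
    one tissue; uterine-common blocks in exactly the three uterine tissues.
    Each block sits strictly inside one TAD that contains at least one gene
    TSS (the designated target gene).  Raises a generation error when the
    requested plantings do not fit.
    """
    config.validate()
    if not np.allclose(true_model.transmat.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigurationError("truth model transition rows must sum to 1")
    if genes is None or tads is None:
        _, g2, t2 = simulate_genome(config)
        genes = genes if genes is not None else g2
        tads = tads if tads is not None else t2
    rng = config._rng(_TAG_PATHS)
    bs = config.bin_size_bp

    paths = {
        tissue: {
            chrom: _sample_chain(true_model, size // bs, rng)
            for chrom, size in genome.chrom_sizes.items()
        }
        for tissue in config.tissues
    }

    tss = gene_tss(genes)
    plantings = [(f"{t}_specific", (t,)) for t in config.tissues
                 for _ in range(config.planted_specific_enhancers_per_tissue)]
    plantings += [("uterine_common", UTERINE_TISSUES)
                  for _ in range(config.uterine_common_enhancers)]

    len_bins = config.enhancer_length_bp // bs
    gap = config.planted_gap_bins
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_sizes}

    if config.promoter_at_tss:
        # promoters exist at gene TSSs in every tissue; they also block
        # enhancer placement, keeping planted EnhA TSS-distal
        hw = config.promoter_halfwidth_bins
        for row in tss.itertuples(index=False):
            nb = genome.chrom_sizes[row.Chromosome] // bs
            b0 = max(int(row.TSS) // bs - hw, 0)
            b1 = min(int(row.TSS) // bs + hw + 1, nb)
            occupied[row.Chromosome].append((b0, b1))
            for tissue in config.tissues:
                paths[tissue][row.Chromosome][b0:b1] = TSSA_TRUE_STATE
    candidates = []
    for row in tads.itertuples(index=False):
        in_tad = tss[(tss["Chromosome"] == row.Chromosome)
                     & (tss["TSS"] >= row.Start) & (tss["TSS"] < row.End)]
        lo = row.Start // bs + 1                 # strict TAD interior, bin units
        hi = row.End // bs - 1 - len_bins
        if len(in_tad) and hi > lo:
            candidates.append((row.Chromosome, lo, hi, list(in_tad["Name"])))
    if plantings and not candidates:
        raise GenerationError("no TAD can host a planted enhancer")

    records = []
    gene_module: dict[str, str] = {}         # a gene serves only one module
    for module, target_tissues in plantings:
        placed = False
        for _ in range(200):
            chrom, lo, hi, tad_genes = candidates[rng.integers(len(candidates))]
            free = [g for g in tad_genes if gene_module.get(g, module) == module]
            if not free:
                continue
            b0 = int(rng.integers(lo, hi))
            b1 = b0 + len_bins
            if all(b1 + gap <= s or e + gap <= b0 for s, e in occupied[chrom]):
                occupied[chrom].append((b0, b1))
                target = free[rng.integers(len(free))]
                gene_module[target] = module
                records.append((chrom, b0 * bs, b1 * bs, module, target))
                for tissue in target_tissues:
                    paths[tissue][chrom][b0:b1] = ENHA_TRUE_STATE
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place planted enhancer for module {module!r}: "
                "requested plantings exceed genome capacity"
            )
    planted = pd.DataFrame(
        records, columns=["Chromosome", "Start", "End", "Module", "TargetGene"]
    ).sort_values(["Chromosome", "Start"]).reset_index(drop=True)
    return GroundTruth(true_model, paths, planted)


# ---------------------------------------------------------------------------
# mark counts
# ---------------------------------------------------------------------------

def simulate_mark_counts(
    ground_truth: GroundTruth, config: SyntheticConfig
) -> list[BinnedTrack]:
    """Bernoulli-Poisson mixture counts per tissue × replicate × mark × chrom."""
    config.validate()
    E = ground_truth.true_model.emissionprob
    if (E < 0).any() or (E > 1).any():
        raise ConfigurationError("emission probabilities must lie in [0, 1]")
    rng = config._rng(_TAG_COUNTS)
    tracks = []
    for tissue in config.tissues:
        for chrom, path in ground_truth.state_paths[tissue].items():
            for rep in range(1, config.n_replicates + 1):
                for m, mark in enumerate(config.marks):
                    present = rng.random(path.size) < E[path, m]
                    lam = np.where(present, config.enriched_rate, config.background_rate)
                    counts = rng.poisson(lam) if path.size else np.zeros(0, dtype=int)
                    tracks.append(
                        BinnedTrack(chrom, config.bin_size_bp,
                                    counts.astype(float), mark, tissue, rep)
                    )
    return tracks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: pd.DataFrame, ground_truth: GroundTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Gene × tissue expression: baseline log-normal everywhere, elevated by
    ``expression_fold`` in the module tissue(s) of each planted enhancer's
    target gene."""
    config.validate()
    known = set(genes["Name"])
    bad = set(ground_truth.planted_enhancers["TargetGene"]) - known
    if bad:
        raise GenerationError(f"unknown target gene identifiers: {sorted(bad)}")
    rng = config._rng(_TAG_EXPR)
    n, tissues = len(genes), list(config.tissues)
    values = config.expression_baseline * np.exp(
        rng.normal(0.0, config.expression_noise_sd, size=(n, len(tissues)))
    )
    expr = pd.DataFrame(values, index=list(genes["Name"]), columns=tissues)
    for row in ground_truth.planted_enhancers.itertuples(index=False):
        targets = ([t for t in UTERINE_TISSUES] if row.Module == "uterine_common"
                   else [row.Module.removesuffix("_specific")])
        for tissue in targets:
            expr.loc[row.TargetGene, tissue] *= config.expression_fold
    expr.index.name = "Gene"
    return expr


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------

def simulate_sequences_with_motifs(
    regions: pd.DataFrame,
    pwm,
    plant_fraction: float,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
):
    """I.i.d.-uniform ACGT sequences for each region, with the PWM consensus
    inserted at a random offset and strand in a ``plant_fraction`` subset.

    Returns (list of SeqRecord, planted-region index array).
    """
    if not 0.0 <= plant_fraction <= 1.0:
        raise ConfigurationError("plant_fraction must be in [0, 1]")
    if rng is None:
        rng = config._rng(_TAG_SEQS)
    consensus = pwm.consensus
    w = len(consensus)
    n = len(regions)
    n_plant = int(round(plant_fraction * n))
    planted_idx = np.sort(rng.choice(n, size=n_plant, replace=False)) if n_plant else np.array([], dtype=int)
    planted_set = set(planted_idx.tolist())

    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    records = []
    for i, row in enumerate(regions.itertuples(index=False)):
        length = int(row.End) - int(row.Start)
        if length < w:
            raise GenerationError(
                f"region {row.Chromosome}:{row.Start}-{row.End} shorter than motif ({w} bp)"
            )
        seq = rng.integers(0, 4, size=length)
        chars = bases[seq]
        if i in planted_set:
            insert = consensus if rng.random() < 0.5 else str(
                Seq(consensus).reverse_complement()
            )
            off = int(rng.integers(0, length - w + 1))
            chars[off:off + w] = list(insert)
        records.append(
            SeqRecord(Seq("".join(chars)),
                      id=f"{row.Chromosome}:{row.Start}-{row.End}", description="")
        )
    return records, planted_idx


def simulate_term_map(
    genes: pd.DataFrame, ground_truth: GroundTruth, config: SyntheticConfig,
    n_background_terms: int = 10, genes_per_term: int = 15,
) -> pd.DataFrame:
    """Gene → term map: one coherent term per planted module (its target
    genes) plus random background terms.  Plumbing for the term-enrichment
    stage on synthetic runs."""
    rng = config._rng(_TAG_TERMS)
    rows = []
    planted = ground_truth.planted_enhancers
    for module, sub in planted.groupby("Module"):
        for g in sorted(set(sub["TargetGene"])):
            rows.append((g, f"{module}_program"))
    names = list(genes["Name"])
    for t in range(n_background_terms):
        for g in rng.choice(names, size=min(genes_per_term, len(names)), replace=False):
            rows.append((g, f"term{t:03d}"))
    return pd.DataFrame(rows, columns=["Gene", "Term"]).drop_duplicates()


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fasta(records, path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")

def write_genome_files(outdir, genome: Genome, genes: pd.DataFrame,
                       tads: pd.DataFrame) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "genes": outdir / "genes.bed",
        "tads": outdir / "tads.bed",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    genes[["Chromosome", "Start", "End", "Name", "Score", "Strand"]].to_csv(
        paths["genes"], sep="\t", header=False, index=False
    )
    tads.to_csv(paths["tads"], sep="\t", header=False, index=False)
    return paths


def write_ground_truth(path, ground_truth: GroundTruth) -> None:
    import json

    payload = {
        "true_model": {
            "startprob": ground_truth.true_model.startprob.tolist(),
            "transmat": ground_truth.true_model.transmat.tolist(),
            "emissionprob": ground_truth.true_model.emissionprob.tolist(),
            "mark_order": list(ground_truth.true_model.mark_order),
        },
        "planted_enhancers": ground_truth.planted_enhancers.to_dict("records"),
        "state_paths": {
            tissue: {chrom: p.tolist() for chrom, p in by_chrom.items()}
            for tissue, by_chrom in ground_truth.state_paths.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
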