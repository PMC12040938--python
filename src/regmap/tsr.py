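"""Tissue-specific regulatory (TSR) enhancer modules and TAD-based targets.

The RRAT matrix ("regulatory regions across tissues") is built over the
merged union of all tissues' strong-active-enhancer (EnhA) intervals: a
region scores 1 for a tissue iff at least one of that tissue's EnhA
intervals overlaps it by >= 1 bp.  Rows with exactly one 1 form the five
tissue-specific modules; the exact cervix+cornua+corpus pattern forms the
uterine-common module; every other pattern is left unassigned rather than
forced into a module.  Enhancer regions are linked to target genes by
shared-TAD co-membership: a gene is a target of a region iff the gene's
TSS and the region's midpoint fall in the same TAD (midpoint assignment
keeps regions straddling a TAD boundary unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

from .errors import ConfigurationError, InputError

MODULE_UNASSIGNED = "unassigned"
MODULE_UTERINE = "uterine_common"


@dataclass
class RRATMatrix:
    """Merged EnhA union regions × tissues binary overlap matrix."""

    regions: pd.DataFrame = field(repr=False)    # Chromosome Start End, genomic order
    tissues: list[str] = field(default_factory=list)
    matrix: np.ndarray = field(default=None, repr=False)   # (n_regions, n_tissues) 0/1

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def module_names(tissues: list[str]) -> list[str]:
    return [f"{t}_specific" for t in tissues] + [MODULE_UTERINE, MODULE_UNASSIGNED]


# ---------------------------------------------------------------------------
# RRAT construction
# ---------------------------------------------------------------------------

def build_rrat(enh_by_tissue: dict[str, pd.DataFrame]) -> RRATMatrix:
    """Union-merge all tissues' EnhA intervals (book-ended merge) and score
    per-tissue >= 1 bp overlap for each merged region."""
    tissues = list(enh_by_tissue)
    if not tissues:
        raise ConfigurationError("no tissues provided")
    frames = []
    for tissue, df in enh_by_tissue.items():
        if len(df):
            if (df["End"] <= df["Start"]).any():
                raise InputError(f"malformed EnhA interval for tissue {tissue!r}")
            frames.append(df[["Chromosome", "Start", "End"]])
    if not frames:
        regions = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        return RRATMatrix(regions, tissues, np.zeros((0, len(tissues)), dtype=int))
    union = pd.concat(frames, ignore_index=True)
    regions = (
        pr.PyRanges(union).merge().df.sort_values(["Chromosome", "Start"])
        .reset_index(drop=True)
    )
    regions["Chromosome"] = regions["Chromosome"].astype(str)
    region_pr = pr.PyRanges(regions)
    mat = np.zeros((len(regions), len(tissues)), dtype=int)
    for j, tissue in enumerate(tissues):
        df = enh_by_tissue[tissue]
        if len(df) == 0:
            continue
        counts = region_pr.count_overlaps(
            pr.PyRanges(df[["Chromosome", "Start", "End"]])
        ).df
        counts["Chromosome"] = counts["Chromosome"].astype(str)
        counts = counts.sort_values(["Chromosome", "Start"]).reset_index(drop=True)
        mat[:, j] = (counts["NumberOverlaps"].to_numpy() > 0).astype(int)
    return RRATMatrix(regions, tissues, mat)


# ---------------------------------------------------------------------------
# module classification
# ---------------------------------------------------------------------------

def classify_modules(
    rrat: RRATMatrix, uterine_tissues: set[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Assign exactly one module per RRAT region.

    Single-tissue rows map to that tissue's specific module; the exact
    three-uterine pattern maps to uterine_common; all other patterns map to
    unassigned.
    """
    uterine = set(uterine_tissues)
    if not uterine <= set(rrat.tissues):
        raise ConfigurationError(
            f"uterine tissues {sorted(uterine - set(rrat.tissues))} not in matrix"
        )
    if len(uterine) != 3:
        raise ConfigurationError("expected exactly three uterine tissue names")
    uterine_cols = np.array([t in uterine for t in rrat.tissues])

    out = rrat.regions.copy()
    modules = []
    for row in rrat.matrix:
        on = row.astype(bool)
        if on.sum() == 1:
            modules.append(f"{rrat.tissues[int(np.flatnonzero(on)[0])]}_specific")
        elif on.sum() == 3 and (on == uterine_cols).all():
            modules.append(MODULE_UTERINE)
        else:
            modules.append(MODULE_UNASSIGNED)
    out["Module"] = modules
    return out


# ---------------------------------------------------------------------------
# TAD-based target linking
# ---------------------------------------------------------------------------

def _validate_tads(tads: pd.DataFrame) -> None:
    if (tads["End"] <= tads["Start"]).any():
        bad = tads[tads["End"] <= tads["Start"]].iloc[0]
        raise InputError(f"malformed TAD {bad['Chromosome']}:{bad['Start']}-{bad['End']}")
    for chrom, sub in tads.groupby("Chromosome"):
        sub = sub.sort_values("Start")
        overlap = sub["Start"].to_numpy()[1:] < sub["End"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            a = sub.iloc[i]
            b = sub.iloc[i + 1]
            raise InputError(
                f"overlapping TADs on {chrom}: "
                f"[{a['Start']}, {a['End']}) and [{b['Start']}, {b['End']})"
            )


def _assign_tad(points: pd.DataFrame, tads: pd.DataFrame) -> np.ndarray:
    """TAD id per (Chromosome, Pos) point; -1 where no TAD contains it."""
    tad_ids = np.full(len(points), -1, dtype=int)
    tads = tads.reset_index(drop=True)
    for chrom, sub in tads.groupby("Chromosome"):
        sub = sub.sort_values("Start")
        sel = points["Chromosome"] == chrom
        if not sel.any():
            continue
        pos = points.loc[sel, "Pos"].to_numpy()
        idx = np.searchsorted(sub["Start"].to_numpy(), pos, side="right") - 1
        ok = (idx >= 0) & (pos < sub["End"].to_numpy()[np.clip(idx, 0, None)])
        ids = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, None)], -1)
        tad_ids[np.flatnonzero(sel.to_numpy())] = ids
    return tad_ids


def link_targets(
    modules: pd.DataFrame, tads: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Shared-TAD enhancer→gene links.

    Returns the module table with ``TargetGenes`` (sorted gene-name list)
    and ``InTad`` (False where the region midpoint lies in no TAD, in which
    case the target set is empty).
    """
    from .synthetic import gene_tss

    _validate_tads(tads)
    out = modules.copy().reset_index(drop=True)
    mids = pd.DataFrame(
        {
            "Chromosome": out["Chromosome"],
            "Pos": (out["Start"] + out["End"]) // 2,
        }
    )
    region_tad = _assign_tad(mids, tads)
    tss = gene_tss(genes)
    gene_tad = _assign_tad(
        tss.rename(columns={"TSS": "Pos"})[["Chromosome", "Pos"]], tads
    )
    genes_in_tad: dict[int, list[str]] = {}
    for name, tid in zip(tss["Name"], gene_tad):
        if tid >= 0:
            genes_in_tad.setdefault(int(tid), []).append(name)
    out["TadId"] = region_tad
    out["InTad"] = region_tad >= 0
    out["TargetGenes"] = [
        sorted(genes_in_tad.get(int(t), [])) if t >= 0 else [] for t in region_tad
    ]
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def module_report(
    linked: pd.DataFrame,
    expression: pd.DataFrame | None,
    tissues: list[str],
    uterine_tissues: set[str] | tuple[str, ...] = (),
) -> dict:
    """Per-module counts, per-region target lists, and target-gene
    expression ranks across tissues.

    For each target gene the report records the tissue ranking of its
    expression and whether the top tissue matches the module's tissue
    (any of the three uterine tissues for the uterine-common module).
    Genes absent from the expression table are listed, not fatal.
    """
    uterine = set(uterine_tissues)
    counts = {m: 0 for m in module_names(tissues)}
    for m in linked["Module"]:
        counts[m] = counts.get(m, 0) + 1

    gene_rows = []
    missing = set()
    for row in linked.itertuples(index=False):
        if row.Module == MODULE_UNASSIGNED:
            continue
        expected = (
            uterine if row.Module == MODULE_UTERINE
            else {row.Module.removesuffix("_specific")}
        )
        for gene in row.TargetGenes:
            if expression is None or gene not in expression.index:
                missing.add(gene)
                continue
            vals = expression.loc[gene]
            top = vals.idxmax()
            ranks = vals.rank(ascending=False)
            gene_rows.append(
                {
                    "Gene": gene,
                    "Module": row.Module,
                    "TopTissue": top,
                    "TopMatchesModule": top in expected,
                    "ModuleTissueRank": float(min(ranks[t] for t in expected)),
                }
            )
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["Gene", "Module", "TopTissue", "TopMatchesModule", "ModuleTissueRank"],
    ).drop_duplicates(subset=["Gene", "Module"]).reset_index(drop=True)
    return {
        "module_counts": counts,
        "tissue_specific_total": int(
            sum(counts[f"{t}_specific"] for t in tissues)
        ),
        "gene_table": gene_table,
        "missing_expression": sorted(missing),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_rrat(rrat: RRATMatrix, modules: pd.DataFrame | None, path) -> None:
    df = rrat.regions.copy()
    for j, t in enumerate(rrat.tissues):
        df[t] = rrat.matrix[:, j]
    if modules is not None:
        df["Module"] = modules["Module"].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_module_beds(modules: pd.DataFrame, outdir) -> dict[str, str]:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for module, sub in modules.groupby("Module"):
        p = outdir / f"module_{module}.bed"
        sub[["Chromosome", "Start", "End"]].to_csv(p, sep="\t", header=False, index=False)
        paths[module] = str(p)
    return paths


def write_region_genes(linked: pd.DataFrame, path) -> None:
    df = linked.copy()
    df["TargetGenes"] = df["TargetGenes"].map(",".join)
    df[["Chromosome", "Start", "End", "Module", "TargetGenes"]].to_csv(
        path, sep="\t", index=False
    )
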