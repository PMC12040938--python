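"""Functional naming and summary statistics of learned chromatin states.

States are named with the 15-label vocabulary (TssA, TssAHet, TxFlnk,
TxFlnkWk, TxFlnkHet, EnhA, EnhAMe, EnhAWk, EnhAHet, EnhPois, ATAC_Is,
TssBiv, Repr, ReprWk, Qui) grouped into six functional categories.  Naming
is a deterministic first-match cascade over binarized emission levels
(high = emission prob >= 0.5) and fold enrichment of the state around
transcription start sites (enriched = fold >= 2); the cascade ships as a
versioned, editable rule table.  Two learned states may receive the same
name; every state receives exactly one.

Summaries follow the field's reporting conventions: per-state element
counts, mean sizes (both pooled and tissue-averaged), genome coverage
(per tissue, then averaged), a six-category rollup, the per-tissue-additive
"regulatory element" total (every non-Quiescent interval, summed over
tissues), and the non-redundant element total NRRET (cross-tissue merged
intervals, book-ended intervals merging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

from .errors import ConfigurationError, InputError
from .hmm import Segmentation, StateModel

STATE_NAMES = [
    "TssA", "TssAHet", "TxFlnk", "TxFlnkWk", "TxFlnkHet",
    "EnhA", "EnhAMe", "EnhAWk", "EnhAHet", "EnhPois",
    "ATAC_Is", "TssBiv", "Repr", "ReprWk", "Qui",
]

CATEGORY_OF = {
    "TssA": "promoter", "TssAHet": "promoter", "TssBiv": "promoter",
    "TxFlnk": "tss_proximal_transcription",
    "TxFlnkWk": "tss_proximal_transcription",
    "TxFlnkHet": "tss_proximal_transcription",
    "EnhA": "enhancer", "EnhAMe": "enhancer", "EnhAWk": "enhancer",
    "EnhAHet": "enhancer", "EnhPois": "enhancer",
    "ATAC_Is": "atac_island",
    "Repr": "repressive", "ReprWk": "repressive",
    "Qui": "quiescent",
}
CATEGORIES = ["promoter", "tss_proximal_transcription", "enhancer",
              "atac_island", "repressive", "quiescent"]

REQUIRED_MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "ATAC")

#: browser palette, one RGB per state name (Roadmap-style hues)
STATE_PALETTE = {
    "TssA": "255,0,0", "TssAHet": "255,69,0", "TssBiv": "205,92,92",
    "TxFlnk": "0,100,0", "TxFlnkWk": "60,179,113", "TxFlnkHet": "143,188,143",
    "EnhA": "255,195,77", "EnhAMe": "255,215,0", "EnhAWk": "255,255,0",
    "EnhAHet": "189,183,107", "EnhPois": "138,145,208",
    "ATAC_Is": "64,224,208",
    "Repr": "128,128,128", "ReprWk": "192,192,192", "Qui": "255,255,255",
}

RULE_TABLE_VERSION = "1.0"

# First-match cascade: per-mark requirement H (emission >= cut), L (< cut) or
# * (don't care); TSS requirement E (fold >= cut), N (fold < cut) or *.
# The trailing catch-all makes naming a total function.
DEFAULT_RULES: list[tuple[dict[str, str], str, str]] = [
    ({"H3K4me3": "L", "H3K4me1": "L", "H3K27ac": "L", "H3K27me3": "L", "ATAC": "L"}, "*", "Qui"),
    ({"H3K4me3": "H", "H3K27me3": "H"}, "*", "TssBiv"),
    ({"H3K4me3": "H", "ATAC": "H"}, "E", "TssA"),
    ({"H3K4me3": "H", "ATAC": "L"}, "*", "TssAHet"),
    ({"H3K4me3": "H", "ATAC": "H"}, "N", "TxFlnk"),
    ({"H3K27ac": "H", "H3K4me1": "H", "ATAC": "H"}, "N", "EnhA"),
    ({"H3K27ac": "H", "H3K4me1": "H", "ATAC": "H"}, "E", "EnhAMe"),
    ({"H3K27ac": "H", "H3K4me1": "H", "ATAC": "L"}, "*", "EnhAHet"),
    ({"H3K4me1": "H", "H3K27me3": "H"}, "*", "EnhPois"),
    ({"H3K4me1": "H", "ATAC": "H"}, "*", "EnhAWk"),
    ({"H3K4me1": "H"}, "*", "TxFlnkWk"),
    ({"H3K27ac": "H", "ATAC": "H"}, "*", "EnhAWk"),
    ({"H3K27ac": "H"}, "*", "TxFlnkHet"),
    ({"H3K4me3": "L", "H3K4me1": "L", "H3K27ac": "L", "H3K27me3": "L", "ATAC": "H"}, "*", "ATAC_Is"),
    ({"H3K27me3": "H"}, "*", "Repr"),
    ({}, "*", "Qui"),
]


@dataclass
class StateLabel:
    state_index: int
    name: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.name not in CATEGORY_OF:
            raise ConfigurationError(f"unknown state name {self.name!r}")
        self.category = CATEGORY_OF[self.name]


@dataclass
class StateSummary:
    """Per-state and per-category statistics over per-tissue segmentations."""

    per_state: pd.DataFrame = field(repr=False)
    per_category: pd.DataFrame = field(repr=False)
    regulatory_element_total: int = 0
    nrret: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# TSS enrichment
# ---------------------------------------------------------------------------

def _seg_list(segmentations) -> list[Segmentation]:
    if isinstance(segmentations, Segmentation):
        return [segmentations]
    if isinstance(segmentations, dict):
        return list(segmentations.values())
    return list(segmentations)


def tss_windows(
    tss: pd.DataFrame, chrom_sizes: dict[str, int], window_bp: int = 2000
) -> pr.PyRanges:
    """Merged, end-clipped ±window neighbourhoods of the TSS set."""
    if len(tss) == 0:
        raise InputError("empty TSS set")
    starts = np.maximum(tss["TSS"].to_numpy() - window_bp, 0)
    ends = np.array(
        [min(t + window_bp, chrom_sizes[c])
         for t, c in zip(tss["TSS"], tss["Chromosome"])]
    )
    return pr.PyRanges(
        pd.DataFrame({"Chromosome": tss["Chromosome"], "Start": starts, "End": ends})
    ).merge()


def tss_enrichment(
    segmentations,
    tss: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_bp: int = 2000,
    n_states: int | None = None,
) -> np.ndarray:
    """Per-state fold enrichment around TSSs.

    fold(k) = (fraction of state-k bases inside TSS windows) /
              (fraction of the genome inside TSS windows);
    a state with no bases anywhere gets fold 0.
    """
    segs = _seg_list(segmentations)
    win = tss_windows(tss, chrom_sizes, window_bp)
    genome_bp = sum(chrom_sizes.values())
    win_bp = int((win.End - win.Start).sum())
    win_frac = win_bp / genome_bp

    df = pd.concat([s.intervals for s in segs], ignore_index=True)
    if n_states is None:
        n_states = int(df["State"].max()) + 1
    folds = np.zeros(n_states)
    for k, sub in df.groupby("State"):
        total = int((sub["End"] - sub["Start"]).sum())
        if total == 0:
            continue
        inter = pr.PyRanges(sub[["Chromosome", "Start", "End"]]).intersect(win)
        inside = 0 if len(inter) == 0 else int((inter.End - inter.Start).sum())
        folds[int(k)] = (inside / total) / win_frac
    return folds


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def _match(rule_marks: dict[str, str], rule_tss: str,
           high: dict[str, bool], tss_enriched: bool) -> bool:
    for mark, req in rule_marks.items():
        if req == "*":
            continue
        if (req == "H") != high[mark]:
            return False
    if rule_tss == "*":
        return True
    return (rule_tss == "E") == tss_enriched


def label_states(
    model: StateModel,
    tss_folds: np.ndarray,
    rules: list[tuple[dict[str, str], str, str]] | None = None,
    emission_cut: float = 0.5,
    fold_cut: float = 2.0,
) -> list[StateLabel]:
    """Name every learned state through the rule cascade.

    Relative-strength repressive split: a state whose marks are all below
    the absolute cut but whose H3K27me3 emission still reaches half the
    strongest H3K27me3 emission across states is ReprWk rather than Qui;
    states at or above the absolute cut are Repr.
    """
    missing = [m for m in REQUIRED_MARKS if m not in model.mark_order]
    if missing:
        raise ConfigurationError(f"mark_order lacks required marks: {missing}")
    if model.n_states < 1:
        raise ConfigurationError("model must have at least one state")
    rules = DEFAULT_RULES if rules is None else rules
    tss_folds = np.asarray(tss_folds, dtype=float)
    col = {m: model.mark_order.index(m) for m in REQUIRED_MARKS}
    k27me3 = model.emissionprob[:, col["H3K27me3"]]
    k27me3_max = float(k27me3.max())

    labels = []
    for k in range(model.n_states):
        high = {m: model.emissionprob[k, col[m]] >= emission_cut for m in REQUIRED_MARKS}
        enriched = bool(tss_folds[k] >= fold_cut) if k < tss_folds.size else False
        name = next(
            name for marks, tssreq, name in rules if _match(marks, tssreq, high, enriched)
        )
        if (
            name == "Qui"
            and k27me3_max >= emission_cut
            and k27me3[k] >= 0.5 * k27me3_max
            and all(
                model.emissionprob[k, col[m]] < emission_cut
                for m in REQUIRED_MARKS if m != "H3K27me3"
            )
        ):
            name = "ReprWk"
        labels.append(StateLabel(k, name))
    return labels


def write_rule_table(path, rules=None) -> None:
    """Persist the cascade as an editable TSV (one rule per row, first match
    wins; columns: the five marks, TSS requirement, state name)."""
    rules = DEFAULT_RULES if rules is None else rules
    rows = [
        {**{m: rule_marks.get(m, "*") for m in REQUIRED_MARKS},
         "TSS": tssreq, "Name": name}
        for rule_marks, tssreq, name in rules
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# state naming rule table v{RULE_TABLE_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_rule_table(path) -> list[tuple[dict[str, str], str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    rules = []
    for row in df.itertuples(index=False):
        marks = {m: getattr(row, m) for m in REQUIRED_MARKS if getattr(row, m) != "*"}
        rules.append((marks, row.TSS, row.Name))
    return rules


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def nonredundant_elements(intervals: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Merge overlapping and book-ended intervals across tissues; count the
    merged (disjoint) elements."""
    if len(intervals) == 0:
        empty = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        return empty, 0
    if (intervals["End"] <= intervals["Start"]).any():
        bad = intervals[intervals["End"] <= intervals["Start"]].iloc[0]
        raise InputError(
            f"malformed interval {bad['Chromosome']}:{bad['Start']}-{bad['End']}"
        )
    merged = (
        pr.PyRanges(intervals[["Chromosome", "Start", "End"]].reset_index(drop=True))
        .merge()
        .df.sort_values(["Chromosome", "Start"])
        .reset_index(drop=True)
    )
    merged["Chromosome"] = merged["Chromosome"].astype(str)
    return merged, len(merged)


def summarize_states(
    segmentations: dict[str, Segmentation],
    labels: list[StateLabel],
    tss_folds: np.ndarray | None = None,
) -> StateSummary:
    """Per-state / per-category statistics across per-tissue segmentations.

    Genome coverage is computed per tissue then averaged; element counts and
    the regulatory-element total are additive over tissues; NRRET counts the
    cross-tissue merged intervals per state.
    """
    name_of = {lab.state_index: lab.name for lab in labels}
    cat_of = {lab.state_index: lab.category for lab in labels}
    K = len(labels)
    tissues = list(segmentations)

    frames = []
    for tissue in tissues:
        df = segmentations[tissue].intervals.copy()
        df["Tissue"] = tissue
        frames.append(df)
    all_iv = pd.concat(frames, ignore_index=True)
    all_iv["Size"] = all_iv["End"] - all_iv["Start"]
    genome_bp_per_tissue = {
        t: int(
            (segmentations[t].intervals["End"] - segmentations[t].intervals["Start"]).sum()
        )
        for t in tissues
    }

    rows = []
    for k in range(K):
        sub = all_iv[all_iv["State"] == k]
        count = len(sub)
        mean_pooled = float(sub["Size"].mean()) if count else 0.0
        per_tissue_means = [
            float(g["Size"].mean()) for _, g in sub.groupby("Tissue") if len(g)
        ]
        mean_tissue_avg = float(np.mean(per_tissue_means)) if per_tissue_means else 0.0
        cov = float(
            np.mean(
                [
                    sub[sub["Tissue"] == t]["Size"].sum() / genome_bp_per_tissue[t]
                    for t in tissues
                ]
            )
        )
        _, nr = nonredundant_elements(sub[["Chromosome", "Start", "End"]])
        rows.append(
            {
                "State": k,
                "Name": name_of[k],
                "Category": cat_of[k],
                "ElementCount": count,
                "MeanSizeBp": mean_pooled,
                "MeanSizeBpTissueAvg": mean_tissue_avg,
                "GenomeCoverage": cov,
                "NRRET": nr,
                "TssFold": float(tss_folds[k]) if tss_folds is not None else np.nan,
            }
        )
    per_state = pd.DataFrame(rows)

    cat_rows = []
    for cat in CATEGORIES:
        sub = per_state[per_state["Category"] == cat]
        cat_rows.append(
            {
                "Category": cat,
                "ElementCount": int(sub["ElementCount"].sum()),
                "GenomeCoverage": float(sub["GenomeCoverage"].sum()),
            }
        )
    per_category = pd.DataFrame(cat_rows)
    regulatory_total = int(
        per_state.loc[per_state["Category"] != "quiescent", "ElementCount"].sum()
    )

    nrret = per_state[["State", "Name", "NRRET"]].copy()
    return StateSummary(per_state, per_category, regulatory_total, nrret)


def state_intervals(
    segmentations: dict[str, Segmentation],
    labels: list[StateLabel],
    name: str,
) -> dict[str, pd.DataFrame]:
    """Per-tissue intervals of every state carrying the given name."""
    states = {lab.state_index for lab in labels if lab.name == name}
    out = {}
    for tissue, seg in segmentations.items():
        df = seg.intervals
        out[tissue] = df[df["State"].isin(states)][
            ["Chromosome", "Start", "End"]
        ].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# browser tracks and tables
# ---------------------------------------------------------------------------

def write_state_browser_bed(seg: Segmentation, labels: list[StateLabel], path) -> None:
    """BED9 with itemRgb coloured by state name (fixed palette)."""
    name_of = {lab.state_index: lab.name for lab in labels}
    df = seg.intervals
    with open(path, "w") as fh:
        fh.write(f'track name="{seg.tissue}_states" itemRgb="On"\n')
        for row in df.itertuples(index=False):
            name = name_of[int(row.State)]
            rgb = STATE_PALETTE[name]
            fh.write(
                f"{row.Chromosome}\t{row.Start}\t{row.End}\t{name}\t0\t.\t"
                f"{row.Start}\t{row.End}\t{rgb}\n"
            )


def write_state_summary(summary: StateSummary, path) -> None:
    summary.per_state.to_csv(path, sep="\t", index=False)
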