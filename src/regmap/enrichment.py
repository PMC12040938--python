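"""Motif scanning and hypergeometric motif/term enrichment.

A statistics-transparent analog of the usual motif/GO tooling: motifs are
explicit position weight matrices scanned by log2 odds against a background
base composition (hit = window score >= a fraction of the maximum
attainable score, both strands), the enrichment unit is per-sequence
presence/absence, and the test is the one-sided hypergeometric upper tail
of foreground presence given pooled foreground+background presence, with
Benjamini-Hochberg adjustment within each test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])       # A<->T, C<->G in BASES order
PROB_FLOOR = 1e-3
DEFAULT_SCORE_FRACTION = 0.8
DEFAULT_ALPHA = 0.05


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities (A, C, G, T)
    plus a background composition.  Probabilities are floored at 1e-3
    before taking log odds (pseudo-probability)."""

    name: str
    matrix: np.ndarray = field(repr=False)       # (w, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25), repr=False
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ConfigurationError("PWM matrix must be w x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("PWM background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, PROB_FLOOR)
        bg = np.maximum(self.background, PROB_FLOOR)
        return np.log2(p / bg[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class MotifHit:
    offset: int          # forward-strand coordinate of the window start
    strand: str          # '+' or '-'
    score: float


def sharp_pwm(name: str, consensus: str, p_consensus: float = 0.91) -> PWM:
    """Near-deterministic PWM around a consensus (off-bases share the rest)."""
    off = (1.0 - p_consensus) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        mat[i, _BASE_INDEX[b]] = p_consensus
    return PWM(name, mat)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.size, 4, dtype=np.int8)          # 4 = N / unknown
    for b, i in _BASE_INDEX.items():
        code[arr == ord(b)] = i
    return code


def _window_scores(code: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all w-windows of an encoded sequence; windows containing N
    are flagged invalid."""
    w = lo.shape[0]
    n_win = code.size - w + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(code == 4, 0, code)
    for i in range(w):
        scores += lo[i, safe[i : i + n_win]]
        valid &= code[i : i + n_win] != 4
    return scores, valid


def scan_pwm(
    sequence: str, pwm: PWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> list[MotifHit]:
    """Scan both strands; hits where score >= score_fraction * max score.

    Coordinates are reported on the forward strand (window start).  Windows
    containing N are skipped; sequences shorter than the motif yield no hits.
    """
    code = _encode(sequence)
    w = pwm.width
    if code.size < w:
        return []
    lo = pwm.log_odds
    threshold = score_fraction * pwm.max_score - 1e-9   # fp-safe comparison
    hits = []
    fwd, fwd_ok = _window_scores(code, lo)
    # reverse-complement scan == scanning with the reversed-complemented PWM
    lo_rc = lo[::-1, _COMPLEMENT_IDX]
    rev, rev_ok = _window_scores(code, lo_rc)
    for off in np.flatnonzero(fwd_ok & (fwd >= threshold)):
        hits.append(MotifHit(int(off), "+", float(fwd[off])))
    for off in np.flatnonzero(rev_ok & (rev >= threshold)):
        hits.append(MotifHit(int(off), "-", float(rev[off])))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def has_hit(sequence: str, pwm: PWM,
            score_fraction: float = DEFAULT_SCORE_FRACTION) -> bool:
    """Presence/absence of >= 1 hit (the enrichment counting unit)."""
    code = _encode(sequence)
    w = pwm.width
    if code.size < w:
        return False
    threshold = score_fraction * pwm.max_score - 1e-9
    lo = pwm.log_odds
    for mat in (lo, lo[::-1, _COMPLEMENT_IDX]):
        scores, ok = _window_scores(code, mat)
        if (ok & (scores >= threshold)).any():
            return True
    return False


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_pvalue(fg_hits: int, fg_total: int, bg_hits: int, bg_total: int) -> float:
    """One-sided upper-tail P(X >= fg_hits) for fg_total draws from a pooled
    population of fg_total+bg_total sequences with fg_hits+bg_hits present."""
    if not (0 <= fg_hits <= fg_total and 0 <= bg_hits <= bg_total):
        raise InputError("hit counts must satisfy 0 <= hits <= totals")
    N = fg_total + bg_total
    K = fg_hits + bg_hits
    return float(stats.hypergeom.sf(fg_hits - 1, N, K, fg_total))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_results(rows: list[dict], alpha: float) -> pd.DataFrame:
    df = pd.DataFrame(
        rows, columns=["item", "fg_hits", "fg_total", "bg_hits", "bg_total", "p_value"]
    )
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df = df.sort_values(["p_value", "item"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["significant"] = df["q_value"] < alpha
    return df


def motif_enrichment(
    fg_sequences: list[str],
    bg_sequences: list[str],
    pwms: list[PWM],
    alpha: float = DEFAULT_ALPHA,
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    top_k: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-motif presence/absence hypergeometric enrichment of foreground
    over pooled foreground+background, BH-adjusted across motifs.

    Returns (all results ranked by ascending p, the significant top-k).
    A motif wider than every sequence simply scores zero hits (p = 1).
    """
    if not fg_sequences or not bg_sequences:
        raise InputError("foreground and background sequence sets must be non-empty")
    rows = []
    for pwm in pwms:
        fg = sum(has_hit(s, pwm, score_fraction) for s in fg_sequences)
        bg = sum(has_hit(s, pwm, score_fraction) for s in bg_sequences)
        rows.append(
            {
                "item": pwm.name,
                "fg_hits": fg,
                "fg_total": len(fg_sequences),
                "bg_hits": bg,
                "bg_total": len(bg_sequences),
                "p_value": hypergeom_pvalue(fg, len(fg_sequences), bg, len(bg_sequences)),
            }
        )
    results = _rank_results(rows, alpha)
    top = results[results["significant"]].head(top_k).reset_index(drop=True)
    return results, top


def term_enrichment(
    target_genes,
    universe,
    term_map: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Hypergeometric term over-representation of target genes in a universe.

    ``term_map`` has columns Gene, Term.  Terms with zero annotated genes in
    the universe are skipped; an empty target set yields an empty result.
    """
    targets = set(target_genes)
    uni = set(universe)
    outside = targets - uni
    if outside:
        raise InputError(f"target genes outside universe: {sorted(outside)[:5]}")
    if not targets:
        return _rank_results([], alpha)
    tm = term_map[term_map["Gene"].isin(uni)]
    rows = []
    for term, sub in tm.groupby("Term"):
        annotated = set(sub["Gene"])
        if not annotated:
            continue
        k = len(targets & annotated)
        rows.append(
            {
                "item": term,
                "fg_hits": k,
                "fg_total": len(targets),
                "bg_hits": len(annotated) - k,
                "bg_total": len(uni) - len(targets),
                "p_value": float(
                    stats.hypergeom.sf(k - 1, len(uni), len(annotated), len(targets))
                ),
            }
        )
    return _rank_results(rows, alpha)


# ---------------------------------------------------------------------------
# PWM text I/O
# ---------------------------------------------------------------------------

def write_pwms(pwms: list[PWM], path) -> None:
    """Simple matrix text: '>name' then w whitespace-separated A C G T rows."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_pwms(path) -> list[PWM]:
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM(name, np.array(rows)))
                name, rows = line[1:], []
            else:
                vals = np.array([float(v) for v in line.split()])
                rows.append(vals / vals.sum())
    if name is not None:
        pwms.append(PWM(name, np.array(rows)))
    return pwms
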