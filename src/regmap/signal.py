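"""Signal binning, normalisation, QC clustering, and Poisson binarization.

Counts are binned by read midpoint, z-scored with the population-SD
convention (``scipy.stats.zscore`` default), QC'd by pairwise Pearson
correlation and PCA at 1 kb resolution, and binarized per mark per tissue
against a genome-wide Poisson background: with lambda the mean count per
bin, the call threshold is the smallest integer c (>= 1) whose upper tail
``P(X >= c | Poisson(lambda))`` drops to the significance level (1e-4 by
default, the conventional strict default for this style of binarization).
Replicates are pooled by summing counts per bin before binarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InputError
from .hmm import ObservationMatrix

logger = logging.getLogger(__name__)

DEFAULT_BINARIZE_P = 1e-4
QC_BIN_SIZE = 1000


@dataclass
class BinnedTrack:
    """Per-chromosome binned signal (raw counts or normalised values)."""

    chromosome: str
    bin_size_bp: int
    values: np.ndarray = field(repr=False)
    mark: str | None = None
    tissue: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)

    @property
    def label(self) -> str:
        parts = [p for p in (self.tissue, self.mark) if p]
        if self.replicate is not None:
            parts.append(f"rep{self.replicate}")
        return "_".join(parts) if parts else self.chromosome


@dataclass
class BinaryTrack:
    """Per-chromosome 0/1 presence calls for one mark in one tissue."""

    chromosome: str
    bin_size_bp: int
    calls: np.ndarray = field(repr=False)
    mark: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.uint8)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def n_bins(chrom_length_bp: int, bin_size_bp: int) -> int:
    return -(-chrom_length_bp // bin_size_bp)     # ceil; last partial bin kept


def bin_intervals(
    intervals: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size_bp: int,
    mode: str = "midpoint",
    **track_meta,
) -> dict[str, BinnedTrack]:
    """Bin intervals into fixed-width bins, one track per chromosome.

    ``mode='midpoint'`` counts interval midpoints per bin (read counting);
    ``mode='coverage'`` sums a ``Value`` column weighted by bp overlap with
    each bin.  Intervals beyond the chromosome end raise an input error
    naming the record.
    """
    if bin_size_bp <= 0:
        raise ConfigurationError("bin_size_bp must be positive")
    out = {
        chrom: BinnedTrack(
            chrom, bin_size_bp,
            np.zeros(n_bins(size, bin_size_bp), dtype=float), **track_meta,
        )
        for chrom, size in chrom_sizes.items()
    }
    if len(intervals) == 0:
        return out
    for idx, row in enumerate(intervals.itertuples(index=False)):
        chrom, start, end = row.Chromosome, int(row.Start), int(row.End)
        if chrom not in chrom_sizes:
            raise InputError(f"record {idx}: unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        if start < 0 or end > size or end <= start:
            raise InputError(
                f"record {idx}: interval {chrom}:{start}-{end} outside [0, {size})"
            )
        track = out[chrom]
        if mode == "midpoint":
            track.values[((start + end) // 2) // bin_size_bp] += 1.0
        elif mode == "coverage":
            value = float(getattr(row, "Value", 1.0))
            b0, b1 = start // bin_size_bp, (end - 1) // bin_size_bp
            for b in range(b0, b1 + 1):
                lo, hi = max(start, b * bin_size_bp), min(end, (b + 1) * bin_size_bp)
                track.values[b] += value * (hi - lo) / (end - start)
        else:
            raise ConfigurationError(f"unknown binning mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# normalisation and QC
# ---------------------------------------------------------------------------

def zscore_track(track: BinnedTrack) -> BinnedTrack:
    """Z-score with population SD (ddof=0); a constant track maps to zeros."""
    v = np.asarray(track.values, dtype=float)
    if v.size == 0:
        raise InputError("cannot z-score an empty track")
    sd = v.std()
    z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    return BinnedTrack(track.chromosome, track.bin_size_bp, z,
                       track.mark, track.tissue, track.replicate)


def _concat_sample(tracks) -> np.ndarray:
    """A sample is a BinnedTrack or a list of them (one per chromosome)."""
    if isinstance(tracks, BinnedTrack):
        return np.asarray(tracks.values, dtype=float)
    return np.concatenate([np.asarray(t.values, dtype=float) for t in tracks])


def _sample_label(tracks, i: int) -> str:
    t = tracks if isinstance(tracks, BinnedTrack) else tracks[0]
    return t.label or f"sample{i}"


def pairwise_correlation(samples: list) -> pd.DataFrame:
    """Genome-wide Pearson correlation matrix between samples.

    Each sample is a BinnedTrack or per-chromosome list of BinnedTracks;
    all samples must share binning and total length.
    """
    vecs = [_concat_sample(s) for s in samples]
    if len({v.size for v in vecs}) != 1:
        raise InputError("samples differ in binned genome length")
    labels = [_sample_label(s, i) for i, s in enumerate(samples)]
    r = np.corrcoef(np.vstack(vecs))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=labels, columns=labels)


def pca_tracks(samples: list, n_components: int = 2):
    """PCA of samples over bins; returns (scores DataFrame, explained-variance
    fractions, non-increasing)."""
    if len(samples) < 2:
        raise InputError("PCA needs at least 2 samples")
    if n_components > len(samples):
        raise InputError("n_components exceeds sample count")
    mat = np.vstack([_concat_sample(s) for s in samples])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(mat)
    labels = [_sample_label(s, i) for i, s in enumerate(samples)]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=labels, columns=cols), pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def poisson_threshold(lam: float, p_threshold: float = DEFAULT_BINARIZE_P) -> int:
    """Smallest integer c >= 1 with P(X >= c | Poisson(lam)) <= p_threshold."""
    if lam < 0:
        raise InputError("lambda must be non-negative")
    if not 0 < p_threshold <= 1:
        raise ConfigurationError("p_threshold must be in (0, 1]")
    c = 1
    while stats.poisson.sf(c - 1, lam) > p_threshold:
        c += 1
    return c


def pool_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Sum counts per bin across replicate tracks of one tissue/mark/chrom."""
    first = tracks[0]
    for t in tracks[1:]:
        if (t.chromosome, t.bin_size_bp, len(t.values)) != (
            first.chromosome, first.bin_size_bp, len(first.values)
        ):
            raise InputError("replicate tracks differ in chromosome or binning")
    total = np.sum([np.asarray(t.values, dtype=float) for t in tracks], axis=0)
    return BinnedTrack(first.chromosome, first.bin_size_bp, total,
                       first.mark, first.tissue, None)


def binarize_poisson(
    track: BinnedTrack,
    p_threshold: float = DEFAULT_BINARIZE_P,
    lam: float | None = None,
) -> BinaryTrack:
    """Call a bin 1 iff its count reaches the Poisson tail threshold.

    ``lam`` defaults to the track's own mean; pass the genome-wide mean to
    share one background across chromosomes (see :func:`binarize_mark`).
    """
    counts = np.asarray(track.values, dtype=float)
    if counts.size and ((counts < 0).any() or (counts != np.round(counts)).any()):
        raise InputError("binarization expects non-negative integer counts")
    if lam is None:
        lam = float(counts.mean()) if counts.size else 0.0
    if lam == 0:
        logger.warning(
            "all-zero track %s/%s on %s: lambda-hat = 0, emitting all-zero calls",
            track.tissue, track.mark, track.chromosome,
        )
        calls = np.zeros(counts.size, dtype=np.uint8)
    else:
        calls = (counts >= poisson_threshold(lam, p_threshold)).astype(np.uint8)
    return BinaryTrack(track.chromosome, track.bin_size_bp, calls,
                       track.mark, track.tissue)


def binarize_mark(
    pooled_by_chrom: dict[str, BinnedTrack],
    p_threshold: float = DEFAULT_BINARIZE_P,
) -> dict[str, BinaryTrack]:
    """Binarize one tissue/mark with a single genome-wide lambda-hat."""
    total = sum(float(np.sum(t.values)) for t in pooled_by_chrom.values())
    nbins = sum(len(t.values) for t in pooled_by_chrom.values())
    lam = total / nbins if nbins else 0.0
    return {
        chrom: binarize_poisson(t, p_threshold, lam=lam)
        for chrom, t in pooled_by_chrom.items()
    }


def to_observation_matrix(
    binary_by_mark: dict[str, BinaryTrack],
    tissue: str,
    chromosome: str,
    mark_order: list[str],
) -> ObservationMatrix:
    """Stack per-mark binary calls into the HMM's bins × marks matrix."""
    missing = [m for m in mark_order if m not in binary_by_mark]
    if missing:
        raise InputError(f"missing binarized marks: {missing}")
    X = np.column_stack([binary_by_mark[m].calls for m in mark_order])
    return ObservationMatrix(tissue, chromosome, X, list(mark_order))


# ---------------------------------------------------------------------------
# track I/O
# ---------------------------------------------------------------------------

def write_bedgraph(path, tracks: list[BinnedTrack]) -> None:
    """Write binned values as bedGraph rows (all bins, including zeros)."""
    with open(path, "w") as fh:
        for t in tracks:
            bs = t.bin_size_bp
            for i, v in enumerate(t.values):
                val = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{t.chromosome}\t{i * bs}\t{(i + 1) * bs}\t{val}\n")


def read_bedgraph(path, bin_size_bp: int, **track_meta) -> dict[str, BinnedTrack]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["Chromosome", "Start", "End", "Value"])
    out = {}
    for chrom, sub in df.groupby("Chromosome", sort=False):
        nb = int(sub["End"].max()) // bin_size_bp + (
            1 if int(sub["End"].max()) % bin_size_bp else 0
        )
        vals = np.zeros(nb, dtype=float)
        vals[sub["Start"].to_numpy() // bin_size_bp] = sub["Value"].to_numpy()
        out[str(chrom)] = BinnedTrack(str(chrom), bin_size_bp, vals, **track_meta)
    return out


def write_binarized(path, tissue: str, chromosome: str,
                    binary_by_mark: dict[str, BinaryTrack],
                    mark_order: list[str]) -> None:
    """ChromHMM-compatible binarized text: header line with tissue and
    chromosome, one column per mark, one 0/1 row per bin."""
    X = np.column_stack([binary_by_mark[m].calls for m in mark_order])
    with open(path, "w") as fh:
        fh.write(f"{tissue}\t{chromosome}\n")
        fh.write("\t".join(mark_order) + "\n")
        np.savetxt(fh, X, fmt="%d", delimiter="\t")


def read_binarized(path, bin_size_bp: int):
    """Read the binarized text layout; returns (tissue, chromosome, tracks)."""
    with open(path) as fh:
        tissue, chromosome = fh.readline().rstrip("\n").split("\t")
        marks = fh.readline().rstrip("\n").split("\t")
        X = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
    tracks = {
        m: BinaryTrack(chromosome, bin_size_bp, X[:, j], m, tissue)
        for j, m in enumerate(marks)
    }
    return tissue, chromosome, tracks
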