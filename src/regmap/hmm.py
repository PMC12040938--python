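"""Multivariate Bernoulli-emission hidden Markov model over binarized marks.

The genome is a sequence of fixed-width bins; each bin carries a binary
presence call per chromatin mark.  A hidden state k emits mark m with
probability E[k, m], marks conditionally independent given the state, so a
bin's emission likelihood is ``prod_m E[k,m]^x (1-E[k,m])^(1-x)``.  One model
is learned jointly across all tissues and chromosomes (each a separate
sequence sharing the parameters), then decoded per tissue to obtain a
chromatin-state segmentation.

Numerics: scaled forward-backward (per-bin normalisation) rather than
log-space recursions, so the E-step weights are reused directly; emission
probabilities are floored to [1e-6, 1-1e-6] each M-step to keep likelihoods
finite.  Sequences up to ~1e7 bins are safe from underflow under this
scaling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

EMISSION_FLOOR = 1e-6
#: absolute log-likelihood change below which EM is declared converged
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 200
DEFAULT_RESTARTS = 3


# ---------------------------------------------------------------------------
# model and observation containers
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """HMM parameters: initial probs, transitions, Bernoulli emissions.

    ``emissionprob[k, m]`` is the probability that mark ``mark_order[m]`` is
    present (call = 1) in a bin of state ``k``.
    """

    startprob: np.ndarray          # (K,)
    transmat: np.ndarray           # (K, K), rows sum to 1
    emissionprob: np.ndarray       # (K, M) in [0, 1]
    mark_order: list[str]
    converged: bool = True

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.emissionprob = np.asarray(self.emissionprob, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_marks(self) -> int:
        return self.emissionprob.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        K = self.n_states
        if self.transmat.shape != (K, K):
            raise ConfigurationError("transition matrix shape mismatch")
        if self.emissionprob.shape[0] != K:
            raise ConfigurationError("emission matrix shape mismatch")
        if len(self.mark_order) != self.n_marks:
            raise ConfigurationError("mark_order length != emission columns")
        if not np.isclose(self.startprob.sum(), 1.0, atol=atol):
            raise ConfigurationError("initial probabilities do not sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=atol):
            raise ConfigurationError("transition rows do not sum to 1")
        if (self.emissionprob < 0).any() or (self.emissionprob > 1).any():
            raise ConfigurationError("emission probabilities outside [0, 1]")

    def permuted(self, perm: np.ndarray) -> "StateModel":
        """Return the model with states relabeled by ``perm`` (new[i] = old[perm[i]])."""
        perm = np.asarray(perm)
        return StateModel(
            startprob=self.startprob[perm],
            transmat=self.transmat[np.ix_(perm, perm)],
            emissionprob=self.emissionprob[perm],
            mark_order=list(self.mark_order),
            converged=self.converged,
        )


@dataclass
class ObservationMatrix:
    """Binary bins × marks matrix for one tissue on one chromosome."""

    tissue: str
    chromosome: str
    X: np.ndarray                  # (T, M) in {0, 1}
    mark_order: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        if self.X.ndim != 2:
            raise InputError("observation matrix must be 2-dimensional")
        if self.X.shape[1] != len(self.mark_order):
            raise InputError(
                f"observation columns ({self.X.shape[1]}) != mark_order "
                f"length ({len(self.mark_order)})"
            )
        if ((self.X != 0) & (self.X != 1)).any():
            raise InputError("observation entries must be 0/1")

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]


@dataclass
class Segmentation:
    """Ordered non-overlapping state-labeled intervals for one tissue.

    ``intervals`` columns: Chromosome, Start, End, State (0-based index);
    intervals are bin-aligned, sorted, and consecutive rows on a chromosome
    differ in state.
    """

    tissue: str
    intervals: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_model(
    K: int,
    M: int,
    seed: int,
    obs_list: list[ObservationMatrix],
    jitter: float = 0.1,
    emission_jitter: float = 0.4,
    strategy: str = "partition",
) -> StateModel:
    """Seeded initial model with perturbed-uniform transitions.

    ``strategy="partition"``: emissions from a random K-way partition of the
    observed bins (each group's per-mark call frequency seeds one state)
    plus a uniform perturbation of up to ``emission_jitter`` that breaks the
    near-symmetry of the partition means (with many bins every group mean
    collapses onto the marginal frequency, which strands EM in symmetric
    local optima).  K=1 reduces exactly to the observed frequencies.

    ``strategy="patterns"``: emissions seeded from the K most frequent
    distinct observed mark patterns (0.1/0.9 soft versions), so every
    common mark combination — including rare-but-coherent ones — starts
    with its own state; sticky transitions (0.9 self).
    """
    if K < 1 or M < 1:
        raise ConfigurationError("K and M must be >= 1")
    if strategy not in ("partition", "patterns"):
        raise ConfigurationError(f"unknown init strategy {strategy!r}")
    rng = np.random.default_rng(seed)

    start = 1.0 + jitter * rng.random(K)
    start /= start.sum()
    if strategy == "patterns" and K > 1:
        trans = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(trans, 0.9)
        trans *= 1.0 + jitter * rng.random((K, K))
        trans /= trans.sum(axis=1, keepdims=True)
    else:
        trans = 1.0 + jitter * rng.random((K, K))
        trans /= trans.sum(axis=1, keepdims=True)

    X = np.concatenate([o.X for o in obs_list], axis=0) if obs_list else None
    if X is None or X.shape[0] == 0:
        emis = rng.random((K, M))
    else:
        if X.shape[1] != M:
            raise ConfigurationError("obs mark count != M")
        overall = X.mean(axis=0)
        if strategy == "patterns" and K > 1:
            patterns, counts = np.unique(X, axis=0, return_counts=True)
            top = patterns[np.argsort(-counts)][:K].astype(float)
            emis = 0.1 + 0.8 * top
            while emis.shape[0] < K:               # fewer patterns than states
                emis = np.vstack([emis, np.clip(
                    overall + 0.2 * rng.uniform(-1, 1, M), 0.05, 0.95)])
        else:
            groups = rng.integers(0, K, size=X.shape[0])
            emis = np.tile(overall, (K, 1)).astype(float)
            for k in range(K):
                sel = groups == k
                if sel.any():
                    emis[k] = X[sel].mean(axis=0)
            if K > 1:
                emis = emis + emission_jitter * rng.uniform(-1.0, 1.0, size=(K, M))
    emis = np.clip(emis, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
    mark_order = obs_list[0].mark_order if obs_list else [f"mark{i}" for i in range(M)]
    model = StateModel(start, trans, emis, list(mark_order))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# scaled forward / backward
# ---------------------------------------------------------------------------

def _emission_matrix(model: StateModel, X: np.ndarray) -> np.ndarray:
    """Per-bin per-state emission likelihood, shape (T, K)."""
    E = np.clip(model.emissionprob, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
    logB = X @ np.log(E).T + (1 - X) @ np.log1p(-E).T
    return np.exp(logB)


def _check_obs(model: StateModel, obs: ObservationMatrix) -> None:
    if obs.X.shape[1] != model.n_marks:
        raise InputError(
            f"observation has {obs.X.shape[1]} marks, model expects {model.n_marks}"
        )


def _forward_batch(model: StateModel, Xs: np.ndarray):
    """Scaled forward pass over a batch of equal-length sequences.

    Xs: (S, T, M).  Returns (loglik (S,), alpha (S, T, K), scales (S, T),
    B (S, T, K)).
    """
    S, T, M = Xs.shape
    K = model.n_states
    B = _emission_matrix(model, Xs.reshape(S * T, M)).reshape(S, T, K)
    alpha = np.empty((S, T, K))
    scales = np.empty((S, T))
    a = model.startprob[None, :] * B[:, 0]
    c = a.sum(axis=1)
    c[c == 0] = np.finfo(float).tiny
    alpha[:, 0] = a / c[:, None]
    scales[:, 0] = c
    A = model.transmat
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c = a.sum(axis=1)
        c[c == 0] = np.finfo(float).tiny
        alpha[:, t] = a / c[:, None]
        scales[:, t] = c
    loglik = np.log(scales).sum(axis=1)
    return loglik, alpha, scales, B


def _backward_batch(model: StateModel, B: np.ndarray, scales: np.ndarray) -> np.ndarray:
    S, T, K = B.shape
    beta = np.empty((S, T, K))
    beta[:, T - 1] = 1.0
    A = model.transmat
    for t in range(T - 2, -1, -1):
        beta[:, t] = (B[:, t + 1] * beta[:, t + 1]) @ A.T / scales[:, t + 1][:, None]
    return beta


def log_likelihood(model: StateModel, obs: ObservationMatrix) -> float:
    """Scaled-forward log-likelihood of one observation sequence."""
    model.validate()
    _check_obs(model, obs)
    if obs.n_bins == 0:
        return 0.0
    ll, *_ = _forward_batch(model, obs.X[None, :, :].astype(float))
    return float(ll[0])


def total_log_likelihood(model: StateModel, obs_list: list[ObservationMatrix]) -> float:
    """Sum of per-sequence log-likelihoods (independent sequences, one model)."""
    return float(sum(log_likelihood(model, o) for o in obs_list))


def posterior_marginals(model: StateModel, obs: ObservationMatrix) -> np.ndarray:
    """Smoothed per-bin state marginals gamma, shape (T, K)."""
    model.validate()
    _check_obs(model, obs)
    if obs.n_bins == 0:
        return np.zeros((0, model.n_states))
    X = obs.X[None, :, :].astype(float)
    _, alpha, scales, B = _forward_batch(model, X)
    beta = _backward_batch(model, B, scales)
    gamma = alpha[0] * beta[0]
    return gamma / gamma.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def _group_by_length(obs_list: list[ObservationMatrix]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, o in enumerate(obs_list):
        groups.setdefault(o.n_bins, []).append(i)
    return groups


def baum_welch(
    model: StateModel,
    obs_list: list[ObservationMatrix],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[StateModel, list[float]]:
    """EM over multiple independent sequences sharing one model.

    Returns the refit model and the per-iteration total log-likelihood trace
    (evaluated at the model *before* each M-step, hence non-decreasing up to
    numerical slack).  Non-convergence at ``max_iter`` flags the model
    (``converged=False``) instead of raising.
    """
    if not obs_list:
        raise InputError("obs_list must be non-empty")
    model.validate()
    for o in obs_list:
        _check_obs(model, o)
    obs_list = [o for o in obs_list if o.n_bins > 0]
    groups = _group_by_length(obs_list)
    batches = {
        T: np.stack([obs_list[i].X for i in idx]).astype(float)
        for T, idx in groups.items()
    }

    cur = replace(model)
    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        K = cur.n_states
        start_acc = np.zeros(K)
        trans_acc = np.zeros((K, K))
        emis_num = np.zeros((K, cur.n_marks))
        emis_den = np.zeros(K)
        total_ll = 0.0
        A = cur.transmat
        for T, Xs in batches.items():
            ll, alpha, scales, B = _forward_batch(cur, Xs)
            beta = _backward_batch(cur, B, scales)
            total_ll += float(ll.sum())
            gamma = alpha * beta                     # (S, T, K); rows sum to 1
            start_acc += gamma[:, 0, :].sum(axis=0)
            if T > 1:
                # xi_t[i,j] = alpha_t[i] A[i,j] B_{t+1}[j] beta_{t+1}[j] / c_{t+1}
                w = B[:, 1:] * beta[:, 1:] / scales[:, 1:, None]   # (S, T-1, K)
                trans_acc += A * np.einsum("sti,stj->ij", alpha[:, :-1], w)
            emis_num += np.einsum("stk,stm->km", gamma, Xs)
            emis_den += gamma.sum(axis=(0, 1))
        trace.append(total_ll)
        if np.isfinite(prev_ll) and abs(total_ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = total_ll

        start = start_acc / start_acc.sum()
        trans = trans_acc.copy()
        rows = trans.sum(axis=1)
        dead = rows == 0
        trans[dead] = 1.0 / K
        trans[~dead] /= rows[~dead, None]
        emis = emis_num / np.maximum(emis_den, np.finfo(float).tiny)[:, None]
        emis = np.clip(emis, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
        cur = StateModel(start, trans, emis, cur.mark_order)
    else:
        logger.warning("EM did not converge in %d iterations", max_iter)
    cur.converged = converged
    return cur, trace


def learn_model(
    obs_list: list[ObservationMatrix],
    K: int,
    seed: int,
    n_restarts: int = DEFAULT_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[StateModel, list[float]]:
    """Best-of-``n_restarts`` Baum-Welch fit (restart r uses seed ``seed + r``).

    The first restart is initialised from the most frequent observed mark
    patterns; the remaining restarts use random partitions for diversity.
    """
    if not obs_list:
        raise InputError("obs_list must be non-empty")
    M = len(obs_list[0].mark_order)
    best: tuple[StateModel, list[float]] | None = None
    for r in range(n_restarts):
        strategy = "patterns" if r == 0 else "partition"
        m0 = init_model(K, M, seed + r, obs_list, strategy=strategy)
        fit, trace = baum_welch(m0, obs_list, tol=tol, max_iter=max_iter)
        if best is None or trace[-1] > best[1][-1]:
            best = (fit, trace)
        logger.info("restart %d: loglik %.3f (%d iters)", r, trace[-1], len(trace))
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# sampling and state matching
# ---------------------------------------------------------------------------

def sample_observations(
    model: StateModel, n_seqs: int, seq_len: int, seed: int,
    tissue: str = "sim",
) -> tuple[list[ObservationMatrix], list[np.ndarray]]:
    """Draw observation sequences (and their hidden paths) from the model."""
    model.validate()
    rng = np.random.default_rng(seed)
    K, M = model.n_states, model.n_marks
    cum_pi = np.cumsum(model.startprob)
    cum_A = np.cumsum(model.transmat, axis=1)
    obs_list, paths = [], []
    for s in range(n_seqs):
        u = rng.random(seq_len)
        path = np.empty(seq_len, dtype=int)
        path[0] = np.searchsorted(cum_pi, u[0], side="right")
        for t in range(1, seq_len):
            path[t] = np.searchsorted(cum_A[path[t - 1]], u[t], side="right")
        path = np.minimum(path, K - 1)
        X = (rng.random((seq_len, M)) < model.emissionprob[path]).astype(np.uint8)
        obs_list.append(ObservationMatrix(tissue, f"seq{s}", X, list(model.mark_order)))
        paths.append(path)
    return obs_list, paths


def best_state_permutation(reference: StateModel, fitted: StateModel) -> np.ndarray:
    """Permutation p minimising total |E_fit[p] - E_ref| (optimal matching)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(
        reference.emissionprob[:, None, :] - fitted.emissionprob[None, :, :]
    ).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols


# ---------------------------------------------------------------------------
# decoding and segmentation
# ---------------------------------------------------------------------------

_VITERBI_TIE_TOL = 1e-9


def _argmax_low(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    """First index whose value is within a tolerance of the max.

    Exact ties (e.g. symmetric models) accumulate one-ulp asymmetries in the
    DP, so a strict argmax would break them arbitrarily; this resolves them
    toward the lower state index.
    """
    mx = arr.max(axis=axis, keepdims=True)
    return np.argmax(arr >= mx - _VITERBI_TIE_TOL, axis=axis)


def viterbi(model: StateModel, obs: ObservationMatrix) -> np.ndarray:
    """Maximum-joint-probability state path; ties break to the lower index."""
    model.validate()
    _check_obs(model, obs)
    T = obs.n_bins
    if T == 0:
        return np.zeros(0, dtype=int)
    K = model.n_states
    E = np.clip(model.emissionprob, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
    X = obs.X.astype(float)
    logB = X @ np.log(E).T + (1 - X) @ np.log1p(-E).T
    with np.errstate(divide="ignore"):
        logA = np.log(model.transmat)
        logpi = np.log(model.startprob)
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA          # (from, to)
        psi[t] = _argmax_low(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(_argmax_low(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def decode(model: StateModel, obs: ObservationMatrix, method: str = "viterbi") -> np.ndarray:
    """State path by ``viterbi`` (joint argmax) or ``posterior`` (per-bin argmax)."""
    if method == "viterbi":
        return viterbi(model, obs)
    if method == "posterior":
        gamma = posterior_marginals(model, obs)
        return gamma.argmax(axis=1) if gamma.size else np.zeros(0, dtype=int)
    raise ConfigurationError(f"unknown decode method: {method!r}")


def segment(
    path: np.ndarray,
    bin_size_bp: int,
    chromosome: str,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Run-length encode a per-bin state path into bin-aligned intervals."""
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        return pd.DataFrame(columns=["Chromosome", "Start", "End", "State"])
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    df = pd.DataFrame(
        {
            "Chromosome": chromosome,
            "Start": starts * bin_size_bp,
            "End": ends * bin_size_bp,
            "State": path[starts],
        }
    )
    if tissue is not None:
        df["Tissue"] = tissue
    return df


def path_from_segments(intervals: pd.DataFrame, bin_size_bp: int) -> np.ndarray:
    """Inverse of :func:`segment` for a single chromosome's intervals."""
    if len(intervals) == 0:
        return np.zeros(0, dtype=int)
    n = int(intervals["End"].max()) // bin_size_bp
    path = np.zeros(n, dtype=int)
    for s, e, k in intervals[["Start", "End", "State"]].itertuples(index=False):
        path[s // bin_size_bp : e // bin_size_bp] = k
    return path


# ---------------------------------------------------------------------------
# model / segmentation I/O
# ---------------------------------------------------------------------------

def save_model(model: StateModel, path) -> None:
    payload = {
        "n_states": model.n_states,
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "emissionprob": model.emissionprob.tolist(),
        "mark_order": list(model.mark_order),
        "converged": bool(model.converged),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> StateModel:
    with open(path) as fh:
        d = json.load(fh)
    model = StateModel(
        np.array(d["startprob"]),
        np.array(d["transmat"]),
        np.array(d["emissionprob"]),
        list(d["mark_order"]),
        converged=bool(d.get("converged", True)),
    )
    model.validate()
    return model


def write_emissions_table(model: StateModel, path) -> None:
    """Tab-separated per-state emission table (states numbered from 1)."""
    df = pd.DataFrame(model.emissionprob, columns=model.mark_order)
    df.insert(0, "State", np.arange(1, model.n_states + 1))
    df.to_csv(path, sep="\t", index=False)


def write_segmentation_bed(seg: Segmentation, path) -> None:
    """BED4 with state names E1..EK (states numbered from 1, browser style)."""
    df = seg.intervals.copy()
    df["Name"] = "E" + (df["State"] + 1).astype(str)
    df[["Chromosome", "Start", "End", "Name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_segmentation_bed(path, tissue: str) -> Segmentation:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["Chromosome", "Start", "End", "Name"])
    df["State"] = df["Name"].str.lstrip("E").astype(int) - 1
    return Segmentation(tissue, df[["Chromosome", "Start", "End", "State"]])
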