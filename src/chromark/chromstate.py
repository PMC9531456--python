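"""Binarization and multivariate Bernoulli-emission HMM segmentation.

Coverage tracks are reduced to 200-bp presence/absence calls by a
Poisson upper-tail test against the genome-wide mean bin count, then a
K-state HMM with per-state independent Bernoulli channel emissions is
fitted by Baum-Welch.  Channels are histone marks in the per-tissue
mode, or tissues in the one-mark-across-tissues mode — the model is
agnostic.  Chromosomes are independent sequences.

Decoding is posterior-max per bin (forward-backward); Viterbi is
available behind a flag.  All recursions use per-position scaling, so
sequences of 1e7 bins do not underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .io_formats import GenomicInterval, SignalTrack

__all__ = [
    "BinarizedTracks",
    "ChromHMMModel",
    "StateSegmentation",
    "binarize",
    "binarize_tracks",
    "poisson_presence_threshold",
    "fit_hmm",
    "segment",
    "state_enrichment",
    "compare_models",
    "hungarian_match",
]

_EPS = 1e-10


def poisson_presence_threshold(lam: float, p_threshold: float) -> int:
    """Smallest count c with P(X >= c | lam) <= p_threshold."""
    if lam <= 0:
        return 1  # any positive count is called present
    c = 0
    while stats.poisson.sf(c - 1, lam) > p_threshold:
        c += 1
    return c


def binarize(
    track: SignalTrack,
    chrom_sizes: Mapping[str, int] | None = None,
    bin_size: int = 200,
    p_threshold: float = 1e-4,
) -> tuple[dict[str, np.ndarray], float]:
    """Per-bin counts -> presence calls via a Poisson upper-tail test.

    Count c = round(sum of value x width in the bin); lambda is the
    genome-wide mean bin count; bin = 1 iff P(X >= c | lambda) <=
    ``p_threshold``.  An all-zero track yields all zeros.
    """
    sizes = chrom_sizes or track.chrom_sizes
    if sizes is None:
        raise ValueError("chromosome sizes required for binarization")
    counts: dict[str, np.ndarray] = {}
    for chrom in sorted(sizes):
        size = sizes[chrom]
        n_bins = -(-size // bin_size)
        c = np.zeros(n_bins)
        if chrom in track.data:
            s, e, v = track.data[chrom]
            # per-bp coverage via a difference array, then fold into bins
            diff = np.zeros(n_bins * bin_size + 1)
            np.add.at(diff, s, v)
            np.add.at(diff, e, -v)
            per_bp = np.cumsum(diff[:-1])
            c = per_bp.reshape(n_bins, bin_size).sum(axis=1)
        counts[chrom] = np.rint(c)
    total = np.concatenate(list(counts.values()))
    lam = float(total.mean()) if len(total) else 0.0
    if lam == 0:
        return {c: np.zeros(len(v), dtype=np.uint8) for c, v in counts.items()}, 0.0
    cut = poisson_presence_threshold(lam, p_threshold)
    return (
        {c: (v >= cut).astype(np.uint8) for c, v in counts.items()},
        lam,
    )


@dataclass
class BinarizedTracks:
    """Binary bins x channels per chromosome (fixed 200-bp grid)."""

    bin_size: int
    channels: list[str]
    data: dict[str, np.ndarray]  # chrom -> (n_bins, n_channels) uint8
    lambdas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, m in self.data.items():
            if m.ndim != 2 or m.shape[1] != len(self.channels):
                raise ValueError(f"{chrom}: matrix shape mismatch")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{chrom}: entries must be binary")

    @property
    def n_bins(self) -> int:
        return sum(m.shape[0] for m in self.data.values())

    def stacked(self) -> np.ndarray:
        return np.vstack([self.data[c] for c in sorted(self.data)])


def binarize_tracks(
    tracks: Mapping[str, SignalTrack],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 200,
    p_threshold: float = 1e-4,
) -> BinarizedTracks:
    channels = list(tracks)
    per_channel = {}
    lambdas = {}
    for name in channels:
        calls, lam = binarize(tracks[name], chrom_sizes, bin_size, p_threshold)
        per_channel[name] = calls
        lambdas[name] = lam
    data = {}
    for chrom in sorted(chrom_sizes):
        data[chrom] = np.column_stack(
            [per_channel[name][chrom] for name in channels]
        ).astype(np.uint8)
    return BinarizedTracks(
        bin_size=bin_size, channels=channels, data=data, lambdas=lambdas
    )


@dataclass
class ChromHMMModel:
    emissions: np.ndarray  # K x M, P(channel present | state)
    transitions: np.ndarray  # K x K row-stochastic
    initial: np.ndarray  # K
    channels: list[str]
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.emissions.shape[0]
        if self.transitions.shape != (K, K) or self.initial.shape != (K,):
            raise ValueError("inconsistent model shapes")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emissions must lie in [0,1]")

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "emissions": self.emissions.tolist(),
                    "transitions": self.transitions.tolist(),
                    "initial": self.initial.tolist(),
                    "channels": self.channels,
                    "loglik_trace": self.loglik_trace,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ChromHMMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            emissions=np.array(d["emissions"]),
            transitions=np.array(d["transitions"]),
            initial=np.array(d["initial"]),
            channels=list(d["channels"]),
            loglik_trace=list(d.get("loglik_trace", [])),
        )


def _log_obs(X: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """T x K log P(x_t | state k) for binary X (T x M)."""
    E = np.clip(emissions, _EPS, 1 - _EPS)
    return X @ np.log(E).T + (1 - X) @ np.log(1 - E).T


try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _fb_core(B, transitions, initial):  # pragma: no cover - jitted
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = initial[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * transitions[i, j]
            alpha[t, j] = a * B[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                bb = B[t + 1, j] * beta[t + 1, j]
                b += transitions[i, j] * bb
                xi_sum[i, j] += (
                    alpha[t, i] * transitions[i, j] * bb / c[t + 1]
                )
            beta[t, i] = b / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        s = 0.0
        for k in range(K):
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s
    return gamma, xi_sum, np.log(c).sum()


def _forward_backward(
    logB: np.ndarray, transitions: np.ndarray, initial: np.ndarray
):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    # shift logB per position for stability before exponentiating
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)
    gamma, xi_sum, logc = _fb_core(
        B, np.ascontiguousarray(transitions), np.ascontiguousarray(initial)
    )
    return gamma, xi_sum, float(logc + shift.sum())


def _init_params(
    X: np.ndarray, K: int, rng: np.random.Generator, restart: int
):
    if restart == 0:
        km = KMeans(
            n_clusters=K, n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X + rng.normal(0, 1e-3, size=X.shape))
        emissions = np.vstack(
            [
                X[km.labels_ == k].mean(axis=0)
                if (km.labels_ == k).any()
                else rng.random(X.shape[1])
                for k in range(K)
            ]
        )
    else:
        emissions = rng.random((K, X.shape[1]))
    emissions = np.clip(emissions, 0.05, 0.95)
    transitions = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(transitions, 0.9)
    transitions /= transitions.sum(axis=1, keepdims=True)
    initial = np.full(K, 1.0 / K)
    return emissions, transitions, initial


def fit_hmm(
    data: BinarizedTracks,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    n_restarts: int = 3,
) -> ChromHMMModel:
    """Baum-Welch EM for a K-state Bernoulli-channel HMM.

    Chromosomes are independent sequences; the best of ``n_restarts``
    seeded initializations (restart 0 = K-means on bin patterns) is
    returned.  The log-likelihood trace of the winning run is stored on
    the model and is non-decreasing by the EM guarantee.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    seqs = [data.data[c].astype(float) for c in sorted(data.data)]
    total_bins = sum(len(s) for s in seqs)
    if K > total_bins:
        raise ValueError("more states than bins")
    X_all = np.vstack(seqs)

    if K == 1:
        em = X_all.mean(axis=0, keepdims=True)
        E = np.clip(em, _EPS, 1 - _EPS)
        ll = float(
            (X_all * np.log(E) + (1 - X_all) * np.log(1 - E)).sum()
        )
        return ChromHMMModel(
            emissions=em, transitions=np.ones((1, 1)), initial=np.ones(1),
            channels=list(data.channels), loglik_trace=[ll],
        )

    best: ChromHMMModel | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, restart])
        emissions, transitions, initial = _init_params(X_all, K, rng, restart)
        trace: list[float] = []
        for _ in range(max_iter):
            gamma_sum = np.zeros(K)
            gamma_x = np.zeros((K, X_all.shape[1]))
            xi_total = np.zeros((K, K))
            init_acc = np.zeros(K)
            loglik = 0.0
            for X in seqs:
                logB = _log_obs(X, emissions)
                gamma, xi_sum, ll = _forward_backward(
                    logB, transitions, initial
                )
                loglik += ll
                gamma_sum += gamma.sum(axis=0)
                gamma_x += gamma.T @ X
                xi_total += xi_sum
                init_acc += gamma[0]
            trace.append(loglik)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break
            # M-step
            emissions = gamma_x / np.maximum(gamma_sum[:, None], _EPS)
            row = xi_total.sum(axis=1, keepdims=True)
            transitions = np.where(
                row > _EPS, xi_total / np.maximum(row, _EPS),
                np.full((K, K), 1.0 / K),
            )
            transitions /= transitions.sum(axis=1, keepdims=True)
            initial = init_acc / init_acc.sum()
        model = ChromHMMModel(
            emissions=np.clip(emissions, 0.0, 1.0),
            transitions=transitions,
            initial=initial,
            channels=list(data.channels),
            loglik_trace=trace,
        )
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    return best


@dataclass
class StateSegmentation:
    bin_size: int
    labels: dict[str, np.ndarray]  # chrom -> int array, states 1..K
    posterior: dict[str, np.ndarray]  # chrom -> max posterior per bin
    n_states: int

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.labels):
                lab = self.labels[chrom]
                if len(lab) == 0:
                    continue
                change = np.flatnonzero(np.diff(lab)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(lab)]))
                for a, b in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{a * self.bin_size}\t{b * self.bin_size}"
                        f"\tE{lab[a]}\n"
                    )


def segment(
    model: ChromHMMModel, data: BinarizedTracks, viterbi: bool = False
) -> StateSegmentation:
    """Per-bin state labels: posterior max (default) or Viterbi path."""
    if model.channels != data.channels:
        raise ValueError("model/data channel mismatch")
    labels, post = {}, {}
    for chrom in sorted(data.data):
        X = data.data[chrom].astype(float)
        if len(X) == 0:
            labels[chrom] = np.array([], dtype=int)
            post[chrom] = np.array([])
            continue
        logB = _log_obs(X, model.emissions)
        if viterbi:
            path = _viterbi(logB, model.transitions, model.initial)
            labels[chrom] = path + 1
            post[chrom] = np.ones(len(path))
        else:
            gamma, _, _ = _forward_backward(
                logB, model.transitions, model.initial
            )
            labels[chrom] = gamma.argmax(axis=1) + 1
            post[chrom] = gamma.max(axis=1)
    return StateSegmentation(
        bin_size=data.bin_size, labels=labels, posterior=post,
        n_states=model.n_states,
    )


def posteriors(model: ChromHMMModel, X: np.ndarray) -> np.ndarray:
    """Forward-backward posterior matrix for one binary sequence."""
    logB = _log_obs(X.astype(float), model.emissions)
    gamma, _, _ = _forward_backward(logB, model.transitions, model.initial)
    return gamma


def _viterbi(
    logB: np.ndarray, transitions: np.ndarray, initial: np.ndarray
) -> np.ndarray:
    T, K = logB.shape
    logA = np.log(np.clip(transitions, _EPS, None))
    delta = np.log(np.clip(initial, _EPS, None)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def state_enrichment(
    seg: StateSegmentation,
    elements: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Fold enrichment of each state over each named element set.

    enrichment(k, e) = (bins in state k overlapping e / bins in state k)
    / (bins overlapping e / total bins); a bin overlaps an element when
    they share >= 1 bp.  Empty states yield NaN.
    """
    total_bins = sum(len(v) for v in seg.labels.values())
    bs = seg.bin_size
    overlap_masks = {}
    for name, ivs in elements.items():
        masks = {
            chrom: np.zeros(len(lab), dtype=bool)
            for chrom, lab in seg.labels.items()
        }
        for iv in ivs:
            if iv.chrom not in masks:
                continue
            b0 = iv.start // bs
            b1 = -(-iv.end // bs)
            masks[iv.chrom][b0:b1] = True
        overlap_masks[name] = masks
    rows = {}
    for k in range(1, seg.n_states + 1):
        in_state = {
            chrom: lab == k for chrom, lab in seg.labels.items()
        }
        n_state = sum(m.sum() for m in in_state.values())
        row = {}
        for name, masks in overlap_masks.items():
            n_elem = sum(m.sum() for m in masks.values())
            if n_state == 0 or n_elem == 0:
                row[name] = np.nan if n_state == 0 else 0.0
                continue
            n_both = sum(
                (in_state[c] & masks[c]).sum() for c in in_state
            )
            row[name] = (n_both / n_state) / (n_elem / total_bins)
        rows[f"E{k}"] = row
    return pd.DataFrame(rows).T


def compare_models(
    candidate: ChromHMMModel, reference: ChromHMMModel
) -> pd.DataFrame:
    """Best Pearson correlation of each candidate state's emission
    vector against any reference state; constant vectors give NaN."""
    if len(candidate.channels) < 2:
        raise ValueError("need >= 2 channels for emission correlation")
    if candidate.channels != reference.channels:
        raise ValueError("channel mismatch")
    rows = []
    for i, ev in enumerate(candidate.emissions):
        best_r, best_state = np.nan, -1
        if np.std(ev) > 0:
            for j, rv in enumerate(reference.emissions):
                if np.std(rv) == 0:
                    continue
                r = float(np.corrcoef(ev, rv)[0, 1])
                if np.isnan(best_r) or r > best_r:
                    best_r, best_state = r, j
        rows.append(
            dict(state=i + 1, best_correlation=best_r,
                 best_reference_state=best_state + 1)
        )
    return pd.DataFrame(rows)


def hungarian_match(
    emissions_a: np.ndarray, emissions_b: np.ndarray
) -> np.ndarray:
    """Permutation mapping states of A onto states of B maximizing the
    summed emission correlation (falls back to negative squared distance
    for constant rows)."""
    Ka, Kb = len(emissions_a), len(emissions_b)
    cost = np.zeros((Ka, Kb))
    for i in range(Ka):
        for j in range(Kb):
            a, b = emissions_a[i], emissions_b[j]
            if np.std(a) > 0 and np.std(b) > 0:
                cost[i, j] = -np.corrcoef(a, b)[0, 1]
            else:
                cost[i, j] = ((a - b) ** 2).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(Ka, dtype=int)
    perm[rows] = cols
    return perm
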