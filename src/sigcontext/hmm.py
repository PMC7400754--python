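"""Composite mutagenesis-related epigenomic (MRE) states.

A multivariate hidden Markov model with independent Bernoulli emissions per
binary feature (chromHMM-style) segments the binned genome into K composite
states. Training is joint across cell types: all per-cell-type, per-chromosome
binary matrices are pooled as independent sequences sharing one parameter set
(so the interpretation of a state is invariant across cell types), and the
Baum-Welch EM algorithm fits initial, transition, and emission parameters.
Decoding is per cell type by posterior-marginal argmax (forward-backward).

Numerics: forward-backward uses per-position scaling, so the per-sequence log
likelihood is the sum of log scaling factors; all probability parameters are
floored at 1e-6 to prevent EM absorption at the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import BinnedTrack

logger = logging.getLogger(__name__)

__all__ = [
    "MREModel",
    "StateAnnotation",
    "train_mre",
    "decode_states",
    "enrichment_scores",
    "state_correspondence",
]

_FLOOR = 1e-6


@dataclass
class MREModel:
    """HMM parameters: initial (K), transition (K, K), Bernoulli emission (K, F)."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    train_log: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        K = self.initial.shape[0]
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K x K")
        if self.emission.ndim != 2 or self.emission.shape[0] != K:
            raise ValueError("emission must be K x F")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-6):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.emission.shape[1])]

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    @property
    def n_features(self) -> int:
        return self.emission.shape[1]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
            "feature_names": self.feature_names,
            "train_log": self.train_log,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MREModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            np.array(obj["initial"]),
            np.array(obj["transition"]),
            np.array(obj["emission"]),
            list(obj["feature_names"]),
            list(obj.get("train_log", [])),
        )


@dataclass
class StateAnnotation:
    """Per-bin decoded state labels (1-based, in 1..K) for one cell type."""

    cell_type: str
    bin_size: int
    labels: dict[str, np.ndarray]  # chrom -> int array of 1-based state labels
    n_states: int

    def concat(self, chrom_order: Sequence[str] | None = None) -> np.ndarray:
        order = list(chrom_order) if chrom_order is not None else list(self.labels)
        return np.concatenate([self.labels[c] for c in order])

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.labels):
                lab = self.labels[chrom]
                # run-length encode identical neighbours
                start = 0
                for i in range(1, len(lab) + 1):
                    if i == len(lab) or lab[i] != lab[start]:
                        fh.write(
                            f"{chrom}\t{start * self.bin_size}\t{i * self.bin_size}\tE{lab[start]}\n"
                        )
                        start = i


def _emission_logprob(obs: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """(T, K) log P(obs_t | state k) for binary obs (T, F) under Bernoulli emissions."""
    p = np.clip(emission, _FLOOR, 1 - _FLOOR)
    return obs @ np.log(p).T + (1 - obs) @ np.log(1 - p).T


def _forward_backward(log_b: np.ndarray, initial: np.ndarray, transition: np.ndarray):
    """Scaled forward-backward.

    Returns (gamma (T,K) posteriors, xi_sum (K,K) summed pair posteriors,
    loglik scalar).
    """
    T, K = log_b.shape
    # scale emission likelihoods per row to avoid underflow before scaling proper
    log_b_max = log_b.max(axis=1, keepdims=True)
    b = np.exp(log_b - log_b_max)  # (T, K), each row max 1
    alpha = np.empty((T, K))
    c = np.empty(T)  # scaling factors
    alpha[0] = initial * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transition) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        x = (alpha[t][:, None] * transition) * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += x
    loglik = float(np.log(c).sum() + log_b_max.sum())
    return gamma, xi_sum, loglik


def sequence_loglik(model: MREModel, obs: np.ndarray) -> float:
    """Log marginal likelihood of one binary observation matrix under the model."""
    obs = np.asarray(obs, dtype=float)
    log_b = _emission_logprob(obs, model.emission)
    _, _, ll = _forward_backward(log_b, model.initial, model.transition)
    return ll


def _as_sequences(observations) -> list[np.ndarray]:
    """Flatten the per-cell-type, per-chromosome structure into a sequence list."""
    seqs: list[np.ndarray] = []
    if isinstance(observations, np.ndarray):
        observations = [observations]
    elif isinstance(observations, dict):
        observations = [observations]
    for item in observations:
        if isinstance(item, np.ndarray):
            seqs.append(np.asarray(item, dtype=float))
        elif isinstance(item, dict):
            for v in item.values():
                seqs.append(np.asarray(v, dtype=float))
        else:  # nested list per cell type
            for v in item:
                seqs.append(np.asarray(v, dtype=float))
    for s in seqs:
        if s.ndim != 2:
            raise ValueError("each observation sequence must be a (bins, features) matrix")
        if not np.isin(s, (0.0, 1.0)).all():
            raise ValueError("observations must be binary 0/1")
    if not seqs:
        raise ValueError("empty observations")
    F = {s.shape[1] for s in seqs}
    if len(F) != 1:
        raise ValueError(f"sequences disagree on feature count: {sorted(F)}")
    return seqs


def _init_params(seqs: list[np.ndarray], K: int, rng: np.random.Generator):
    F = seqs[0].shape[1]
    means = np.concatenate(seqs).mean(axis=0)
    emission = np.clip(means[None, :] + rng.uniform(-0.1, 0.1, size=(K, F)), _FLOOR, 1 - _FLOOR)
    # sticky prior: 0.8 self-transition, rest spread uniformly
    transition = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(transition, 0.8 if K > 1 else 1.0)
    transition /= transition.sum(axis=1, keepdims=True)
    initial = np.full(K, 1.0 / K)
    return initial, transition, emission


def train_mre(
    observations,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    restarts: int = 3,
    feature_names: Sequence[str] | None = None,
) -> MREModel:
    """Fit a K-state Bernoulli HMM jointly over all sequences by Baum-Welch EM.

    ``observations`` may be a single (bins, features) binary matrix, a list of
    them, or a list of per-cell-type dicts/lists of per-chromosome matrices;
    every matrix is treated as an independent chain restarting from the
    initial distribution (chromosome boundaries break the chain). The best of
    ``restarts`` seeded EM runs (by final log likelihood) is returned; its
    per-iteration log-likelihood trace is in ``train_log`` and is
    non-decreasing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    seqs = _as_sequences(observations)
    F = seqs[0].shape[1]
    if F < 1:
        raise ValueError("need at least one feature")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(F)]

    if K == 1:  # closed form: no hidden structure
        means = np.concatenate(seqs).mean(axis=0)
        model = MREModel(np.ones(1), np.ones((1, 1)), means[None, :].clip(_FLOOR, 1 - _FLOOR), names)
        model.train_log = [sum(sequence_loglik(model, s) for s in seqs)]
        return model

    best: MREModel | None = None
    root = np.random.default_rng(seed)
    for r in range(restarts):
        rng = np.random.default_rng(root.integers(2**31))
        initial, transition, emission = _init_params(seqs, K, rng)
        trace: list[float] = []
        prev_ll = -np.inf
        for it in range(max_iter):
            init_acc = np.zeros(K)
            xi_acc = np.zeros((K, K))
            gamma_sum = np.zeros(K)
            gamma_obs = np.zeros((K, F))
            ll = 0.0
            for s in seqs:
                log_b = _emission_logprob(s, emission)
                gamma, xi, l = _forward_backward(log_b, initial, transition)
                init_acc += gamma[0]
                xi_acc += xi
                gamma_sum += gamma.sum(axis=0)
                gamma_obs += gamma.T @ s
                ll += l
            trace.append(ll)
            if ll - prev_ll < tol and it > 0:
                break
            prev_ll = ll
            initial = np.clip(init_acc / init_acc.sum(), _FLOOR, None)
            initial /= initial.sum()
            transition = np.clip(xi_acc, _FLOOR, None)
            transition /= transition.sum(axis=1, keepdims=True)
            emission = np.clip(gamma_obs / gamma_sum[:, None], _FLOOR, 1 - _FLOOR)
        cand = MREModel(initial, transition, emission, names, trace)
        if best is None or trace[-1] > best.train_log[-1]:
            best = cand
        logger.info("train_mre restart %d: loglik %.2f after %d iterations", r, trace[-1], len(trace))
    assert best is not None
    return best


def decode_states(
    model: MREModel,
    observations,
    cell_type: str = "cell",
    bin_size: int = 10_000,
) -> StateAnnotation:
    """Posterior-marginal decoding for one cell type.

    ``observations`` is a dict of per-chromosome (bins, features) binary
    matrices (or a single matrix, labelled "chr1"). Each bin gets the state
    with the highest forward-backward posterior; exact ties break to the
    lowest state index.
    """
    if isinstance(observations, np.ndarray):
        observations = {"chr1": observations}
    labels: dict[str, np.ndarray] = {}
    for chrom, obs in observations.items():
        obs = np.asarray(obs, dtype=float)
        if obs.shape[1] != model.n_features:
            raise ValueError(
                f"{chrom}: observation has {obs.shape[1]} features, model expects {model.n_features}"
            )
        log_b = _emission_logprob(obs, model.emission)
        gamma, _, _ = _forward_backward(log_b, model.initial, model.transition)
        # argmax returns the first (lowest) index on ties
        labels[chrom] = gamma.argmax(axis=1).astype(np.int64) + 1
    return StateAnnotation(cell_type, bin_size, labels, model.n_states)


def posterior_marginals(model: MREModel, obs: np.ndarray) -> np.ndarray:
    """(T, K) posterior state probabilities for one sequence (rows sum to 1)."""
    obs = np.asarray(obs, dtype=float)
    log_b = _emission_logprob(obs, model.emission)
    gamma, _, _ = _forward_backward(log_b, model.initial, model.transition)
    return gamma


def enrichment_scores(
    annotation: StateAnnotation,
    tracks: Sequence[BinnedTrack],
) -> np.ndarray:
    """Fold enrichment of each binary feature in each state.

    ``enrichment[s, f] = P(feature f | state s+1) / P(feature f)``; a feature
    absent genome-wide gives NaN (0/0 undefined).
    """
    K = annotation.n_states
    chroms = list(annotation.labels)
    lab = annotation.concat(chroms)
    out = np.empty((K, len(tracks)))
    for f, tr in enumerate(tracks):
        if tr.bin_size != annotation.bin_size:
            raise ValueError(f"track {tr.feature_name}: bin size mismatch")
        vals = np.concatenate([tr.values[c] for c in chroms]).astype(float)
        if len(vals) != len(lab):
            raise ValueError(f"track {tr.feature_name}: bin count mismatch")
        overall = vals.mean()
        for s in range(K):
            mask = lab == s + 1
            if overall == 0 or not mask.any():
                out[s, f] = np.nan
            else:
                out[s, f] = vals[mask].mean() / overall
    return out


def state_correspondence(
    annotation_a: StateAnnotation,
    annotation_b: StateAnnotation,
) -> np.ndarray:
    """Row-normalized overlap of a's states with b's states over shared bins.

    Entry (i, j) is the fraction of bins labelled i+1 in ``annotation_a``
    that are labelled j+1 in ``annotation_b``. Rows of states that occur sum
    to 1; an unused state's row is all zero.
    """
    if annotation_a.bin_size != annotation_b.bin_size:
        raise ValueError("bin size mismatch between annotations")
    chroms = sorted(set(annotation_a.labels) & set(annotation_b.labels))
    if sorted(annotation_a.labels) != sorted(annotation_b.labels):
        raise ValueError("annotations cover different chromosomes")
    la = annotation_a.concat(chroms)
    lb = annotation_b.concat(chroms)
    if len(la) != len(lb):
        raise ValueError("bin count mismatch between annotations")
    Ka, Kb = annotation_a.n_states, annotation_b.n_states
    M = np.zeros((Ka, Kb))
    np.add.at(M, (la - 1, lb - 1), 1.0)
    rowsum = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(rowsum > 0, M / rowsum, 0.0)
    return M
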