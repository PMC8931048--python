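"""Product-Bernoulli hidden Markov model over binarized mark tracks.

Baum-Welch EM with per-position scaling; sequences of equal length are
stacked into batches so the time loop vectorizes across samples and
chromosomes.  Chromosome boundaries break transitions: each sequence is
treated as an independent chain restarted from the initial distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ValidationError

__all__ = ["BernoulliHMM", "viterbi_brute_force"]

_EPS = 1e-300


def _log_emission(obs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """log b_k(o_t) for binary obs (T, M) against emissions (K, M) -> (T, K)."""
    logp = np.log(phi)
    logq = np.log1p(-phi)
    return obs @ (logp - logq).T + logq.sum(axis=1)


@dataclass
class BernoulliHMM:
    """K-state HMM emitting M conditionally independent Bernoulli marks."""

    K: int
    emissions: np.ndarray  # (K, M) in (0, 1)
    transitions: np.ndarray  # (K, K) row-stochastic
    initial: np.ndarray  # (K,)
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if self.emissions.shape[0] != self.K:
            raise ValidationError("emissions shape inconsistent with K")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValidationError("initial distribution must sum to 1")
        if np.any(self.emissions <= 0.0) or np.any(self.emissions >= 1.0):
            raise ValidationError("emission probabilities must lie in (0, 1)")

    @property
    def n_marks(self) -> int:
        return self.emissions.shape[1]

    # -- inference ---------------------------------------------------------

    def _batched(self, sequences: Sequence[np.ndarray]) -> list[tuple[np.ndarray, list[int]]]:
        """Group sequences by length into (batch array (B,T,M), original idx)."""
        groups: dict[int, list[int]] = {}
        for i, s in enumerate(sequences):
            groups.setdefault(s.shape[0], []).append(i)
        return [
            (np.stack([sequences[i].astype(float) for i in idx]), idx)
            for T, idx in sorted(groups.items())
        ]

    def _forward_backward(self, batch: np.ndarray):
        """Scaled forward-backward on a batch (B, T, M).

        Returns (loglik_per_seq (B,), gamma (B,T,K), xi_sum (K,K))."""
        B, T, _ = batch.shape
        K = self.K
        em = np.exp(
            np.einsum("btm,km->btk", batch, np.log(self.emissions / (1 - self.emissions)))
            + np.log1p(-self.emissions).sum(axis=1)
        )  # (B, T, K)
        em = np.maximum(em, _EPS)
        A = self.transitions
        alpha = np.empty((B, T, K))
        c = np.empty((B, T))
        a = self.initial * em[:, 0]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / c[:, 0, None]
        for t in range(1, T):
            a = (alpha[:, t - 1] @ A) * em[:, t]
            c[:, t] = a.sum(axis=1)
            alpha[:, t] = a / c[:, t, None]
        beta = np.empty((B, T, K))
        beta[:, T - 1] = 1.0
        xi_sum = np.zeros((K, K))
        for t in range(T - 2, -1, -1):
            w = beta[:, t + 1] * em[:, t + 1] / c[:, t + 1, None]
            beta[:, t] = w @ A.T
            xi_sum += A * (alpha[:, t].T @ w)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        return np.log(c).sum(axis=1), gamma, xi_sum

    def log_likelihood(self, sequences: Sequence[np.ndarray]) -> float:
        total = 0.0
        for batch, _ in self._batched(sequences):
            ll, _, _ = self._forward_backward(batch)
            total += ll.sum()
        return float(total)

    def posterior(self, sequence: np.ndarray) -> np.ndarray:
        """Per-position posterior state probabilities (T, K)."""
        _, gamma, _ = self._forward_backward(sequence[None].astype(float))
        return gamma[0]

    def viterbi(self, sequence: np.ndarray) -> np.ndarray:
        """Jointly most probable state path (ties to lowest state index)."""
        obs = np.asarray(sequence, dtype=float)
        T = obs.shape[0]
        logem = _log_emission(obs, self.emissions)
        logA = np.log(np.maximum(self.transitions, _EPS))
        delta = np.log(np.maximum(self.initial, _EPS)) + logem[0]
        back = np.zeros((T, self.K), dtype=np.intp)
        for t in range(1, T):
            scores = delta[:, None] + logA
            back[t] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + logem[t]
        path = np.empty(T, dtype=np.intp)
        path[T - 1] = int(delta.argmax())
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        return path

    # -- learning ----------------------------------------------------------

    @classmethod
    def fit(
        cls,
        sequences: Sequence[np.ndarray],
        K: int,
        n_restarts: int = 5,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 200,
    ) -> "BernoulliHMM":
        """Baum-Welch over all sequences; returns the best of n_restarts."""
        if K < 1:
            raise ValidationError("K must be >= 1")
        if not sequences:
            raise ValidationError("need at least one sequence")
        M = sequences[0].shape[1]
        rng = np.random.default_rng(seed)
        best: BernoulliHMM | None = None
        for _ in range(max(1, n_restarts)):
            model = cls._fit_once(sequences, K, M, rng, tol, max_iter)
            if best is None or model.loglik > best.loglik:
                best = model
        return best

    @classmethod
    def _fit_once(cls, sequences, K, M, rng, tol, max_iter) -> "BernoulliHMM":
        phi = rng.uniform(0.15, 0.85, size=(K, M))
        A = rng.dirichlet(np.full(K, 5.0), size=K) * 0.2 + 0.8 * np.eye(K) / 1.0
        A /= A.sum(axis=1, keepdims=True)
        pi = np.full(K, 1.0 / K)
        model = cls(K, phi, A, pi)
        prev_ll = -np.inf
        converged = False
        history: list[float] = []
        for _ in range(max_iter):
            ll_total = 0.0
            xi_acc = np.zeros((K, K))
            gamma0_acc = np.zeros(K)
            num = np.zeros((K, M))
            den = np.zeros(K)
            for batch, _ in model._batched(sequences):
                ll, gamma, xi = model._forward_backward(batch)
                ll_total += ll.sum()
                xi_acc += xi
                gamma0_acc += gamma[:, 0].sum(axis=0)
                num += np.einsum("btk,btm->km", gamma, batch)
                den += gamma.sum(axis=(0, 1))
            history.append(ll_total)
            if np.isfinite(prev_ll):
                rel = (ll_total - prev_ll) / max(abs(prev_ll), 1.0)
                if rel < -1e-10:
                    warnings.warn("EM log-likelihood decreased; numerical issue")
                if abs(rel) < tol:
                    converged = True
                    prev_ll = ll_total
                    break
            prev_ll = ll_total
            # M-step (smoothed to keep parameters interior)
            phi = (num + 0.5) / (den + 1.0)[:, None]
            A = xi_acc + 1e-6
            A /= A.sum(axis=1, keepdims=True)
            pi = gamma0_acc + 1e-6
            pi /= pi.sum()
            model = cls(K, phi, A, pi)
        if not converged:
            warnings.warn(f"EM did not converge within {max_iter} iterations")
        model.loglik = float(prev_ll)
        model.converged = converged
        model.loglik_history = history
        return model

    def n_parameters(self) -> int:
        K, M = self.K, self.n_marks
        return K * M + K * (K - 1) + (K - 1)

    def bic(self, sequences: Sequence[np.ndarray]) -> float:
        n = sum(s.shape[0] for s in sequences)
        return self.n_parameters() * np.log(n) - 2.0 * self.loglik


def viterbi_brute_force(model: BernoulliHMM, sequence: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration oracle for short sequences (testing aid)."""
    from itertools import product

    obs = np.asarray(sequence, dtype=float)
    T = obs.shape[0]
    logem = _log_emission(obs, model.emissions)
    logA = np.log(np.maximum(model.transitions, _EPS))
    logpi = np.log(np.maximum(model.initial, _EPS))
    best_path, best_score = None, -np.inf
    for path in product(range(model.K), repeat=T):
        s = logpi[path[0]] + logem[0, path[0]]
        for t in range(1, T):
            s += logA[path[t - 1], path[t]] + logem[t, path[t]]
        if s > best_score + 1e-12:
            best_score, best_path = s, path
    return np.array(best_path, dtype=np.intp)
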