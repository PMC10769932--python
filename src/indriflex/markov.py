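"""Per-singer transition matrices, stationary distributions, entropy rates.

Each singer's contributions are modeled as realizations of one first-order,
time-homogeneous Markov chain over the phrase alphabet.  Transition counts
are pooled across the singer's contributions but never across contribution
boundaries (the last token of one contribution does not "transition" to the
first token of the next).  The chain's unpredictability is its entropy
rate

    H = - sum_i  pi_i  sum_j  P_ij log P_ij        (0 * log 0 := 0)

the stationary-distribution-weighted average conditional entropy of the next
phrase given the current one.  Higher H means a less predictable, more
flexible singer; H is bounded by log(k) for a k-state chain, attained iff P
is uniform.

Empirical matrices from small samples are often reducible (states with no
way back).  For the stationary distribution the chain is restricted to its
largest recurrent communicating class; optional add-alpha smoothing (off by
default) restores irreducibility over the observed states instead.  The
restriction applied is recorded in the result.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Sequence

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .corpus import Contribution

__all__ = [
    "TransitionMatrix",
    "EntropyResult",
    "ReducibleChainError",
    "estimate_transition_matrix",
    "stationary_distribution",
    "entropy_rate",
    "simulate_entropy_rate",
    "singer_entropy",
    "entropy_table",
    "transition_matrix_frame",
]


class ReducibleChainError(ValueError):
    """No unique stationary distribution exists (and restriction is ambiguous)."""


@dataclasses.dataclass
class TransitionMatrix:
    """Observed transition counts and the row-normalized probabilities.

    ``states`` holds the ordered set of states actually observed; ``probs``
    rows with at least one outgoing transition sum to 1 (rows never observed
    as a source are left at zero and excluded from recurrent-class
    restriction).
    """

    states: tuple[Hashable, ...]
    counts: np.ndarray
    probs: np.ndarray
    smoothing_alpha: float = 0.0

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


def _tokens_of(seq) -> tuple:
    if isinstance(seq, Contribution):
        return tuple(t.value for t in seq.tokens)
    return tuple(getattr(t, "value", t) for t in seq)


def estimate_transition_matrix(
    sequences: Sequence,
    states: Sequence[Hashable] | None = None,
    smoothing_alpha: float = 0.0,
    singer_id: str = "",
) -> TransitionMatrix:
    """Pool transition counts over sequences and row-normalize.

    ``states`` fixes the state support and ordering; by default only the
    observed states are used, in first-appearance order.  ``smoothing_alpha``
    adds alpha pseudo-counts to every cell before normalizing (add-alpha
    smoothing; 0 = maximum-likelihood estimate).  Raises when the pooled
    sequences contain no transition at all.
    """
    seqs = [_tokens_of(s) for s in sequences]
    if states is None:
        order: dict = {}
        for s in seqs:
            for tok in s:
                order.setdefault(tok, len(order))
        states = tuple(order)
    else:
        states = tuple(states)
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    counts = np.zeros((k, k), dtype=np.int64)
    for s in seqs:
        for a, b in zip(s, s[1:]):
            counts[index[a], index[b]] += 1
    if counts.sum() == 0:
        who = f" for singer {singer_id!r}" if singer_id else ""
        raise ValueError(
            f"no transitions observed{who}: all sequences have length < 2"
        )
    work = counts.astype(float)
    if smoothing_alpha > 0:
        work += smoothing_alpha
    row_sums = work.sum(axis=1)
    probs = np.zeros_like(work)
    nz = row_sums > 0
    probs[nz] = work[nz] / row_sums[nz, None]
    return TransitionMatrix(states=states, counts=counts, probs=probs,
                            smoothing_alpha=smoothing_alpha)


def _recurrent_classes(P: np.ndarray) -> list[np.ndarray]:
    """Closed (recurrent) communicating classes of the chain's support graph."""
    adj = csr_matrix(P > 0)
    n_comp, labels = csgraph.connected_components(adj, directed=True,
                                                  connection="strong")
    classes = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        outside = np.setdiff1d(np.arange(P.shape[0]), members)
        if outside.size == 0 or not np.any(P[np.ix_(members, outside)] > 0):
            classes.append(members)
    return classes


def _restrict_to_recurrent(tm: TransitionMatrix) -> tuple[np.ndarray, np.ndarray, str]:
    """Indices of the class used for pi, its sub-matrix, and a note.

    Terminal states (observed only as targets, or whose every continuation
    leads out of the remaining support) are trimmed iteratively — a
    contribution's last token has no observed continuation, so such states
    carry no conditional-entropy information.  The surviving sub-chain is
    row-renormalized before its closed communicating classes are extracted.
    """
    n = tm.n_states
    active = np.arange(n)
    P_full = tm.probs
    trimmed = False
    while active.size:
        sub = P_full[np.ix_(active, active)]
        keep = sub.sum(axis=1) > 0
        if keep.all():
            break
        trimmed = True
        active = active[keep]
    if active.size == 0:
        raise ReducibleChainError(
            "chain has no recurrent class among observed source states"
        )
    sub = P_full[np.ix_(active, active)]
    sub = sub / sub.sum(axis=1, keepdims=True)

    classes = _recurrent_classes(sub)
    if not classes:
        raise ReducibleChainError(
            "chain has no recurrent class among observed source states"
        )
    if len(classes) == 1:
        local = classes[0]
    else:
        sizes = [len(c) for c in classes]
        best = max(sizes)
        top = [c for c in classes if len(c) == best]
        if len(top) > 1:
            raise ReducibleChainError(
                f"no unique stationary distribution: {len(classes)} recurrent "
                f"classes with tied largest size {best}"
            )
        local = top[0]
    idx = active[local]
    if len(idx) == n:
        note = ""
    else:
        note = "restricted to largest recurrent class" + (
            " after trimming terminal states" if trimmed else ""
        )
    sub = P_full[np.ix_(idx, idx)]
    sub = sub / sub.sum(axis=1, keepdims=True)
    return idx, sub, note


def stationary_distribution(
    tm: TransitionMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Stationary distribution pi with pi @ P = pi, sum(pi) = 1.

    For a :class:`TransitionMatrix` the chain is first restricted to its
    largest recurrent communicating class; the returned vector is over the
    full state set, with zero mass on dropped states.  Computed from the
    dominant left eigenvector, falling back to (Cesaro-averaged) power
    iteration when the eigensolver result is unusable.  Raises
    :class:`ReducibleChainError` when no unique pi exists.
    """
    if isinstance(tm, np.ndarray):
        tm = TransitionMatrix(
            states=tuple(range(tm.shape[0])),
            counts=np.zeros_like(tm, dtype=np.int64),
            probs=np.asarray(tm, dtype=float),
        )
    idx, P, _note = _restrict_to_recurrent(tm)
    pi_sub = _stationary_irreducible(P, tol=tol, max_iter=max_iter)
    pi = np.zeros(tm.n_states)
    pi[idx] = pi_sub
    return pi


def _stationary_irreducible(P: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    k = P.shape[0]
    if k == 1:
        return np.ones(1)
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    s = pi.sum()
    if s > 0:
        pi = pi / s
        if np.max(np.abs(pi @ P - pi)) < 1e-8:
            return pi
    # power iteration with running average (handles periodic chains)
    pi = np.full(k, 1.0 / k)
    avg = pi.copy()
    for it in range(1, max_iter + 1):
        pi = pi @ P
        avg += (pi - avg) / (it + 1)
        if it % 50 == 0 and np.max(np.abs(avg @ P - avg)) < tol:
            break
    return avg / avg.sum()


def entropy_rate(
    tm: TransitionMatrix | np.ndarray,
    pi: np.ndarray | None = None,
    log_base: float | None = None,
) -> float:
    """Entropy rate H = -sum_i pi_i sum_j P_ij log P_ij.

    Default units are nats (natural log); pass ``log_base=2`` for bits.
    ``pi`` defaults to the stationary distribution of ``tm``.
    """
    if isinstance(tm, np.ndarray):
        P = np.asarray(tm, dtype=float)
    else:
        P = tm.probs
    if pi is None:
        pi = stationary_distribution(tm)
    pi = np.asarray(pi, dtype=float)
    if pi.shape[0] != P.shape[0]:
        raise ValueError("pi dimension does not match the transition matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(P), 0.0)
    H = float(-np.sum(pi[:, None] * P * logP))
    if log_base is not None:
        H /= np.log(log_base)
    return max(H, 0.0)


def simulate_entropy_rate(
    tm: TransitionMatrix | np.ndarray,
    chain_length: int = 100_000,
    n_reps: int = 5,
    seed: int = 0,
    log_base: float | None = None,
) -> tuple[float, float]:
    """Simulation-based entropy rate: mean plug-in H over simulated chains.

    Each replicate simulates a chain of ``chain_length`` tokens started from
    the stationary distribution, re-estimates the transition matrix, and
    evaluates its analytic entropy rate.  Returns ``(mean, standard error)``;
    the mean converges to the analytic H of the generating matrix as the
    chain length grows.
    """
    if isinstance(tm, np.ndarray):
        P_full = np.asarray(tm, dtype=float)
        states = tuple(range(P_full.shape[0]))
        tm = TransitionMatrix(states=states,
                              counts=np.zeros_like(P_full, dtype=np.int64),
                              probs=P_full)
    idx, P, _ = _restrict_to_recurrent(tm)
    pi = _stationary_irreducible(P, tol=1e-12, max_iter=100_000)
    rng = np.random.default_rng(seed)
    k = P.shape[0]
    cum = np.cumsum(P, axis=1)
    values = np.empty(n_reps)
    for r in range(n_reps):
        states_sim = np.empty(chain_length, dtype=np.int64)
        states_sim[0] = rng.choice(k, p=pi)
        u = rng.random(chain_length - 1)
        for t in range(1, chain_length):
            states_sim[t] = np.searchsorted(cum[states_sim[t - 1]], u[t - 1],
                                            side="right")
        est = estimate_transition_matrix([tuple(states_sim)])
        values[r] = entropy_rate(est, log_base=log_base)
    se = float(values.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(values.mean()), se


@dataclasses.dataclass
class EntropyResult:
    """Entropy rate of one singer's pooled contribution chain."""

    singer_id: str
    states: tuple
    stationary: np.ndarray
    entropy_rate: float
    method: str  # "analytic" or "simulated"
    n_transitions: int
    note: str = ""


def singer_entropy(
    sequences: Sequence,
    singer_id: str = "",
    method: str = "analytic",
    smoothing_alpha: float = 0.0,
    log_base: float | None = None,
    chain_length: int = 100_000,
    n_reps: int = 5,
    seed: int = 0,
) -> EntropyResult:
    """Estimate one singer's entropy rate from their contributions.

    ``method="analytic"`` (canonical) evaluates H in closed form from the
    empirical matrix; ``method="simulated"`` mirrors the simulation-based
    procedure (simulate long chains from the empirical matrix, re-estimate,
    average the plug-in H).
    """
    tm = estimate_transition_matrix(sequences, smoothing_alpha=smoothing_alpha,
                                    singer_id=singer_id)
    idx, P, note = _restrict_to_recurrent(tm)
    pi_sub = _stationary_irreducible(P, tol=1e-12, max_iter=100_000)
    pi = np.zeros(tm.n_states)
    pi[idx] = pi_sub
    if method == "analytic":
        H = entropy_rate(tm.probs[np.ix_(idx, idx)], pi_sub, log_base=log_base)
    elif method == "simulated":
        H, _se = simulate_entropy_rate(tm, chain_length=chain_length,
                                       n_reps=n_reps, seed=seed,
                                       log_base=log_base)
    else:
        raise ValueError("method must be 'analytic' or 'simulated'")
    return EntropyResult(
        singer_id=singer_id,
        states=tm.states,
        stationary=pi,
        entropy_rate=H,
        method=method,
        n_transitions=tm.n_transitions,
        note=note,
    )


def entropy_table(
    corpus,
    method: str = "analytic",
    smoothing_alpha: float = 0.0,
    log_base: float | None = None,
    seed: int = 0,
) -> "pd.DataFrame":
    """Per-singer entropy rates over a whole corpus.

    Singers whose pooled chain admits no entropy rate (no transitions, or an
    ambiguous recurrent structure) are reported with NaN and an explanatory
    note rather than dropped silently.
    """
    import pandas as pd  # local import: keeps the numeric core pandas-free

    rows = []
    for sid, meta in corpus.singers.items():
        seqs = [c.tokens for c in corpus.contributions_of(sid)]
        try:
            res = singer_entropy(seqs, singer_id=sid, method=method,
                                 smoothing_alpha=smoothing_alpha,
                                 log_base=log_base, seed=seed)
            H, n_tr, note = res.entropy_rate, res.n_transitions, res.note
        except (ValueError, ReducibleChainError) as exc:
            H, n_tr, note = float("nan"), 0, str(exc)
        rows.append(
            {
                "singer_id": sid,
                "category": meta.category,
                "group_id": meta.group_id,
                "entropy_rate": H,
                "method": method,
                "n_transitions": n_tr,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def transition_matrix_frame(tm: TransitionMatrix, kind: str = "probs"):
    """Labeled DataFrame of a transition matrix (flow-table layout:
    source states as rows, target states as columns)."""
    import pandas as pd

    mat = tm.probs if kind == "probs" else tm.counts
    return pd.DataFrame(mat, index=list(tm.states), columns=list(tm.states))
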