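"""Two-state hidden Markov model with univariate Gaussian emissions.

This is the segmenter that turns a per-bin log2-difference track into
discrete genomic domains.  The model has two hidden states — "negative"
(state 0) and "positive" (state 1, the damage-enriched state) — each
emitting the observed bin value from its own normal distribution.
Parameters are fitted by Baum-Welch expectation-maximization over all
chromosomes jointly (each chromosome an independent observation sequence
sharing one parameter set), and the state path is decoded with the
Viterbi algorithm, whose maximum-probability path is inherently a set of
discrete runs.

Numerical scheme: forward/backward use per-position scaling (the
log-likelihood is the summed log of the scaling constants), Viterbi runs
in log space.  A variance floor prevents emission collapse onto a single
observation during EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage import GenomicBin

__all__ = [
    "GaussianHMMParams",
    "SegmentationResult",
    "Domain",
    "initialize_params",
    "forward_log",
    "forward_backward",
    "viterbi",
    "baum_welch",
    "segment",
    "call_domains",
]

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_FLOOR = 1e-6
POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class GaussianHMMParams:
    """Parameters of the two-state Gaussian-emission HMM.

    State 1 is the "positive" state: after fitting, states are relabeled
    so that ``means[1] >= means[0]``.
    """

    initial: np.ndarray      # (2,) initial state probabilities
    transitions: np.ndarray  # (2,2) row-stochastic
    means: np.ndarray        # (2,) emission means, log2-difference units
    variances: np.ndarray    # (2,) emission variances, > 0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.initial.shape != (2,) or self.transitions.shape != (2, 2):
            raise ValueError("this model is strictly two-state")
        if abs(self.initial.sum() - 1) > 1e-12:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    def relabeled(self) -> "GaussianHMMParams":
        """Canonical ordering: state 1 has the larger emission mean."""
        if self.means[1] >= self.means[0]:
            return self
        perm = [1, 0]
        return GaussianHMMParams(
            initial=self.initial[perm],
            transitions=self.transitions[np.ix_(perm, perm)],
            means=self.means[perm],
            variances=self.variances[perm],
        )

    def log_emissions(self, obs: np.ndarray) -> np.ndarray:
        """(T, 2) matrix of per-state normal log densities."""
        x = obs[:, None]
        return -0.5 * (
            np.log(2 * np.pi * self.variances)
            + (x - self.means) ** 2 / self.variances
        )


@dataclass
class Domain:
    """A maximal run of same-state bins merged into one genomic interval."""

    chrom: str
    start: int
    end: int
    state: str  # "positive" or "negative"
    n_bins: int
    mean_signal: float
    mean_posterior: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("domain end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    """Fitted model plus per-chromosome decoding of a binned signal."""

    state_paths: dict[str, np.ndarray]          # one state per bin
    positive_posteriors: dict[str, np.ndarray]  # P(state 1) per bin
    observations: dict[str, np.ndarray]
    log_likelihood: float
    n_iterations: int
    params: GaussianHMMParams
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    degenerate: bool = False


def _check_obs(obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or len(obs) == 0:
        raise ValueError("observations must be a non-empty 1-D sequence")
    bad = np.flatnonzero(~np.isfinite(obs))
    if bad.size:
        raise ValueError(f"non-finite observation at position {bad[0]}")
    return obs


def initialize_params(
    values: Sequence[float],
    strategy: str = "quantile",
    seed: int = 0,
) -> GaussianHMMParams:
    """Deterministic quantile-split initialization.

    The values are split at their median rank; the lower half seeds state
    0 and the upper half state 1.  Transitions start sticky (0.9 self)
    because the domains being segmented span many consecutive bins.  The
    ``seed`` argument is accepted for interface uniformity; the quantile
    strategy is fully deterministic.
    """
    if strategy != "quantile":
        raise ValueError(f"unknown initialization strategy {strategy!r}")
    values = _check_obs(np.asarray(values, dtype=float))
    if len(values) < 4:
        raise ValueError("need at least 4 values to initialize")
    if np.ptp(values) == 0:
        raise ValueError("all observations identical: degenerate emissions")
    ordered = np.sort(values)
    half = len(ordered) // 2
    low, high = ordered[:half], ordered[half:]
    means = np.array([low.mean(), high.mean()])
    variances = np.maximum(
        np.array([low.var(), high.var()]), DEFAULT_VARIANCE_FLOOR
    )
    return GaussianHMMParams(
        initial=np.array([0.5, 0.5]),
        transitions=np.array([[0.9, 0.1], [0.1, 0.9]]),
        means=means,
        variances=variances,
    )


def _scaled_forward(
    logB: np.ndarray, params: GaussianHMMParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward pass; returns (alpha_hat (T,2), scales (T,), loglik).

    Emission densities are renormalized per position by their max log
    density so the linear-space recursion never under/overflows.
    """
    T = logB.shape[0]
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, 2))
    scales = np.empty(T)
    a = params.initial * B[0]
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    A = params.transitions
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        scales[t] = a.sum()
        alpha[t] = a / scales[t]
    loglik = float(np.log(scales).sum() + shift.sum())
    return alpha, scales, loglik


def _scaled_backward(
    logB: np.ndarray, params: GaussianHMMParams, scales: np.ndarray
) -> np.ndarray:
    T = logB.shape[0]
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    A = params.transitions
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scales[t + 1]
    return beta


def forward_log(obs: Sequence[float], params: GaussianHMMParams) -> float:
    """Log-likelihood log p(obs | params) via the scaled forward recursion."""
    obs = _check_obs(np.asarray(obs, dtype=float))
    _, _, loglik = _scaled_forward(params.log_emissions(obs), params)
    return loglik


def forward_backward(
    obs: Sequence[float], params: GaussianHMMParams
) -> tuple[np.ndarray, float]:
    """Per-position state posteriors (T, 2) and the log-likelihood."""
    obs = _check_obs(np.asarray(obs, dtype=float))
    logB = params.log_emissions(obs)
    alpha, scales, loglik = _scaled_forward(logB, params)
    beta = _scaled_backward(logB, params, scales)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, loglik


def viterbi(obs: Sequence[float], params: GaussianHMMParams) -> np.ndarray:
    """Maximum-probability state path (log-space dynamic programming).

    Ties at the final backtrace choice resolve toward the lower state
    index.
    """
    obs = _check_obs(np.asarray(obs, dtype=float))
    logB = params.log_emissions(obs)
    T = len(obs)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transitions)
        logpi = np.log(params.initial)
    delta = logpi + logB[0]
    back = np.empty((T, 2), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)  # argmax prefers lower index on ties
        delta = cand[back[t], [0, 1]] + logB[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path.astype(int)


def baum_welch(
    obs_by_chrom: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    init: GaussianHMMParams,
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> tuple[GaussianHMMParams, list[float], bool]:
    """Fit the two-state model by EM over multiple independent sequences.

    All sequences (chromosomes) share one parameter set.  Iterates until
    the relative log-likelihood improvement drops below ``tol`` or
    ``max_iter`` is reached; non-convergence is reported through the
    returned flag, not an exception.  Returns the fitted parameters
    (relabeled so state 1 has the larger mean), the per-iteration
    log-likelihood trace, and the convergence flag.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if isinstance(obs_by_chrom, Mapping):
        seqs = [_check_obs(np.asarray(v, float)) for v in obs_by_chrom.values()]
    else:
        seqs = [_check_obs(np.asarray(v, float)) for v in obs_by_chrom]
    if sum(len(s) for s in seqs) < 10:
        raise ValueError("need at least 10 observations in total")

    params = init
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        pi_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        g_acc = np.zeros(2)
        gx_acc = np.zeros(2)
        gxx_acc = np.zeros(2)
        total_ll = 0.0
        A = params.transitions
        for obs in seqs:
            logB = params.log_emissions(obs)
            alpha, scales, ll = _scaled_forward(logB, params)
            beta = _scaled_backward(logB, params, scales)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            total_ll += ll
            pi_acc += gamma[0]
            if len(obs) > 1:
                shift = logB.max(axis=1)
                B = np.exp(logB - shift[:, None])
                # xi[t] ∝ alpha_t(i) A_ij b_j(t+1) beta_{t+1}(j)
                xi = (
                    alpha[:-1, :, None]
                    * A[None, :, :]
                    * (B[1:] * beta[1:])[:, None, :]
                )
                xi /= xi.sum(axis=(1, 2), keepdims=True)
                xi_acc += xi.sum(axis=0)
            g_acc += gamma.sum(axis=0)
            gx_acc += gamma.T @ obs
            gxx_acc += gamma.T @ (obs**2)
        trace.append(total_ll)

        means = gx_acc / g_acc
        variances = gxx_acc / g_acc - means**2
        if np.any(variances < variance_floor):
            logger.warning("emission variance hit the floor; clamping")
        variances = np.maximum(variances, variance_floor)
        row_sums = xi_acc.sum(axis=1, keepdims=True)
        transitions = np.where(row_sums > 0, xi_acc / row_sums, A)
        transitions /= transitions.sum(axis=1, keepdims=True)
        params = GaussianHMMParams(
            initial=pi_acc / pi_acc.sum(),
            transitions=transitions,
            means=means,
            variances=variances,
        )
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break
    return params.relabeled(), trace, converged


def segment(
    obs_by_chrom: Mapping[str, Sequence[float]],
    init: GaussianHMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    model_selection: bool = True,
) -> SegmentationResult:
    """Fit the model and decode every chromosome.

    Convenience wrapper: quantile initialization on the pooled values
    (unless ``init`` is given), Baum-Welch training, Viterbi decoding and
    positive-state posteriors per chromosome.

    A two-state Gaussian HMM will happily split pure noise into two
    near-identical states, so with ``model_selection`` on (the default)
    the fitted model is compared by BIC against a single-Gaussian null;
    when one state suffices, the result is flagged ``degenerate`` and
    every bin is decoded as negative (no positive domains are called).
    """
    obs_by_chrom = {
        c: _check_obs(np.asarray(v, float)) for c, v in obs_by_chrom.items()
    }
    if init is None:
        pooled = np.concatenate(list(obs_by_chrom.values()))
        init = initialize_params(pooled)
    params, trace, converged = baum_welch(
        obs_by_chrom, init, tol=tol, max_iter=max_iter,
        variance_floor=variance_floor,
    )
    paths: dict[str, np.ndarray] = {}
    posts: dict[str, np.ndarray] = {}
    total_ll = 0.0
    for chrom, obs in obs_by_chrom.items():
        paths[chrom] = viterbi(obs, params)
        gamma, ll = forward_backward(obs, params)
        posts[chrom] = gamma[:, 1]
        total_ll += ll

    degenerate = False
    if model_selection:
        pooled = np.concatenate(list(obs_by_chrom.values()))
        n = len(pooled)
        var1 = max(float(pooled.var()), variance_floor)
        ll1 = float(
            -0.5 * n * (np.log(2 * np.pi * var1) + 1.0)
        )  # Gaussian MLE log-likelihood
        # free parameters: 2 for the single Gaussian; 7 for the HMM
        # (1 initial + 2 transition + 2 means + 2 variances)
        bic1 = 2 * np.log(n) - 2 * ll1
        bic2 = 7 * np.log(n) - 2 * total_ll
        if bic1 <= bic2:
            logger.warning(
                "one-state model preferred by BIC; decoding all-negative"
            )
            degenerate = True
            paths = {c: np.zeros(len(v), dtype=int)
                     for c, v in obs_by_chrom.items()}
    return SegmentationResult(
        state_paths=paths,
        positive_posteriors=posts,
        observations=obs_by_chrom,
        log_likelihood=total_ll,
        n_iterations=len(trace),
        params=params,
        converged=converged,
        loglik_trace=trace,
        degenerate=degenerate,
    )


def call_domains(
    result: SegmentationResult,
    bins: Sequence[GenomicBin],
    min_bins: int = 1,
) -> list[Domain]:
    """Merge the per-bin state path into genomic domains.

    Maximal runs of the same state become one domain; positive runs
    shorter than ``min_bins`` are reassigned to the negative state before
    merging; chromosome boundaries always break domains.  Positive
    domains are the damage (γ-H2A.v-type) domain calls.
    """
    by_chrom: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    domains: list[Domain] = []
    for chrom, path in result.state_paths.items():
        cbins = by_chrom.get(chrom, [])
        if len(cbins) != len(path):
            raise ValueError(
                f"{chrom}: {len(path)} states but {len(cbins)} bins"
            )
        path = np.asarray(path, dtype=int).copy()
        obs = result.observations[chrom]
        post = result.positive_posteriors[chrom]
        if min_bins > 1:
            for i0, i1, state in _runs(path):
                if state == 1 and i1 - i0 < min_bins:
                    path[i0:i1] = 0
        for i0, i1, state in _runs(path):
            domains.append(
                Domain(
                    chrom=chrom,
                    start=cbins[i0].start,
                    end=cbins[i1 - 1].end,
                    state=POSITIVE if state == 1 else NEGATIVE,
                    n_bins=i1 - i0,
                    mean_signal=float(np.mean(obs[i0:i1])),
                    mean_posterior=float(np.mean(post[i0:i1])),
                )
            )
    return domains


def _runs(path: np.ndarray):
    """Yield (start_idx, end_idx_exclusive, state) for maximal equal runs."""
    i = 0
    n = len(path)
    while i < n:
        j = i
        while j < n and path[j] == path[i]:
            j += 1
        yield i, j, int(path[i])
        i = j


def positive_domains(domains: Sequence[Domain]) -> list[Domain]:
    """Filter a domain list down to the positive (damage-enriched) calls."""
    return [d for d in domains if d.state == POSITIVE]
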