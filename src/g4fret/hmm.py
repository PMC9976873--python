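"""Trace selection, hidden-Markov segmentation and dwell-time kinetics.

Corrected smFRET traces are segmented into discrete efficiency states with
a Gaussian-emission HMM.  The number of states is chosen by fitting
k = 1..max_states with several seeded EM restarts each and minimizing the
Bayesian information criterion; the most-likely state path comes from
Viterbi decoding.  Maximal runs of constant state become dwells, whose
exponential lifetimes are estimated either by the maximum-likelihood mean
of uncensored dwells or by a binned-histogram exponential fit.

Traces are admitted to analysis only when they show clean single-step
photobleaching: one downward acceptor step at most (watched in the direct
acceptor-excitation channel F_AA) and one donor step at most (watched in
the summed donor-excitation signal F_DD + F_AD, which collapses to
background when the donor dies).  Multi-step traces — aggregates or
colocalized doublets — are rejected.

Traces split into a low-FRET group (all visited states below E = 0.6:
unfolded and partly folded molecules) and a high-FRET group (at least one
state at or above 0.6: fully folded conformations present).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import curve_fit

logging.getLogger("hmmlearn").setLevel(logging.ERROR)
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .fret import CorrectedTrace
from .simulate import RawTrace

__all__ = [
    "HmmResult",
    "Dwell",
    "DwellSet",
    "TraceClassification",
    "HmmSegmenter",
    "select_traces",
    "fit_hmm",
    "extract_dwells",
    "fit_dwell_lifetime",
    "classify_trace",
]


@dataclass(frozen=True)
class HmmResult:
    n_states: int
    state_means: np.ndarray  # sorted ascending
    state_sds: np.ndarray
    transition_matrix: np.ndarray  # row-stochastic, per-frame
    state_path: np.ndarray  # most-likely state per frame
    score: float  # negative BIC of the selected model (higher is better)

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_means", np.asarray(self.state_means, float))
        object.__setattr__(self, "state_sds", np.asarray(self.state_sds, float))
        object.__setattr__(self, "transition_matrix", np.asarray(self.transition_matrix, float))
        object.__setattr__(self, "state_path", np.asarray(self.state_path, int))
        if np.any(np.diff(self.state_means) < 0):
            raise ValueError("state_means must be sorted ascending")
        rows = self.transition_matrix.sum(axis=1)
        if self.n_states > 0 and np.any(np.abs(rows - 1) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.state_path.size and self.state_path.max() >= self.n_states:
            raise ValueError("state_path refers to unknown state")


@dataclass(frozen=True)
class Dwell:
    state: int
    duration: float  # s, positive multiple of frame_time
    left_censored: bool = False
    right_censored: bool = False

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass(frozen=True)
class DwellSet:
    dwells: tuple[Dwell, ...]
    frame_time: float

    def for_state(self, state: int, include_censored: bool = False) -> list[Dwell]:
        return [
            d
            for d in self.dwells
            if d.state == state and (include_censored or not d.censored)
        ]

    def durations(self, state: int, include_censored: bool = False) -> np.ndarray:
        return np.array(
            [d.duration for d in self.for_state(state, include_censored)]
        )


@dataclass(frozen=True)
class TraceClassification:
    group: str  # "low" | "high"
    visited_states: tuple[float, ...]  # means of visited states
    has_direct_low_high_transition: bool


# ---------------------------------------------------------------------------
# photobleaching-step trace selection


def _two_segment_step(x: np.ndarray) -> tuple[int, float]:
    """Best single change-point by two-segment mean fit.

    Returns (index, step) where the mean changes by ``step`` at ``index``
    (segment boundaries exclude trivial one-frame segments).
    """
    n = x.size
    if n < 4:
        return 0, 0.0
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])
    ks = np.arange(2, n - 1)
    left_mean = csum[ks] / ks
    right_mean = (csum[n] - csum[ks]) / (n - ks)
    sse = (
        csq[n]
        - ks * left_mean**2
        - (n - ks) * right_mean**2
    )
    best = int(np.argmin(sse))
    k = int(ks[best])
    return k, float(right_mean[best] - left_mean[best])


def _find_down_steps(x: np.ndarray, min_step: float, _offset: int = 0) -> list[int]:
    """Recursive binary segmentation for downward mean steps >= min_step."""
    k, step = _two_segment_step(x)
    if k == 0 or abs(step) < min_step:
        return []
    steps = []
    if step < 0:
        steps.append(_offset + k)
    steps += _find_down_steps(x[:k], min_step, _offset)
    steps += _find_down_steps(x[k:], min_step, _offset + k)
    return sorted(steps)


def _noise_sd(x: np.ndarray) -> float:
    """Robust per-frame noise from absolute successive differences.

    Median-based; falls back to the 75th percentile when more than half the
    differences are exactly zero (e.g. a long constant post-bleach tail).
    """
    d = np.abs(np.diff(x))
    if d.size == 0:
        return 0.0
    med = float(np.median(d))
    if med > 0:
        return med / (np.sqrt(2) * 0.6745)
    # |N(0, sqrt(2) sigma)| has 75th percentile sqrt(2) * 1.1503 * sigma
    return float(np.percentile(d, 75)) / (np.sqrt(2) * 1.1503)


def select_traces(
    raws: Sequence[RawTrace],
    min_step_sigma: float = 3.0,
    min_usable_frames: int = 5,
) -> list[RawTrace]:
    """Keep traces with single-step donor and/or acceptor photobleaching.

    Acceptor bleaching is detected as downward steps in F_AA; donor
    bleaching as a downward step in F_DD + F_AD after which the signal sits
    at the background level.  More than one step in either channel rejects
    the trace.  Traces with no bleach within the record are accepted with
    their full length usable; accepted traces get ``usable_range`` set to
    the pre-bleach frames.
    """
    accepted: list[RawTrace] = []
    for raw in raws:
        s = raw.f_dd + raw.f_ad
        aa = raw.f_aa
        sigma_s = max(_noise_sd(s), 1e-12)
        sigma_aa = max(_noise_sd(aa), 1e-12)
        steps_aa = _find_down_steps(aa, min_step_sigma * sigma_aa)
        if len(steps_aa) > 1:
            continue  # multi-step acceptor bleaching: aggregate/doublet
        steps_s = _find_down_steps(s, min_step_sigma * sigma_s)
        # an acceptor bleach also perturbs the summed donor-excitation
        # signal, and conformational transitions shift it slightly; a donor
        # bleach removes essentially the whole donor-excitation signal, so
        # only large steps away from the acceptor step count
        donor_steps = [
            k
            for k in steps_s
            if not _near(k, steps_aa, tol=3)
            and _step_drop(s, k) > 0.25 * max(np.mean(s[:k]), 1e-12)
        ]
        if len(donor_steps) > 1:
            continue
        cut = raw.n_frames
        if steps_aa:
            cut = min(cut, steps_aa[0])
        if donor_steps:
            cut = min(cut, donor_steps[0])
        if cut < min_usable_frames:
            continue
        raw.usable_range = (0, cut)
        accepted.append(raw)
    return accepted


def _near(k: int, others: Sequence[int], tol: int) -> bool:
    return any(abs(k - o) <= tol for o in others)


def _step_drop(x: np.ndarray, k: int, window: int = 25) -> float:
    """Local mean drop across a candidate step."""
    pre = x[max(k - window, 0) : k]
    post = x[k : k + window]
    if pre.size == 0 or post.size == 0:
        return 0.0
    return float(pre.mean() - post.mean())


# ---------------------------------------------------------------------------
# HMM segmentation


class HmmSegmenter:
    """Gaussian-emission HMM segmentation of one corrected trace
    (sklearn-style estimator).

    ``fit(E)`` fits k = 1..max_states with ``n_restarts`` seeded EM runs
    each, keeps the best likelihood per k and selects k by BIC.  Fitted
    attributes: ``n_states_``, ``means_`` (ascending), ``sds_``,
    ``transmat_``, ``path_`` (Viterbi), ``score_`` (negative BIC).
    """

    def __init__(
        self,
        max_states: int = 5,
        n_restarts: int = 5,
        n_iter: int = 150,
        tol: float = 1e-3,
        min_sd: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.max_states = max_states
        self.n_restarts = n_restarts
        self.n_iter = n_iter
        self.tol = tol
        self.min_sd = min_sd
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_states": self.max_states,
            "n_restarts": self.n_restarts,
            "n_iter": self.n_iter,
            "tol": self.tol,
            "min_sd": self.min_sd,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "HmmSegmenter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _bic(logl: float, k: int, n: int) -> float:
        # free parameters: k-1 start probs, k(k-1) transition, k means, k vars
        p = (k - 1) + k * (k - 1) + 2 * k
        return -2.0 * logl + p * np.log(n)

    def _fit_k(self, x: np.ndarray, k: int) -> tuple[GaussianHMM | None, float]:
        best, best_logl = None, -np.inf
        # sticky transition prior: smFRET dwells span many frames
        sticky = np.full((k, k), 0.05 / max(k - 1, 1))
        np.fill_diagonal(sticky, 0.95 if k > 1 else 1.0)
        for r in range(self.n_restarts):
            seed = (self.random_state * 1000 + k * 100 + r) % (2**31)
            hmm = GaussianHMM(
                n_components=k,
                covariance_type="diag",
                n_iter=self.n_iter,
                tol=self.tol,
                min_covar=self.min_sd**2,
                random_state=seed,
                init_params="mc" if r else "c",
            )
            hmm.startprob_ = np.full(k, 1.0 / k)
            hmm.transmat_ = sticky.copy()
            if r == 0:
                # deterministic spread start: evenly spaced quantiles
                qs = (np.arange(k) + 0.5) / k
                hmm.means_ = np.quantile(x, qs).reshape(-1, 1)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hmm.fit(x)
                    logl = float(hmm.score(x))
            except Exception:
                continue
            if np.isfinite(logl) and logl > best_logl:
                best, best_logl = hmm, logl
        return best, best_logl

    def fit(self, E: np.ndarray, y=None) -> "HmmSegmenter":
        e = np.asarray(E, dtype=float).ravel()
        e = e[np.isfinite(e)]
        if e.size < 20:
            raise ValueError(f"need >= 20 usable frames, got {e.size}")
        if self.max_states < 1:
            raise ValueError("max_states must be >= 1")
        if np.var(e) < 1e-12:
            self._set_single_state(e)
            return self
        x = e.reshape(-1, 1)
        best_bic, chosen, chosen_k = np.inf, None, 1
        for k in range(1, self.max_states + 1):
            hmm, logl = self._fit_k(x, k)
            if hmm is None:
                continue
            bic = self._bic(logl, k, e.size)
            if bic < best_bic:
                best_bic, chosen, chosen_k = bic, hmm, k
        if chosen is None:
            raise RuntimeError("all HMM fits failed")
        means = chosen.means_.ravel()
        sds = np.sqrt(chosen.covars_.reshape(chosen_k, -1).ravel())
        order = np.argsort(means)
        transmat = chosen.transmat_[np.ix_(order, order)]
        # renormalize against EM round-off
        transmat = transmat / transmat.sum(axis=1, keepdims=True)
        inv = np.empty_like(order)
        inv[order] = np.arange(chosen_k)
        _, raw_path = chosen.decode(x, algorithm="viterbi")
        self.n_states_ = chosen_k
        self.means_ = means[order]
        self.sds_ = sds[order]
        self.transmat_ = transmat
        self.path_ = inv[raw_path]
        self.score_ = -best_bic
        return self

    def _set_single_state(self, e: np.ndarray) -> None:
        self.n_states_ = 1
        self.means_ = np.array([float(e.mean())])
        self.sds_ = np.array([max(float(e.std()), self.min_sd)])
        self.transmat_ = np.array([[1.0]])
        self.path_ = np.zeros(e.size, dtype=int)
        self.score_ = 0.0

    def predict(self, E: np.ndarray) -> np.ndarray:
        if not hasattr(self, "path_"):
            raise RuntimeError("fit the estimator first")
        e = np.asarray(E, float).ravel()
        # nearest-mean assignment for out-of-sample frames
        return np.argmin(np.abs(e[:, None] - self.means_[None, :]), axis=1)

    @property
    def result_(self) -> HmmResult:
        return HmmResult(
            n_states=self.n_states_,
            state_means=self.means_,
            state_sds=self.sds_,
            transition_matrix=self.transmat_,
            state_path=self.path_,
            score=self.score_,
        )


def fit_hmm(
    trace: CorrectedTrace,
    max_states: int = 5,
    n_restarts: int = 5,
    seed: int = 0,
) -> HmmResult:
    """Segment one corrected trace; see :class:`HmmSegmenter`."""
    seg = HmmSegmenter(max_states=max_states, n_restarts=n_restarts, random_state=seed)
    seg.fit(trace.usable)
    return seg.result_


# ---------------------------------------------------------------------------
# dwell times and lifetimes


def extract_dwells(result: HmmResult, frame_time: float) -> DwellSet:
    """Run-length encode the decoded path; boundary dwells are censored."""
    path = result.state_path
    if path.size == 0:
        return DwellSet(dwells=(), frame_time=frame_time)
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    dwells = tuple(
        Dwell(
            state=int(path[a]),
            duration=float((b - a) * frame_time),
            left_censored=(a == 0),
            right_censored=(b == path.size),
        )
        for a, b in zip(starts, stops)
    )
    return DwellSet(dwells=dwells, frame_time=frame_time)


def _histogram_tau(durations: np.ndarray, width: float, tau0: float) -> float:
    n_bins = int(np.ceil(durations.max() / width))
    edges = width * np.arange(n_bins + 1) + width / 2  # bins centred on multiples
    counts, _ = np.histogram(durations, bins=edges)
    centers = width * np.arange(1, n_bins + 1)
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram fit needs at least two occupied bins")

    def decay(t, A, tau):
        return A * np.exp(-t / tau)

    # empty bins carry tail information and are kept; unweighted least
    # squares avoids the small-count bias of observed-count Poisson weights
    popt, _ = curve_fit(decay, centers, counts, p0=(counts.max(), tau0), maxfev=10000)
    return float(popt[1])


def fit_dwell_lifetime(
    dwells: DwellSet,
    state: int,
    method: str = "mle",
    min_dwells: int = 10,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Exponential lifetime of one state from its uncensored dwells.

    ``method="mle"`` (default): the sample mean, the maximum-likelihood
    estimator for an exponential, with standard error mean/sqrt(n).
    ``method="histogram"``: bin the dwell durations (bin width = one frame)
    and fit A * exp(-t / tau) to the counts — the classic lifetime-
    histogram procedure; its standard error comes from a seeded bootstrap
    over dwells (the fit covariance understates the sampling spread under
    the heteroskedastic bin counts).
    """
    durations = dwells.durations(state)
    n = durations.size
    if n < min_dwells:
        raise ValueError(
            f"need >= {min_dwells} uncensored dwells in state {state}, got {n}"
        )
    if method == "mle":
        tau = float(durations.mean())
        return tau, tau / np.sqrt(n)
    if method == "histogram":
        width = dwells.frame_time
        tau0 = max(durations.mean(), width)
        tau = _histogram_tau(durations, width, tau0)
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_bootstrap):
            resample = rng.choice(durations, size=n, replace=True)
            try:
                boot.append(_histogram_tau(resample, width, tau))
            except (ValueError, RuntimeError):
                continue
        se = float(np.std(boot, ddof=1)) if len(boot) > 1 else float("nan")
        return tau, se
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# low/high FRET classification


def classify_trace(
    result: HmmResult,
    threshold: float = 0.6,
    low_mean: float = 0.25,
) -> TraceClassification:
    """Assign a trace to the low- or high-FRET group.

    High iff any visited state mean is at or above the threshold.  Also
    flags the rare direct unfolded <-> fully-folded events: consecutive
    dwells jumping between a state with mean <= ``low_mean`` and one with
    mean >= ``threshold`` in either direction.
    """
    path = result.state_path
    visited = sorted(set(int(s) for s in path))
    visited_means = tuple(float(result.state_means[s]) for s in visited)
    group = "high" if any(m >= threshold for m in visited_means) else "low"
    direct = False
    if path.size > 1:
        change = np.flatnonzero(np.diff(path))
        for i in change:
            a, b = result.state_means[path[i]], result.state_means[path[i + 1]]
            if (a <= low_mean and b >= threshold) or (b <= low_mean and a >= threshold):
                direct = True
                break
    return TraceClassification(
        group=group,
        visited_states=visited_means,
        has_direct_low_high_transition=direct,
    )
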