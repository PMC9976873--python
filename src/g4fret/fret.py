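"""FRET efficiency correction, histograms and folded fractions.

The per-frame transfer efficiency is computed from the two donor-excitation
channels after the standard ALEX corrections::

    F_DD' = F_DD - bg_DD
    F_AA' = F_AA - bg_AA
    F_AD' = F_AD - bg_AD - alpha * F_DD' - delta * F_AA'
    E     = F_AD' / (F_AD' + gamma * F_DD')

with alpha the donor-leakage fraction, delta the acceptor direct-excitation
fraction and gamma the detection-imbalance factor.  E is deliberately not
clipped to [0, 1]; frames with a non-positive denominator are flagged
invalid (NaN) and excluded from histograms rather than imputed.

Histograms count one entry per usable frame.  The folded fraction is the
share of counts at or above a threshold (default E >= 0.6, the fully folded
band); its uncertainty comes from randomly splitting the trace pool into
three equal parts and building one histogram per subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import RawTrace

__all__ = [
    "CorrectionFactors",
    "CorrectedTrace",
    "FretHistogram",
    "FretCorrector",
    "correct_trace",
    "ensemble_fret",
    "build_histogram",
    "folded_fraction",
    "fraction_uncertainty",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_HIST_RANGE",
]

#: histogram range admits corrected E slightly outside [0, 1] under noise;
#: the default width keeps a bin edge exactly at the 0.6 threshold.
DEFAULT_HIST_RANGE = (-0.1, 1.1)
DEFAULT_BIN_WIDTH = 0.025


@dataclass(frozen=True)
class CorrectionFactors:
    """ALEX correction factors (sample-averaged, as used for all traces)."""

    alpha: float = 0.15
    delta: float = 0.05
    gamma: float = 1.2
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)  # DD, AD, AA

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1 and 0 <= self.delta < 1):
            raise ValueError("alpha and delta must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        bg = self.background
        if np.isscalar(bg):
            bg = (float(bg),) * 3
        object.__setattr__(self, "background", tuple(float(b) for b in bg))
        if len(self.background) != 3:
            raise ValueError("background needs one value per channel (DD, AD, AA)")


@dataclass
class CorrectedTrace:
    """Per-frame corrected efficiency; invalid frames are NaN."""

    E: np.ndarray
    frame_time: float
    usable_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.usable_range is None:
            self.usable_range = (0, self.E.size)
        a, b = self.usable_range
        if not (0 <= a <= b <= self.E.size):
            raise ValueError("usable_range outside trace bounds")

    @property
    def usable(self) -> np.ndarray:
        """Valid efficiencies inside the usable (pre-bleach) range."""
        a, b = self.usable_range
        e = self.E[a:b]
        return e[np.isfinite(e)]


@dataclass(frozen=True)
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_frames: int
    n_traces: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if counts.size != edges.size - 1 or np.any(counts < 0):
            raise ValueError("counts must be non-negative, one per bin")
        if int(counts.sum()) != self.n_frames:
            raise ValueError("histogram must conserve frame counts")


class FretCorrector:
    """Transformer applying the ALEX corrections to raw traces.

    sklearn-style: ``transform`` maps a list of :class:`RawTrace` to a list
    of :class:`CorrectedTrace`.  There is nothing to fit (the correction
    factors are sample-averaged constants), so ``fit`` is a no-op kept for
    pipeline compatibility.
    """

    def __init__(
        self,
        alpha: float = 0.15,
        delta: float = 0.05,
        gamma: float = 1.2,
        background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> None:
        self.alpha = alpha
        self.delta = delta
        self.gamma = gamma
        self.background = background

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "delta": self.delta,
            "gamma": self.gamma,
            "background": self.background,
        }

    def set_params(self, **params) -> "FretCorrector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def factors(self) -> CorrectionFactors:
        return CorrectionFactors(self.alpha, self.delta, self.gamma, self.background)

    def fit(self, X=None, y=None) -> "FretCorrector":
        return self

    def transform(self, X: Sequence[RawTrace]) -> list[CorrectedTrace]:
        return [correct_trace(raw, self.factors) for raw in X]

    def fit_transform(self, X, y=None) -> list[CorrectedTrace]:
        return self.fit(X, y).transform(X)


def correct_trace(raw: RawTrace, corr: CorrectionFactors) -> CorrectedTrace:
    """Apply background, leakage, direct-excitation and gamma corrections.

    Frames where the corrected denominator F_AD' + gamma * F_DD' is not
    positive are flagged NaN (excluded downstream, never an exception).
    """
    if raw.n_frames == 0:
        raise ValueError("raw trace is empty")
    bg_dd, bg_ad, bg_aa = corr.background
    f_dd = raw.f_dd - bg_dd
    f_aa = raw.f_aa - bg_aa
    f_ad = raw.f_ad - bg_ad - corr.alpha * f_dd - corr.delta * f_aa
    denom = f_ad + corr.gamma * f_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(denom > 0, f_ad / denom, np.nan)
    return CorrectedTrace(E=E, frame_time=raw.frame_time, usable_range=raw.usable_range)


def ensemble_fret(I_DA: float, I_DD: float) -> float:
    """Bulk (fluorimeter) proximity ratio E = I_DA / (I_DA + I_DD)."""
    total = I_DA + I_DD
    if total <= 0:
        raise ValueError("I_DA + I_DD must be positive")
    return float(I_DA / total)


def build_histogram(
    traces: Sequence[CorrectedTrace],
    bin_width: float = DEFAULT_BIN_WIDTH,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE,
) -> FretHistogram:
    """One count per usable valid frame; values outside the range are
    clamped into the edge bins so frame counts are conserved."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = hist_range
    n_bins = int(round((hi - lo) / bin_width))
    if not np.isclose(lo + n_bins * bin_width, hi, atol=1e-9):
        raise ValueError("bin_width must tile the histogram range exactly")
    edges = lo + np.arange(n_bins + 1) * bin_width
    values = [t.usable for t in traces]
    pooled = np.concatenate(values) if values else np.array([])
    if pooled.size == 0:
        raise ValueError("no usable frames")
    eps = bin_width * 1e-9
    clamped = np.clip(pooled, lo, hi - eps)
    counts, _ = np.histogram(clamped, bins=edges)
    return FretHistogram(
        bin_edges=edges,
        counts=counts,
        n_frames=int(pooled.size),
        n_traces=len(traces),
    )


def folded_fraction(hist: FretHistogram, threshold: float = 0.6) -> float:
    """Fraction of frames in bins at or above the threshold.

    The threshold must coincide with a bin edge; anything else would
    silently split a bin.
    """
    matches = np.isclose(hist.bin_edges, threshold, atol=1e-9)
    if not matches.any():
        raise ValueError(
            f"threshold {threshold} does not fall on a bin edge; "
            "choose a bin width that places an edge there"
        )
    i = int(np.argmax(matches))
    return float(hist.counts[i:].sum() / hist.counts.sum())


def fraction_uncertainty(
    traces: Sequence[CorrectedTrace],
    n_splits: int = 3,
    threshold: float = 0.6,
    bin_width: float = DEFAULT_BIN_WIDTH,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Folded fraction and its spread from a random equal split of traces.

    Traces are shuffled and dealt round-robin into ``n_splits`` near-equal
    groups; the folded fraction is computed per group and the sample mean
    and standard deviation (ddof = 1) across groups returned.
    """
    if len(traces) < n_splits:
        raise ValueError(
            f"need at least n_splits={n_splits} traces, got {len(traces)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(traces))
    fractions = []
    for g in range(n_splits):
        group = [traces[i] for i in order[g::n_splits]]
        hist = build_histogram(group, bin_width=bin_width, hist_range=hist_range)
        fractions.append(folded_fraction(hist, threshold))
    fractions = np.asarray(fractions)
    return float(fractions.mean()), float(fractions.std(ddof=1))
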