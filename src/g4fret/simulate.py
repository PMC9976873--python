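"""Synthetic single-molecule FRET trace generator.

Emulates the smFRET observable stream of a surface-immobilized Tel8
molecule imaged under alternating laser excitation (ALEX): three detection
channels per 200 ms frame —

    F_DD  donor emission under donor excitation
    F_AD  acceptor emission under donor excitation (the FRET channel)
    F_AA  acceptor emission under acceptor excitation (for the direct-
          excitation correction)

The molecule's conformational state follows a continuous-time Markov chain
from :mod:`g4fret.kinetics`; each state carries a mean FRET efficiency and
an emission width.  Rendering applies, in this order: motion blur (frame E
is the occupancy-weighted mean over the frame interval), emission-width
noise, the instrument distortions the analysis must undo (donor leakage
alpha, acceptor direct excitation delta, detection imbalance gamma,
per-channel background), single-step photobleaching with independent
exponential clocks for the two dyes, and additive Gaussian channel noise.

Time-course ensembles emulate a LiCl -> NaCl buffer exchange at t = 0:
every molecule starts unfolded and observation windows open at the
requested time points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import (
    STATES,
    STATE_INDEX,
    KineticModel,
    sample_ctmc_path,
)

__all__ = [
    "GeneratorConfig",
    "TraceTruth",
    "RawTrace",
    "sample_ctmc_path",
    "render_trace",
    "generate_traces",
    "generate_timecourse_dataset",
    "DEFAULT_STATE_EMISSION",
]

#: default state -> (mean E, sd E) emission map: unfolded strand at E~0.2,
#: every one-G4 intermediate near the partly folded band at E~0.4, the
#: fully folded (two consecutive G4s) state at E~0.8.
DEFAULT_STATE_EMISSION: dict[str, tuple[float, float]] = {
    "U": (0.2, 0.05),
    "P2": (0.4, 0.05),
    "P3": (0.4, 0.05),
    "P4": (0.4, 0.05),
    "P5": (0.4, 0.05),
    "P6": (0.4, 0.05),
    "F": (0.8, 0.05),
}

MIXED_FRAME = "mix"  # truth label for frames spanning a state change


@dataclass(frozen=True)
class GeneratorConfig:
    """Instrument and emission parameters of the trace generator.

    Defaults follow the imaging conditions the analysis is designed for:
    200 ms frames, 500 s records, leakage alpha = 0.15, direct excitation
    delta = 0.05, detection imbalance gamma = 1.2.
    """

    frame_time: float = 0.2  # s
    trace_length: float = 500.0  # s
    total_intensity: float = 1000.0  # photons/frame, arbitrary units
    noise_sd: float = 30.0  # additive per-channel noise, same units
    background: tuple[float, float, float] = (100.0, 100.0, 100.0)  # DD, AD, AA
    alpha: float = 0.15
    delta: float = 0.05
    gamma: float = 1.2
    donor_bleach_rate: float = 0.002  # 1/s
    acceptor_bleach_rate: float = 0.004  # 1/s
    state_emission: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_EMISSION)
    )
    n_fluorophore_pairs: int = 1  # >1 models a colocalized-doublet artifact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.trace_length < self.frame_time:
            raise ValueError("trace_length must be at least one frame")
        if not (0 <= self.alpha < 1 and 0 <= self.delta < 1):
            raise ValueError("alpha and delta must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ValueError("bleach rates must be >= 0")
        if self.n_fluorophore_pairs < 1:
            raise ValueError("n_fluorophore_pairs must be >= 1")
        bg = self.background
        if np.isscalar(bg):
            bg = (float(bg),) * 3
        object.__setattr__(self, "background", tuple(float(b) for b in bg))
        if len(self.background) != 3:
            raise ValueError("background needs one value per channel (DD, AD, AA)")
        for state, (mean, sd) in self.state_emission.items():
            if not (-0.2 < mean < 1.2):
                raise ValueError(f"emission mean for {state} outside (-0.2, 1.2)")
            if sd < 0:
                raise ValueError(f"emission sd for {state} must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.trace_length / self.frame_time + 1e-9))

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class TraceTruth:
    """Ground-truth annotations attached to a synthetic trace."""

    state: np.ndarray  # per-frame label; MIXED_FRAME where a jump occurs
    efficiency: np.ndarray  # per-frame true (noise-free, blurred) E
    donor_bleach_frame: int | None  # first bleached frame index (0-based)
    acceptor_bleach_frame: int | None
    donor_bleach_time: float | None  # continuous bleach times, s
    acceptor_bleach_time: float | None


@dataclass
class RawTrace:
    """Per-frame three-channel intensities, optionally with ground truth."""

    frames: np.ndarray  # (n, 3) columns F_DD, F_AD, F_AA
    frame_time: float
    truth: TraceTruth | None = None
    usable_range: tuple[int, int] | None = None  # [start, stop) set by selection

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ValueError("frames must be (n, 3): F_DD, F_AD, F_AA")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("all channel intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def f_dd(self) -> np.ndarray:
        return self.frames[:, 0]

    @property
    def f_ad(self) -> np.ndarray:
        return self.frames[:, 1]

    @property
    def f_aa(self) -> np.ndarray:
        return self.frames[:, 2]


def _frame_occupancy(
    path: Sequence[tuple[str, float]], edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Time-weighted state occupancy per frame.

    Returns (occ, pure) where occ is (n_frames, n_states) with rows summing
    to 1 and pure[i] is the state index occupying the whole frame, or -1.
    """
    n_frames = edges.size - 1
    occ = np.zeros((n_frames, len(STATES)))
    entry = np.array([t for _, t in path])
    states = [s for s, _ in path]
    exits = np.append(entry[1:], np.inf)
    for s, t0, t1 in zip(states, entry, exits):
        lo = np.clip(np.maximum(edges[:-1], t0), None, edges[1:])
        hi = np.clip(np.minimum(edges[1:], t1), edges[:-1], None)
        overlap = np.clip(hi - lo, 0.0, None)
        occ[:, STATE_INDEX[s]] += overlap
    widths = np.diff(edges)
    occ /= widths[:, None]
    pure = np.where(np.max(occ, axis=1) >= 1.0 - 1e-12, np.argmax(occ, axis=1), -1)
    return occ, pure


def render_trace(
    path: Sequence[tuple[str, float]],
    cfg: GeneratorConfig,
    model: KineticModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> RawTrace:
    """Render a state path into an ALEX intensity trace.

    ``model`` is accepted for interface symmetry with the path sampler; the
    emission map lives in ``cfg``.  ``seed`` overrides ``cfg.seed``.

    Per frame, with true efficiency E (occupancy-blurred state mean plus
    emission-width noise) and total intensity I::

        F_AD_ideal = I * E
        F_DD_ideal = I * (1 - E) / gamma
        F_AA_ideal = I

    distorted to the observed channels by adding alpha * F_DD leakage and
    delta * F_AA direct excitation to F_AD, plus background and Gaussian
    channel noise.  Photobleaching truncates the dye signals: after the
    acceptor bleaches, F_AD and F_AA fall to background and the donor
    recovers its full (unquenched) intensity; after the donor bleaches,
    F_DD and F_AD fall to background while F_AA persists until the acceptor
    dies.  A doublet artifact (``n_fluorophore_pairs > 1``) superimposes
    additional independent dye pairs, producing multi-step bleaching.
    """
    del model  # emission map comes from cfg
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_frames
    edges = np.arange(n + 1) * cfg.frame_time
    if not path or path[0][1] > 0:
        raise ValueError("path must start at t = 0")
    occ, pure = _frame_occupancy(path, edges)

    means = np.array([cfg.state_emission[s][0] for s in STATES])
    sds = np.array([cfg.state_emission[s][1] for s in STATES])
    e_blur = occ @ means
    sd_blur = occ @ sds

    I = cfg.total_intensity
    bg = np.asarray(cfg.background)
    dd = np.zeros(n)
    ad = np.zeros(n)
    aa = np.zeros(n)

    donor_bt: float | None = None
    acceptor_bt: float | None = None
    donor_bf: int | None = None
    acceptor_bf: int | None = None
    first_truth_e: np.ndarray | None = None
    for pair in range(cfg.n_fluorophore_pairs):
        e_true = e_blur + sd_blur * rng.standard_normal(n)
        t_d = rng.exponential(1 / cfg.donor_bleach_rate) if cfg.donor_bleach_rate > 0 else np.inf
        t_a = rng.exponential(1 / cfg.acceptor_bleach_rate) if cfg.acceptor_bleach_rate > 0 else np.inf
        frame_mid = edges[:-1]
        donor_alive = frame_mid < t_d - 1e-12
        acceptor_alive = frame_mid < t_a - 1e-12
        both = donor_alive & acceptor_alive
        # FRET-coupled emission while both dyes are alive
        dd += np.where(both, I * (1 - e_true) / cfg.gamma, 0.0)
        ad += np.where(
            both, I * e_true + cfg.alpha * I * (1 - e_true) / cfg.gamma + cfg.delta * I, 0.0
        )
        aa += np.where(both, I, 0.0)
        # donor alone: unquenched donor, dark acceptor channels
        dd += np.where(donor_alive & ~acceptor_alive, I / cfg.gamma, 0.0)
        # acceptor alone: direct excitation channel only
        aa += np.where(acceptor_alive & ~donor_alive, I, 0.0)
        if pair == 0:
            donor_bt = None if np.isinf(t_d) else float(t_d)
            acceptor_bt = None if np.isinf(t_a) else float(t_a)
            # first fully dark frame per dye (dye counts as alive for a
            # whole frame if alive at the frame start)
            donor_bf = int(np.argmin(donor_alive)) if not donor_alive.all() else None
            acceptor_bf = (
                int(np.argmin(acceptor_alive)) if not acceptor_alive.all() else None
            )
            first_truth_e = np.where(both, e_true, np.where(donor_alive, 0.0, np.nan))

    noise = cfg.noise_sd * rng.standard_normal((n, 3)) if cfg.noise_sd > 0 else 0.0
    frames = np.column_stack([dd, ad, aa]) + bg[None, :] + noise

    truth_state = np.array(
        [STATES[p] if p >= 0 else MIXED_FRAME for p in pure], dtype=object
    )
    truth = TraceTruth(
        state=truth_state,
        efficiency=np.asarray(first_truth_e),
        donor_bleach_frame=donor_bf,
        acceptor_bleach_frame=acceptor_bf,
        donor_bleach_time=donor_bt,
        acceptor_bleach_time=acceptor_bt,
    )
    return RawTrace(frames=frames, frame_time=cfg.frame_time, truth=truth)


def simulate_discrete_trace(
    means: Sequence[float],
    sds: Sequence[float],
    transmat: np.ndarray,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-aligned discrete-state efficiency series (no motion blur).

    Simulates a per-frame Markov chain with the given row-stochastic
    transition matrix and Gaussian emissions; dwell times are geometric in
    frames.  Used for segmentation benchmarks where state changes must
    coincide with frame boundaries — the full renderer's sub-frame blur
    would otherwise add genuine intermediate-valued frames.

    Returns ``(state_path, E)``.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    transmat = np.asarray(transmat, float)
    k = means.size
    if transmat.shape != (k, k) or np.any(np.abs(transmat.sum(axis=1) - 1) > 1e-9):
        raise ValueError("transmat must be row-stochastic and match means")
    rng = np.random.default_rng(seed)
    p = np.full(k, 1.0 / k) if start is None else np.asarray(start, float)
    path = np.empty(n_frames, dtype=int)
    path[0] = rng.choice(k, p=p)
    for i in range(1, n_frames):
        path[i] = rng.choice(k, p=transmat[path[i - 1]])
    E = means[path] + sds[path] * rng.standard_normal(n_frames)
    return path, E


def generate_traces(
    model: KineticModel,
    cfg: GeneratorConfig,
    n_traces: int,
    initial_state: str = "U",
    seed: int | None = None,
) -> list[RawTrace]:
    """Sample ``n_traces`` independent molecules and render them."""
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    out = []
    for _ in range(n_traces):
        path_rng, render_rng = root.spawn(2)
        path = sample_ctmc_path(model, cfg.trace_length, initial_state, path_rng)
        out.append(render_trace(path, cfg, seed=render_rng))
    return out


def generate_timecourse_dataset(
    model: KineticModel,
    cfg: GeneratorConfig,
    timepoints: Sequence[float],
    n_molecules: int,
    seed: int | None = None,
) -> tuple[list[tuple[float, list[RawTrace]]], dict[float, np.ndarray]]:
    """Folding time-course ensemble after a buffer exchange at t = 0.

    Every molecule starts unfolded; at each requested time point an
    observation window of ``cfg.trace_length`` opens on every molecule.
    Returns ``(dataset, truth_occupancy)`` where ``dataset`` is a list of
    ``(timepoint, [RawTrace, ...])`` and ``truth_occupancy[timepoint]`` is
    the empirical state distribution (aligned with STATES) at that instant.
    """
    timepoints = [float(t) for t in timepoints]
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    if sorted(timepoints) != timepoints or timepoints[0] < 0:
        raise ValueError("timepoints must be sorted and non-negative")
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    horizon = timepoints[-1] + cfg.trace_length + cfg.frame_time
    dataset: list[tuple[float, list[RawTrace]]] = [(tp, []) for tp in timepoints]
    occ_counts = {tp: np.zeros(len(STATES)) for tp in timepoints}
    for _ in range(n_molecules):
        path_rng, render_rng = root.spawn(2)
        path = sample_ctmc_path(model, horizon, "U", path_rng)
        entry = np.array([t for _, t in path])
        for (tp, traces) in dataset:
            idx = int(np.searchsorted(entry, tp, side="right")) - 1
            occ_counts[tp][STATE_INDEX[path[idx][0]]] += 1
            window = _shift_path(path, tp, cfg.trace_length)
            traces.append(render_trace(window, cfg, seed=render_rng.spawn(1)[0]))
    truth = {
        tp: (c / n_molecules if n_molecules else c) for tp, c in occ_counts.items()
    }
    return dataset, truth


def _shift_path(
    path: Sequence[tuple[str, float]], t0: float, duration: float
) -> list[tuple[str, float]]:
    """Restrict a path to [t0, t0 + duration) and rebase time to zero."""
    out: list[tuple[str, float]] = []
    for (s, t), (_, t_next) in zip(path, list(path[1:]) + [(None, np.inf)]):
        if t_next <= t0 or t >= t0 + duration:
            continue
        out.append((s, max(t - t0, 0.0)))
    return out
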