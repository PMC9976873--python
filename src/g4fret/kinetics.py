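"""Off-path folding model of consecutive telomeric G-quadruplexes.

An eight-repeat human telomeric strand (Tel8) can hold two G-quadruplexes
(G4s) at once.  A first G4 nucleates at any of five repeat positions; only
the two terminal positions leave room for a second G4 ("on-path"), while a
G4 in any of the three internal positions blocks full folding ("off-path")
and must unfold before the strand can fully condense.  The model is a
continuous-time Markov chain over seven states:

    U            unfolded strand
    P2 .. P6     one G4 at repeat position 2..6 (P2, P6 on-path by default)
    F            two consecutive G4s (fully folded)

with rate constants

    k_f    total nucleation rate out of U (split over positions by
           ``nucleation_weights``, so the unfolded-state lifetime is 1/k_f)
    k_u    unfolding rate of a single G4 (position independent)
    k_f2   folding rate of the second G4 (on-path states only)
    k_u2   unfolding rate of the second G4 (F returns to on-path states)

The chain is a tree, so detailed balance yields a closed-form stationary
distribution which is cross-checked against the numerical null space of
the rate matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm, null_space
from scipy.optimize import least_squares

__all__ = [
    "STATES",
    "P_STATES",
    "ON_PATH_DEFAULT",
    "KineticModel",
    "Occupancy",
    "TimeCourse",
    "RateFitResult",
    "RateFitter",
    "rate_matrix",
    "initial_partition",
    "simulate_ode",
    "sample_ctmc_path",
    "simulate_gillespie",
    "folded_fraction_curve",
    "equilibrium",
    "fit_rates",
    "delta_g",
]

P_STATES: tuple[str, ...] = ("P2", "P3", "P4", "P5", "P6")
STATES: tuple[str, ...] = ("U",) + P_STATES + ("F",)
ON_PATH_DEFAULT: tuple[str, ...] = ("P2", "P6")

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: gas constant in kJ mol^-1 K^-1
R_GAS = 8.31446261815324e-3

RATE_NAMES = ("k_f", "k_u", "k_f2", "k_u2")


@dataclass(frozen=True)
class KineticModel:
    """Rate constants and topology of the off-path folding model.

    Parameters
    ----------
    k_f, k_u, k_f2, k_u2
        First/second G4 folding and unfolding rate constants, 1/s.
        ``k_f`` is the *total* exit rate from U; it is split across
        positions by ``nucleation_weights``.
    on_path
        One-G4 states from which the second G4 can fold directly.
    nucleation_weights
        Probability of nucleating at each of P2..P6; must sum to 1.
    """

    k_f: float
    k_u: float
    k_f2: float = 0.0
    k_u2: float = 0.0
    on_path: tuple[str, ...] = ON_PATH_DEFAULT
    nucleation_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        object.__setattr__(self, "on_path", tuple(self.on_path))
        object.__setattr__(
            self, "nucleation_weights", tuple(float(w) for w in self.nucleation_weights)
        )
        if len(self.nucleation_weights) != len(P_STATES):
            raise ValueError("nucleation_weights must have one entry per P-state")
        w = np.asarray(self.nucleation_weights)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("nucleation_weights must be non-negative and sum to 1")
        unknown = set(self.on_path) - set(P_STATES)
        if unknown:
            raise ValueError(f"on_path contains unknown states: {sorted(unknown)}")
        if self.k_f2 > 0 and not self.on_path:
            raise ValueError("on_path must be non-empty when k_f2 > 0")

    @property
    def rates(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    def with_rates(self, **rates: float) -> "KineticModel":
        return replace(self, **rates)

    @property
    def on_path_weight(self) -> float:
        """Total nucleation probability landing in an on-path state."""
        return sum(
            w for s, w in zip(P_STATES, self.nucleation_weights) if s in self.on_path
        )


@dataclass(frozen=True)
class Occupancy:
    """State-probability vector at one time point."""

    time: float
    probabilities: np.ndarray  # aligned with STATES

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (len(STATES),):
            raise ValueError(f"expected {len(STATES)} state probabilities")
        if np.any(p < -1e-10) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[STATE_INDEX[state]])


@dataclass(frozen=True)
class TimeCourse:
    """Folded-fraction observations (or model output) versus time."""

    times: np.ndarray
    folded_fraction: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.folded_fraction, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "folded_fraction", f)
        if self.uncertainty is not None:
            object.__setattr__(self, "uncertainty", np.asarray(self.uncertainty, float))
        if t.ndim != 1 or f.shape != t.shape:
            raise ValueError("times and folded_fraction must be 1-D and aligned")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("times must be non-negative and sorted")
        if np.any((f < -1e-9) | (f > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")


def rate_matrix(model: KineticModel) -> np.ndarray:
    """Infinitesimal generator Q over ``STATES`` (rows sum to zero).

    U -> Pi at k_f * w_i; Pi -> U at k_u; Pi -> F at k_f2 for on-path i;
    F -> on-path Pi at k_u2 split by renormalized nucleation weights.
    """
    n = len(STATES)
    Q = np.zeros((n, n))
    iU, iF = STATE_INDEX["U"], STATE_INDEX["F"]
    on_w = model.on_path_weight
    for s, w in zip(P_STATES, model.nucleation_weights):
        i = STATE_INDEX[s]
        Q[iU, i] = model.k_f * w
        Q[i, iU] = model.k_u
        if s in model.on_path:
            Q[i, iF] = model.k_f2
            if on_w > 0:
                Q[iF, i] = model.k_u2 * w / on_w
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def initial_partition(model: KineticModel) -> tuple[Occupancy, float]:
    """Occupancy just after fast nucleation, and the on-path fraction.

    Under kinetic equipartitioning every nucleation position is equally
    likely, so immediately after the burst of first-G4 folding the
    population is spread over P2..P6 by the nucleation weights; with the
    default uniform weights and terminal on-path states this puts 40% of
    molecules on-path and 60% off-path.
    """
    p = np.zeros(len(STATES))
    for s, w in zip(P_STATES, model.nucleation_weights):
        p[STATE_INDEX[s]] = w
    return Occupancy(0.0, p), model.on_path_weight


def _as_probability_vector(p0: Occupancy | Sequence[float] | Mapping[str, float]) -> np.ndarray:
    if isinstance(p0, Occupancy):
        return p0.probabilities.copy()
    if isinstance(p0, Mapping):
        v = np.zeros(len(STATES))
        for s, val in p0.items():
            v[STATE_INDEX[s]] = val
        return v
    v = np.asarray(p0, dtype=float)
    if v.shape != (len(STATES),):
        raise ValueError(f"expected a vector of length {len(STATES)}")
    return v


def all_unfolded() -> Occupancy:
    """Initial condition after LiCl -> folding-buffer exchange: all U."""
    p = np.zeros(len(STATES))
    p[STATE_INDEX["U"]] = 1.0
    return Occupancy(0.0, p)


def simulate_ode(
    model: KineticModel,
    p0: Occupancy | Sequence[float] | Mapping[str, float],
    times: Sequence[float],
) -> list[Occupancy]:
    """Solve the master equation dp/dt = p Q at the requested times.

    Uses the matrix exponential of the fixed generator, which is exact for
    a time-homogeneous chain; probabilities are conserved by construction.
    """
    p = _as_probability_vector(p0)
    if abs(p.sum() - 1.0) > 1e-8 or np.any(p < -1e-12):
        raise ValueError("initial occupancy must be a normalized probability vector")
    Q = rate_matrix(model)
    out: list[Occupancy] = []
    # One eigendecomposition serves every time point; expm is the fallback
    # when the generator is defective or badly conditioned.
    try:
        lam, V = np.linalg.eig(Q.T)
        Vinv = np.linalg.inv(V)
        use_eig = np.linalg.cond(V) < 1e10
    except np.linalg.LinAlgError:
        use_eig = False
    for t in times:
        if t < 0:
            raise ValueError("times must be non-negative")
        if t == 0:
            out.append(Occupancy(0.0, p.copy()))
            continue
        if use_eig:
            pt = (V @ (np.exp(lam * t) * (Vinv @ p))).real
        else:
            pt = p @ expm(Q * t)
        pt = np.clip(pt, 0.0, None)
        pt /= pt.sum()
        out.append(Occupancy(float(t), pt))
    return out


def sample_ctmc_path(
    model: KineticModel,
    t_max: float,
    initial_state: str = "U",
    seed: int | np.random.Generator | None = None,
) -> list[tuple[str, float]]:
    """Exact stochastic simulation of one state path on [0, t_max].

    Returns a piecewise-constant path as ``[(state, entry_time), ...]``;
    holding times are exponential with the state's total exit rate.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if initial_state not in STATE_INDEX:
        raise ValueError(f"unknown initial state {initial_state!r}")
    rng = np.random.default_rng(seed)
    Q = rate_matrix(model)
    path: list[tuple[str, float]] = [(initial_state, 0.0)]
    i = STATE_INDEX[initial_state]
    t = 0.0
    while True:
        exit_rate = -Q[i, i]
        if exit_rate <= 0:
            break  # absorbing
        t += rng.exponential(1.0 / exit_rate)
        if t >= t_max:
            break
        probs = Q[i].copy()
        probs[i] = 0.0
        probs /= probs.sum()
        i = rng.choice(len(STATES), p=probs)
        path.append((STATES[i], t))
    return path


def simulate_gillespie(
    model: KineticModel,
    n_molecules: int,
    times: Sequence[float],
    seed: int | np.random.Generator | None = None,
    p0: Occupancy | None = None,
) -> tuple[list[Occupancy], np.ndarray]:
    """Stochastic twin of :func:`simulate_ode`.

    Simulates ``n_molecules`` independent molecules jump-by-jump
    (vectorized across molecules) and returns empirical occupancies at the
    requested times together with binomial standard errors, shape
    ``(n_times, n_states)``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    times_arr = np.asarray(times, dtype=float)
    if np.any(times_arr < 0) or np.any(np.diff(times_arr) < 0):
        raise ValueError("times must be non-negative and sorted")
    rng = np.random.default_rng(seed)
    Q = rate_matrix(model)
    exit_rates = -np.diag(Q)
    jump_probs = Q.copy()
    np.fill_diagonal(jump_probs, 0.0)
    with np.errstate(invalid="ignore"):
        jump_cdf = np.cumsum(
            np.where(exit_rates[:, None] > 0, jump_probs / np.where(exit_rates, exit_rates, 1.0)[:, None], 0.0),
            axis=1,
        )

    if p0 is None:
        states = np.full(n_molecules, STATE_INDEX["U"], dtype=np.intp)
    else:
        states = rng.choice(len(STATES), size=n_molecules, p=p0.probabilities)
    t = np.zeros(n_molecules)
    t_max = times_arr[-1] if times_arr.size else 0.0
    nt, ns = times_arr.size, len(STATES)
    # Each constant-state segment [t, t_next) covers a contiguous run of
    # query indices; book it in a difference array and cumulate at the end.
    diff = np.zeros((nt + 1, ns))
    alive = np.ones(n_molecules, dtype=bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        er = exit_rates[states[idx]]
        holding = np.full(idx.size, np.inf)
        pos = er > 0
        if pos.any():
            holding[pos] = rng.exponential(1.0 / er[pos])
        t_next = t[idx] + holding
        i0 = np.searchsorted(times_arr, t[idx], side="left")
        i1 = np.searchsorted(times_arr, t_next, side="left")
        seg = i1 > i0
        np.add.at(diff, (i0[seg], states[idx[seg]]), 1.0)
        np.add.at(diff, (i1[seg], states[idx[seg]]), -1.0)
        done = (t_next > t_max) | ~pos
        alive[idx[done]] = False
        cont = idx[~done]
        if cont.size:
            u = rng.random(cont.size)
            states[cont] = np.argmax(jump_cdf[states[cont]] >= u[:, None], axis=1)
            t[cont] = t_next[~done]
    counts = np.cumsum(diff[:-1], axis=0)
    freqs = counts / n_molecules
    se = np.sqrt(np.clip(freqs * (1 - freqs), 0, None) / n_molecules)
    occs = [Occupancy(float(tq), f / f.sum()) for tq, f in zip(times_arr, freqs)]
    return occs, se


def folded_fraction_curve(
    occupancies: Iterable[Occupancy],
    folded_states: tuple[str, ...] = ("F",),
) -> TimeCourse:
    """Fraction of fully folded molecules (the only state with E >= 0.6
    under the default emission map) versus time."""
    occs = list(occupancies)
    times = np.array([o.time for o in occs])
    frac = np.array([sum(o[s] for s in folded_states) for o in occs])
    return TimeCourse(times, np.clip(frac, 0.0, 1.0))


def equilibrium(model: KineticModel, method: str = "closed_form") -> Occupancy:
    """Stationary distribution of the folding chain.

    The state graph is a tree, so detailed balance gives the closed form
    (unnormalized)::

        pi_U = 1,  pi_Pi = k_f w_i / k_u,  pi_F = k_f k_f2 W / (k_u k_u2)

    with W the total on-path nucleation weight.  ``method="nullspace"``
    instead computes the null space of Q^T numerically; the two must agree
    to ~1e-10 on any irreducible model.
    """
    if model.k_f <= 0 or model.k_u <= 0:
        raise ValueError("chain is reducible: k_f and k_u must both be positive")
    if model.k_f2 > 0 and model.k_u2 <= 0:
        raise ValueError("chain is reducible: F is absorbing (k_f2 > 0, k_u2 = 0)")
    if method == "nullspace":
        Q = rate_matrix(model)
        ns = null_space(Q.T, rcond=1e-12)
        if ns.shape[1] != 1:
            raise ValueError("rate matrix does not have a unique stationary vector")
        v = ns[:, 0]
        v = v * np.sign(v.sum())
        return Occupancy(np.inf, np.clip(v, 0, None) / v.sum())
    if method != "closed_form":
        raise ValueError(f"unknown method {method!r}")
    pi = np.zeros(len(STATES))
    pi[STATE_INDEX["U"]] = 1.0
    for s, w in zip(P_STATES, model.nucleation_weights):
        pi[STATE_INDEX[s]] = model.k_f * w / model.k_u
    if model.k_f2 > 0:
        W = model.on_path_weight
        pi[STATE_INDEX["F"]] = model.k_f * model.k_f2 * W / (model.k_u * model.k_u2)
    return Occupancy(np.inf, pi / pi.sum())


# ---------------------------------------------------------------------------
# rate fitting


@dataclass
class RateFitResult:
    model: KineticModel
    free: tuple[str, ...]
    cost: float
    residuals: np.ndarray
    stderr: dict[str, float]
    n_starts: int
    identifiable: bool
    dof: int
    profile_ci: dict[str, tuple[float, float]] | None = None


class RateFitter:
    """Weighted least-squares fit of the folding rate constants to a
    folded-fraction time course (sklearn-style estimator).

    The model curve is ``folded_fraction_curve(simulate_ode(...))`` from an
    all-unfolded start; free rates are optimized in log space with
    multi-start local search (plateaus are common in this 4-parameter
    landscape).

    Parameters
    ----------
    template : KineticModel
        Topology and starting rates; fixed rates are taken from here.
    fixed : sequence of rate names to hold at template values.
    n_starts : number of random restarts (log-uniform over bounds).
    bounds : (lo, hi) bounds on every free rate, 1/s.
    random_state : seed for the restart draws.
    """

    def __init__(
        self,
        template: KineticModel,
        fixed: Sequence[str] = (),
        n_starts: int = 20,
        bounds: tuple[float, float] = (1e-6, 1e3),
        random_state: int | None = 0,
    ) -> None:
        self.template = template
        self.fixed = tuple(fixed)
        self.n_starts = n_starts
        self.bounds = bounds
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "template": self.template,
            "fixed": self.fixed,
            "n_starts": self.n_starts,
            "bounds": self.bounds,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "RateFitter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------

    def _model_curve(self, rates: Mapping[str, float], times: np.ndarray) -> np.ndarray:
        model = self.template.with_rates(**rates)
        occs = simulate_ode(model, all_unfolded(), times)
        return folded_fraction_curve(occs).folded_fraction

    def _residual_fn(self, times, y, w, free):
        def fn(log_rates: np.ndarray) -> np.ndarray:
            rates = {name: float(np.exp(lr)) for name, lr in zip(free, log_rates)}
            return (self._model_curve(rates, times) - y) * w

        return fn

    def fit(self, times, fractions, sd=None) -> "RateFitter":
        unknown = set(self.fixed) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate names in fixed: {sorted(unknown)}")
        free = tuple(n for n in RATE_NAMES if n not in self.fixed)
        times = np.asarray(times, dtype=float)
        y = np.asarray(fractions, dtype=float)
        if sd is None:
            w = np.ones_like(y)
        else:
            sd = np.asarray(sd, dtype=float)
            w = 1.0 / np.where(sd > 0, sd, np.nanmin(sd[sd > 0]) if np.any(sd > 0) else 1.0)
        n_free = len(free)
        if n_free == 0:
            res = (self._model_curve({}, times) - y) * w
            self.model_ = self.template
            self.free_ = free
            self.result_ = RateFitResult(
                model=self.template, free=free, cost=0.5 * float(res @ res),
                residuals=res, stderr={}, n_starts=0, identifiable=True,
                dof=0,
            )
            return self
        if np.count_nonzero(np.diff(np.round(y, 12)) != 0) + 1 < n_free and times.size < n_free:
            raise ValueError(f"need at least {n_free} non-degenerate time points")

        rng = np.random.default_rng(self.random_state)
        lo, hi = np.log(self.bounds[0]), np.log(self.bounds[1])
        fn = self._residual_fn(times, y, w, free)
        starts = [np.array([np.log(max(getattr(self.template, n), self.bounds[0])) for n in free])]
        starts += [rng.uniform(lo, hi, size=n_free) for _ in range(max(self.n_starts - 1, 0))]
        solutions = []
        for x0 in starts:
            try:
                sol = least_squares(fn, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            solutions.append(sol)
        if not solutions:
            raise RuntimeError("all optimization starts failed")
        solutions.sort(key=lambda s: s.cost)
        best = solutions[0]
        rates = {n: float(np.exp(v)) for n, v in zip(free, best.x)}
        fitted = self.template.with_rates(**rates)

        # flat-objective detection: near-optimal solutions far apart in
        # parameter space signal non-identifiability
        tol = max(1e-10, 1e-3 * (best.cost + 1e-12))
        near = [s for s in solutions if s.cost <= best.cost + tol]
        spread = max((np.max(np.abs(s.x - best.x)) for s in near), default=0.0)
        identifiable = spread < np.log(1.5)

        stderr = self._covariance_stderr(best, free)
        self.model_ = fitted
        self.free_ = free
        self.result_ = RateFitResult(
            model=fitted, free=free, cost=float(best.cost),
            residuals=best.fun, stderr=stderr, n_starts=len(starts),
            identifiable=identifiable, dof=int(times.size - n_free),
        )
        if not identifiable:
            import warnings

            warnings.warn(
                "rate fit is not identifiable: multiple parameter sets reach "
                "the optimum (flat objective)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    @staticmethod
    def _covariance_stderr(sol, free) -> dict[str, float]:
        J = sol.jac
        n, p = J.shape
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se_log = np.full(p, np.nan)
        # delta method: se(k) = k * se(log k)
        return {n_: float(np.exp(x) * s) for n_, x, s in zip(free, sol.x, se_log)}

    def predict(self, times) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the estimator first")
        return self._model_curve({}, np.asarray(times, float)) if not self.free_ else self._model_curve(
            {n: getattr(self.model_, n) for n in self.free_}, np.asarray(times, float)
        )

    def profile_ci(self, times, fractions, sd=None, n_grid: int = 21) -> dict[str, tuple[float, float]]:
        """Profile-likelihood ~68% intervals (chi-square +1 crossing) on the
        free rates, re-optimizing the remaining rates at every grid point."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator first")
        times = np.asarray(times, float)
        y = np.asarray(fractions, float)
        w = np.ones_like(y) if sd is None else 1.0 / np.asarray(sd, float)
        out: dict[str, tuple[float, float]] = {}
        best_cost = self.result_.cost
        target = best_cost + 0.5  # 0.5*chi2 convention of least_squares cost
        for name in self.free_:
            khat = getattr(self.model_, name)
            others = tuple(n for n in self.free_ if n != name)
            grid = khat * np.exp(np.linspace(-2.5, 2.5, n_grid))
            costs = np.empty(n_grid)
            for i, kval in enumerate(grid):
                tmpl = self.model_.with_rates(**{name: float(kval)})
                sub = RateFitter(tmpl, fixed=tuple(set(RATE_NAMES) - set(others)),
                                 n_starts=3, bounds=self.bounds,
                                 random_state=self.random_state)
                try:
                    sub.fit(times, y, sd)
                    costs[i] = sub.result_.cost
                except Exception:
                    costs[i] = np.inf
            inside = costs <= target
            if inside.any():
                out[name] = (float(grid[inside].min()), float(grid[inside].max()))
            else:
                out[name] = (float(khat), float(khat))
        self.result_.profile_ci = out
        return out


def fit_rates(
    observed: TimeCourse,
    model_template: KineticModel,
    fixed: Sequence[str] = (),
    n_starts: int = 20,
    seed: int | None = 0,
) -> RateFitResult:
    """Functional wrapper over :class:`RateFitter`."""
    est = RateFitter(model_template, fixed=fixed, n_starts=n_starts, random_state=seed)
    est.fit(observed.times, observed.folded_fraction, observed.uncertainty)
    return est.result_


def delta_g(k_fold: float, k_unfold: float, temperature: float = 298.15) -> float:
    """Gibbs free energy of folding from the rate ratio, kJ/mol.

    dG = -R T ln(k_fold / k_unfold); negative when folding is favourable.
    """
    if k_fold <= 0 or k_unfold <= 0:
        raise ValueError("rates must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -R_GAS * temperature * float(np.log(k_fold / k_unfold))
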