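"""Least-squares calibration of the driver model by multi-start Powell search.

Shared (fixed-effect) parameters — the two event-rate elasticities, the
driving-suppression slope and the event decay time — are estimated jointly
with per-driver parameters (driving need, initial event rate) by minimising
one pooled mean squared error between simulated and observed events/month
and miles/month.  Because the two series differ by more than an order of
magnitude in scale, each series' squared errors are standardised by the
observed series' population variance before pooling, making the objective
scale-free.

The optimiser is a multi-start derivative-free search that exploits the
problem's structure.  Given the shared parameters the pooled objective
separates across drivers, so every evaluation of the shared block profiles
out the per-driver parameters: a coarse joint grid scan (which cannot be
trapped on the plateaus where candidate parameters collapse driving to
zero) followed by a vectorised damped Gauss-Newton refinement of all
drivers' small least-squares subproblems at once.  The shared block itself
is minimised by Powell's conjugate-direction method with bounded
golden-section line searches.  Start points are sampled uniformly within
box bounds; per-driver start coordinates are keyed to the driver id, not
the panel position, so results are invariant to driver ordering.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .model import SimulationConfig, Trajectory, simulate_cohort_paths

__all__ = [
    "CalibrationProblem",
    "OptimizerSettings",
    "CalibrationResult",
    "CalibrationError",
    "objective",
    "calibrate",
    "bootstrap_ci",
    "DEFAULT_BOUNDS",
]

SHARED_DEFAULT = ("beta1", "beta2", "beta3", "event_decay_time")
INDIVIDUAL_DEFAULT = ("driving_need", "initial_event_rate")
_ALL_PARAMS = (
    "beta1", "beta2", "beta3", "event_decay_time", "risky_fraction",
    "driving_need", "initial_event_rate",
)
# initial_recent_events may additionally be calibrated (shared or per driver)
_EXTRA = ("initial_recent_events",)

#: Default box bounds; negative-effect parameters span a scale-appropriate
#: negative range, the decay time (0.1, 24] months, rates strictly positive.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta1": (-0.002, 0.0),
    "beta2": (-0.05, 0.0),
    "beta3": (-20.0, 0.0),
    "event_decay_time": (0.1, 24.0),
    "risky_fraction": (0.0, 1.0),
    "driving_need": (0.0, 3000.0),
    "initial_event_rate": (1e-4, 1.5),
    "initial_recent_events": (0.0, 500.0),
}

_PENALTY = 1e12
_BLOWUP = 1e30


class CalibrationError(RuntimeError):
    pass


@njit(cache=True)
def _sim_kernel(b1, b2, b3, tau, frac, need, rate, r0, c0, spm, out_ev, out_mi):
    """Euler-simulate all drivers, writing monthly events and miles.

    Scalar inner loops, no allocations: this is the hot path of the
    multi-start search.  Numerical blow-up writes large finite values so the
    squared error stays finite and steers the search away smoothly.
    """
    m, d = out_ev.shape
    dt = 1.0 / spm
    for i in range(d):
        recent = r0[i]
        cum = c0[i]
        bad = False
        for t in range(m):
            ev_m = 0.0
            mi_m = 0.0
            if not bad:
                for _ in range(spm):
                    z = b1 * cum + b2 * recent
                    if z > 50.0:
                        bad = True
                        break
                    epm = rate[i] * np.exp(z)
                    driving = need[i] + b3 * recent
                    if driving < 0.0:
                        driving = 0.0
                    flow = epm * driving
                    ev_m += flow * dt
                    mi_m += driving * dt
                    recent = recent + dt * (flow * frac - recent / tau)
                    if recent < 0.0:
                        recent = 0.0
                    cum = cum + dt * driving
            if bad or not (np.isfinite(ev_m) and np.isfinite(mi_m)):
                bad = True
                out_ev[t, i] = 1e9
                out_mi[t, i] = 1e9
            else:
                out_ev[t, i] = ev_m
                out_mi[t, i] = mi_m


@dataclass(frozen=True)
class OptimizerSettings:
    """Multi-start search settings.

    ``n_starts`` points are sampled uniformly within bounds and searched
    briefly (``explore_iter`` outer Powell iterations); the best
    ``n_polish`` candidates are then polished with up to ``max_iter`` outer
    iterations at relative objective tolerance ``tolerance``.
    """

    n_starts: int = 200
    seed: int = 0
    max_iter: int = 60
    tolerance: float = 1e-10
    explore_iter: int = 1
    n_polish: int = 2

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class CalibrationProblem:
    """Observed panel plus the parameter partition and bounds.

    ``shared_params`` are common to all drivers, ``individual_params`` vary
    per driver, ``fixed`` are held constant; the three sets must be disjoint
    and cover every model parameter.  ``config`` supplies the time grid and
    the initial stocks used when ``initial_recent_events`` is not calibrated.
    ``aggregate=True`` averages the panel into one pseudo-driver and fits
    that single series pair.
    """

    panel: tuple[Trajectory, ...]
    shared_params: tuple[str, ...] = SHARED_DEFAULT
    individual_params: tuple[str, ...] = INDIVIDUAL_DEFAULT
    fixed: dict = field(default_factory=lambda: {"risky_fraction": 0.07})
    bounds: dict = field(default_factory=dict)
    config: SimulationConfig = SimulationConfig()
    aggregate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "panel", tuple(self.panel))
        object.__setattr__(self, "shared_params", tuple(self.shared_params))
        object.__setattr__(self, "individual_params", tuple(self.individual_params))
        if not self.panel:
            raise ValueError("panel must contain at least one driver")
        names = list(self.shared_params) + list(self.individual_params) + list(self.fixed)
        if len(names) != len(set(names)):
            raise ValueError("shared, individual and fixed sets must be disjoint")
        missing = set(_ALL_PARAMS) - set(names)
        if missing:
            raise ValueError(f"parameter partition must cover the model: missing {sorted(missing)}")
        unknown = set(names) - set(_ALL_PARAMS) - set(_EXTRA)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        allowed_ind = {"driving_need", "initial_event_rate", "initial_recent_events"}
        bad_ind = set(self.individual_params) - allowed_ind
        if bad_ind:
            raise ValueError(
                f"only {sorted(allowed_ind)} may vary per driver; got {sorted(bad_ind)}"
            )
        m = len(self.panel[0].months)
        if m < 2:
            raise ValueError("panel needs at least 2 months per driver")
        for t in self.panel:
            if len(t.months) != m:
                raise ValueError("all drivers must share the same month grid")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass
class CalibrationResult:
    """Best fit found by the multi-start search.

    ``estimates`` maps shared parameter names to scalars and individual
    parameter names to per-driver dicts keyed by driver id.  ``ci`` is
    populated by :func:`bootstrap_ci`.
    """

    estimates: dict
    objective: float
    per_driver_fit: list[Trajectory]
    n_converged: int
    n_starts: int
    warnings: list[str] = field(default_factory=list)
    ci: dict | None = None


class _Workspace:
    """Precomputed arrays, packing and the profiled objective."""

    def __init__(self, problem: CalibrationProblem):
        self.problem = problem
        panel = sorted(problem.panel, key=lambda t: t.driver_id)
        if problem.aggregate:
            months = panel[0].months
            ev = np.mean([t.events for t in panel], axis=0)
            mi = np.mean([t.miles for t in panel], axis=0)
            panel = [Trajectory("aggregate", months, ev, mi)]
        self.panel = panel
        self.ids = [t.driver_id for t in panel]
        self.d = len(panel)
        self.m = len(panel[0].months)
        self.obs_events = np.ascontiguousarray(np.stack([t.events for t in panel], axis=1))
        self.obs_miles = np.ascontiguousarray(np.stack([t.miles for t in panel], axis=1))
        var_e = max(float(np.var(self.obs_events)), 1e-12)
        var_m = max(float(np.var(self.obs_miles)), 1e-12)
        self.w_events = 1.0 / var_e
        self.w_miles = 1.0 / var_m
        self.shared = list(problem.shared_params)
        self.individual = list(problem.individual_params)
        self.k = len(self.shared)
        self.n_ind = len(self.individual)
        self.n_free = self.k + self.d * self.n_ind
        self.sh_lo = np.array([problem.bound(n)[0] for n in self.shared])
        self.sh_span = np.array([problem.bound(n)[1] for n in self.shared]) - self.sh_lo
        self.ind_lo = np.array([problem.bound(n)[0] for n in self.individual])
        self.ind_span = np.array([problem.bound(n)[1] for n in self.individual]) - self.ind_lo
        cfg = problem.config
        self.spm = cfg.steps_per_month
        self.fixed = {
            "risky_fraction": 0.0,
            "initial_recent_events": cfg.initial_recent_events,
        }
        self.fixed.update(problem.fixed)
        self._c0 = np.full(self.d, float(cfg.initial_cumulative_miles))
        self._ev = np.empty((self.m, self.d))
        self._mi = np.empty((self.m, self.d))
        self._buf = {
            name: np.empty(self.d)
            for name in ("driving_need", "initial_event_rate", "initial_recent_events")
        }
        self._cached_svals: dict | None = None
        self._sv_scalars: tuple | None = None
        # per-driver coordinates in [0,1] tracking the current profile point
        self.xind = np.full((self.n_ind, self.d), 0.5)

    # -- packing ---------------------------------------------------------
    def pack01(self, candidate: dict) -> np.ndarray:
        """Joint [0,1] vector [shared..., block per individual parameter]."""
        x = np.empty(self.n_free)
        for i, name in enumerate(self.shared):
            x[i] = candidate[name]
        for j, name in enumerate(self.individual):
            v = candidate[name]
            if isinstance(v, dict):
                arr = np.array([v[i_] for i_ in self.ids], dtype=float)
            else:
                arr = np.broadcast_to(np.asarray(v, dtype=float), (self.d,)).copy()
            x[self.k + j * self.d : self.k + (j + 1) * self.d] = arr
        x[: self.k] = (x[: self.k] - self.sh_lo) / self.sh_span
        for j in range(self.n_ind):
            sl = slice(self.k + j * self.d, self.k + (j + 1) * self.d)
            x[sl] = (x[sl] - self.ind_lo[j]) / self.ind_span[j]
        return x

    def split(self, x01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xsh = np.clip(x01[: self.k], 0.0, 1.0)
        if self.n_ind:
            xind = np.clip(x01[self.k :].reshape(self.n_ind, self.d), 0.0, 1.0)
        else:
            xind = np.empty((0, self.d))
        return xsh, xind

    def shared_values(self, xsh01: np.ndarray) -> dict:
        vals = dict(self.fixed)
        nat = self.sh_lo + self.sh_span * np.clip(xsh01, 0.0, 1.0)
        for i, name in enumerate(self.shared):
            vals[name] = float(nat[i])
        return vals

    def ind_natural(self, xind01: np.ndarray) -> dict:
        return {
            name: self.ind_lo[j] + self.ind_span[j] * np.clip(xind01[j], 0.0, 1.0)
            for j, name in enumerate(self.individual)
        }

    # -- objective -------------------------------------------------------
    def _prep(self, svals: dict) -> None:
        self._sv_scalars = (
            svals["beta1"], svals["beta2"], svals["beta3"],
            svals["event_decay_time"], svals["risky_fraction"],
        )
        for name, buf in self._buf.items():
            if name not in self.individual:
                buf.fill(float(svals[name]))
        self._cached_svals = svals

    def simulate01(self, svals: dict, xind01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Simulated (events, miles) panels at a scaled point; reuses buffers."""
        if svals is not self._cached_svals:
            self._prep(svals)
        for j, name in enumerate(self.individual):
            buf = self._buf[name]
            np.clip(xind01[j], 0.0, 1.0, out=buf)
            buf *= self.ind_span[j]
            buf += self.ind_lo[j]
        _sim_kernel(
            *self._sv_scalars,
            self._buf["driving_need"],
            self._buf["initial_event_rate"],
            self._buf["initial_recent_events"],
            self._c0, self.spm, self._ev, self._mi,
        )
        return self._ev, self._mi

    def per_driver_sse(self, svals: dict, xind01: np.ndarray) -> np.ndarray:
        ev, mi = self.simulate01(svals, xind01)
        return (
            self.w_events * np.sum((ev - self.obs_events) ** 2, axis=0)
            + self.w_miles * np.sum((mi - self.obs_miles) ** 2, axis=0)
        )

    def residuals(self, svals: dict, xind01: np.ndarray) -> np.ndarray:
        """Stacked weighted residuals, shape (2m, d)."""
        ev, mi = self.simulate01(svals, xind01)
        return np.concatenate(
            [
                np.sqrt(self.w_events) * (ev - self.obs_events),
                np.sqrt(self.w_miles) * (mi - self.obs_miles),
            ],
            axis=0,
        )

    # -- inner (per-driver) profiling ------------------------------------
    def inner_solve(
        self, svals: dict, xind: np.ndarray, grid: int = 5, n_gn: int = 8
    ) -> np.ndarray:
        """Profile out every driver's block, vectorised across drivers.

        A joint grid scan over the block (with the incoming point as one
        extra candidate) picks a basin per driver; a damped Gauss-Newton
        iteration on each driver's least-squares subproblem then refines to
        high precision.  Fixed iteration counts and the deep refinement make
        the result an (effectively) deterministic function of ``svals``.
        Mutates ``xind``; returns the per-driver SSE at the final point.
        """
        if self.n_ind == 0:
            return self.per_driver_sse(svals, xind)
        # candidate set: incoming point, coarse joint grid, and a
        # data-informed moment-matching guess; the two best distinct
        # candidates per driver seed the refinement
        cands = [xind.copy(), self._moment_candidate(svals)]
        pts = np.linspace(0.0, 1.0, grid)
        xtmp = np.empty_like(xind)
        for combo in itertools.product(pts, repeat=self.n_ind):
            for j in range(self.n_ind):
                xtmp[j] = combo[j]
            cands.append(xtmp.copy())
        f_all = np.stack([self.per_driver_sse(svals, c) for c in cands], axis=0)
        order = np.argsort(f_all, axis=0)
        x_all = np.stack(cands, axis=0)  # (n_cand, n_ind, d)
        cols = np.arange(self.d)
        results = []
        for rank in range(2):
            pick = order[rank]
            xr = np.ascontiguousarray(
                np.transpose(x_all[pick, :, cols])  # (d, n_ind) -> (n_ind, d)
            )
            fr = self._gauss_newton(svals, xr, f_all[pick, cols], n_gn)
            results.append((fr, xr))
        f0, x0 = results[0]
        f1, x1 = results[1]
        better1 = f1 < f0
        for j in range(self.n_ind):
            xind[j] = np.where(better1, x1[j], x0[j])
        return np.where(better1, f1, f0)

    def _moment_candidate(self, svals: dict) -> np.ndarray:
        """Per-driver start from the observed series: driving need from the
        miles law with a decay-projected recent-events path, event rate from
        observed events over rate-law-adjusted exposure."""
        tau = svals["event_decay_time"]
        b1, b2, b3 = svals["beta1"], svals["beta2"], svals["beta3"]
        r0 = self._r0_guess(svals)
        decay = np.maximum(1.0 - 1.0 / (tau * self.spm), 0.0) ** (
            self.spm * np.arange(self.m)
        )
        r_path = r0[None, :] * decay[:, None]  # (m, d)
        cum = np.vstack([np.zeros(self.d), np.cumsum(self.obs_miles, axis=0)[:-1]])
        cand = np.empty((self.n_ind, self.d))
        nat = {
            "driving_need": np.mean(self.obs_miles - b3 * r_path, axis=0),
            "initial_recent_events": r0,
        }
        expo = np.sum(self.obs_miles * np.exp(b1 * cum + b2 * r_path), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.sum(self.obs_events, axis=0) / expo
        nat["initial_event_rate"] = np.where(np.isfinite(rate), rate, 0.05)
        for j, name in enumerate(self.individual):
            cand[j] = (nat[name] - self.ind_lo[j]) / self.ind_span[j]
        return np.clip(cand, 0.0, 1.0)

    def _r0_guess(self, svals: dict) -> np.ndarray:
        if "initial_recent_events" in self.individual:
            return np.full(self.d, float(self.fixed["initial_recent_events"]))
        return np.full(self.d, float(svals["initial_recent_events"]))

    def _gauss_newton(
        self, svals: dict, xind: np.ndarray, fx: np.ndarray, n_gn: int
    ) -> np.ndarray:
        """Damped Gauss-Newton on every driver's block at once, in place."""
        n = self.n_ind
        lam = np.full(self.d, 1e-3)
        h = 1e-6
        eye = np.eye(n)[None, :, :]
        for _ in range(n_gn):
            r0 = self.residuals(svals, xind).copy()
            jac = np.empty((2 * self.m, n, self.d))
            for j in range(n):
                step = np.where(xind[j] + h <= 1.0, h, -h)
                xind[j] += step
                rj = self.residuals(svals, xind)
                jac[:, j, :] = (rj - r0) / step
                xind[j] -= step
            a = np.einsum("rjd,rkd->djk", jac, jac)
            g = np.einsum("rjd,rd->dj", jac, r0)
            diag = np.maximum(np.einsum("djj->dj", a), 1e-12)
            damp = a + (lam[:, None] * diag)[:, :, None] * eye
            try:
                delta = -np.linalg.solve(damp, g[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                delta = -g / diag
            xcand = np.clip(xind + delta.T, 0.0, 1.0)
            fc = self.per_driver_sse(svals, xcand)
            accept = fc < fx
            for j in range(n):
                xind[j] = np.where(accept, xcand[j], xind[j])
            fx = np.where(accept, fc, fx)
            lam = np.where(accept, lam / 3.0, lam * 10.0)
            np.clip(lam, 1e-9, 1e6, out=lam)
        return fx

    # -- start sampling ---------------------------------------------------
    def starts(self, seed: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Uniform starts: shared (n, k) and individual (n, n_ind, d) blocks,
        the latter keyed to driver ids for panel-order invariance."""
        rng = np.random.default_rng([seed, 0x5EED])
        sh = rng.uniform(size=(n, self.k))
        ind = np.empty((n, self.n_ind, self.d))
        for pos, did in enumerate(self.ids):
            rng_d = np.random.default_rng([seed, zlib.crc32(did.encode())])
            ind[:, :, pos] = rng_d.uniform(size=(n, self.n_ind))
        return sh, ind

    def profile_objective(self, xsh01: np.ndarray, grid: int, n_gn: int) -> float:
        svals = self.shared_values(xsh01)
        fx = self.inner_solve(svals, self.xind, grid, n_gn)
        total = float(np.sum(fx))
        if not np.isfinite(total) or total >= 1e9:
            return _PENALTY
        return total / (2 * self.d * self.m)


def objective(candidate: dict, problem: CalibrationProblem) -> float:
    """Pooled variance-standardised MSE of a candidate parameter assignment.

    ``candidate`` maps each free parameter name to a scalar (shared) or to a
    per-driver mapping/array (individual).  Non-finite simulations return a
    large finite penalty.
    """
    ws = _Workspace(problem)
    xsh, xind = ws.split(ws.pack01(candidate))
    total = float(np.sum(ws.per_driver_sse(ws.shared_values(xsh), xind)))
    if not np.isfinite(total) or total >= 1e9:
        return _PENALTY
    return total / (2 * ws.d * ws.m)


def _golden_line(f, x, u, fx, n_iter: int):
    """Bounded golden-section line search along direction ``u`` from ``x``.

    The search interval is the intersection of the line with the unit box;
    the incumbent point is always a candidate, so the step never increases
    the objective.  Returns (x_new, f_new).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hi = np.where(u > 0, (1.0 - x) / u, np.where(u < 0, -x / u, np.inf))
        t_lo = np.where(u > 0, -x / u, np.where(u < 0, (1.0 - x) / u, -np.inf))
    hi = float(np.min(t_hi))
    lo = float(np.max(t_lo))
    if not np.isfinite(hi) or not np.isfinite(lo) or hi <= lo:
        return x, fx
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d_ = a + invphi * (b - a)
    fc = f(np.clip(x + c * u, 0.0, 1.0))
    fd = f(np.clip(x + d_ * u, 0.0, 1.0))
    for _ in range(n_iter):
        if fc <= fd:
            b, d_, fd = d_, c, fc
            c = b - invphi * (b - a)
            fc = f(np.clip(x + c * u, 0.0, 1.0))
        else:
            a, c, fc = c, d_, fd
            d_ = a + invphi * (b - a)
            fd = f(np.clip(x + d_ * u, 0.0, 1.0))
    t_best, f_best = (c, fc) if fc <= fd else (d_, fd)
    if f_best < fx:
        return np.clip(x + t_best * u, 0.0, 1.0), f_best
    return x, fx


def _powell(f, x0: np.ndarray, maxiter: int, ftol: float, ls_iters: int):
    """Powell's conjugate-direction minimisation in the unit box.

    Classic scheme: line-search each direction in turn, then replace the
    direction of largest decrease with the overall displacement and search
    along it (the 'pattern move').  Deterministic and bounded.
    """
    k = len(x0)
    x = np.clip(np.asarray(x0, dtype=float).copy(), 0.0, 1.0)
    fx = f(x)
    dirs = [np.eye(k)[i] for i in range(k)]
    for _ in range(maxiter):
        x_prev, f_prev = x.copy(), fx
        biggest, i_big = 0.0, 0
        for i, u in enumerate(dirs):
            f_before = fx
            x, fx = _golden_line(f, x, u, fx, ls_iters)
            if f_before - fx > biggest:
                biggest, i_big = f_before - fx, i
        disp = x - x_prev
        norm = float(np.linalg.norm(disp))
        if norm > 1e-14:
            u_new = disp / norm
            x, fx = _golden_line(f, x, u_new, fx, ls_iters)
            dirs[i_big] = u_new
        if f_prev - fx <= ftol * (abs(f_prev) + abs(fx)) + 1e-300:
            break
    return x, fx


def _search_from(
    ws: _Workspace,
    xsh0: np.ndarray,
    xind0: np.ndarray,
    maxiter: int,
    tol: float,
    grid: int,
    n_gn: int,
    ls_iters: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One Powell local search over the shared block with profiled drivers."""
    ws.xind = xind0.copy()
    if ws.k == 0:
        svals = ws.shared_values(np.empty(0))
        fvec = ws.inner_solve(svals, ws.xind, grid, n_gn * max(maxiter, 1))
        total = float(np.sum(fvec))
        fval = _PENALTY if (not np.isfinite(total) or total >= 1e9) else total / (2 * ws.d * ws.m)
        return fval, np.empty(0), ws.xind.copy()
    xsh, fval = _powell(
        lambda s: ws.profile_objective(s, grid, n_gn),
        xsh0, maxiter, tol, ls_iters,
    )
    return float(fval), xsh, ws.xind.copy()


def calibrate(
    problem: CalibrationProblem, settings: OptimizerSettings = OptimizerSettings()
) -> CalibrationResult:
    """Multi-start Powell minimisation of the calibration objective.

    Deterministic given (panel, bounds, settings): start points derive from
    ``settings.seed`` and driver ids.  Raises :class:`CalibrationError` when
    no start improves on the non-finite-simulation penalty.
    """
    ws = _Workspace(problem)
    warn: list[str] = []
    n_points = 2 * ws.d * ws.m
    if n_points < ws.n_free:
        warn.append(
            f"underdetermined: {ws.n_free} free parameters for {n_points} observations"
        )
    sh0, ind0 = ws.starts(settings.seed, settings.n_starts)
    explored: list[tuple[float, np.ndarray, np.ndarray]] = []
    for i in range(settings.n_starts):
        f, xsh, xind = _search_from(
            ws, sh0[i], ind0[i], settings.explore_iter, settings.tolerance,
            grid=4, n_gn=5, ls_iters=8,
        )
        explored.append((f, xsh, xind))
    explored.sort(key=lambda t: t[0])
    if explored[0][0] >= _PENALTY:
        raise CalibrationError("all starts ended at the infeasible-simulation penalty")
    best_f, best_sh, best_ind = np.inf, None, None
    for f0, xsh, xind in explored[: settings.n_polish]:
        f, xs, xi = _search_from(
            ws, xsh, xind, settings.max_iter, settings.tolerance,
            grid=5, n_gn=10, ls_iters=20,
        )
        if f < best_f:
            best_f, best_sh, best_ind = f, xs, xi
    n_converged = sum(1 for f, _, _ in explored if f <= best_f + settings.tolerance)

    svals = ws.shared_values(best_sh)
    estimates: dict = {name: svals[name] for name in ws.shared}
    ind_nat = ws.ind_natural(best_ind)
    for name in ws.individual:
        estimates[name] = {did: float(v) for did, v in zip(ws.ids, ind_nat[name])}
    ev, mi = _simulate_fit(ws, svals, ind_nat)
    fits = [
        Trajectory(did, ws.panel[i].months, np.maximum(ev[:, i], 0.0), np.maximum(mi[:, i], 0.0))
        for i, did in enumerate(ws.ids)
    ]
    return CalibrationResult(
        estimates=estimates,
        objective=float(best_f),
        per_driver_fit=fits,
        n_converged=n_converged,
        n_starts=settings.n_starts,
        warnings=warn,
    )


def _simulate_fit(ws: _Workspace, svals: dict, ind_nat: dict):
    def get(name):
        if name in ind_nat:
            return ind_nat[name]
        return svals[name]

    ev, mi, _, _ = simulate_cohort_paths(
        svals["beta1"], svals["beta2"], svals["beta3"],
        svals["event_decay_time"], svals["risky_fraction"],
        get("driving_need"), get("initial_event_rate"),
        get("initial_recent_events"),
        float(ws.problem.config.initial_cumulative_miles),
        months=ws.m, steps_per_month=ws.spm,
    )
    if ev.ndim == 1:
        ev = ev[:, None]
        mi = mi[:, None]
    return ev, mi


def bootstrap_ci(
    problem: CalibrationProblem,
    settings: OptimizerSettings,
    n_boot: int,
    seed: int,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% intervals for shared parameters by driver resampling.

    Drivers are resampled with replacement ``n_boot`` times and each
    replicate panel recalibrated with ``settings``; failed replicates are
    dropped (more than half failing is an error).  Deterministic given
    ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    panel = sorted(problem.panel, key=lambda t: t.driver_id)
    d = len(panel)
    reps: list[dict] = []
    failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, d, size=d)
        boot = []
        for j, i in enumerate(sorted(idx)):
            t = panel[i]
            boot.append(Trajectory(f"b{j:03d}_{t.driver_id}", t.months, t.events, t.miles))
        try:
            res = calibrate(
                replace(problem, panel=tuple(boot)),
                replace(settings, seed=settings.seed + b + 1),
            )
            reps.append({k: res.estimates[k] for k in problem.shared_params})
        except CalibrationError:
            failed += 1
    if failed > n_boot / 2:
        raise CalibrationError(f"{failed}/{n_boot} bootstrap replicates failed")
    out = {}
    for name in problem.shared_params:
        vals = np.array([r[name] for r in reps])
        out[name] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return out
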