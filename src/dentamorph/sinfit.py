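"""Sinusoidal dentation model and its simulated-annealing fit.

The silhouette y(x) is modelled as ``y = A sin(w x + phi) + b`` with
amplitude A, angular frequency w (frequency f = w / 2pi in bumps per
mm), phase phi and bias b.  The fit minimizes the mean squared residual

    J(A, w, phi, b) = mean_x ( y(x) - [A sin(w x + phi) + b] )^2

which is multimodal in w, so a probabilistic global optimizer is used:
simulated annealing with geometric cooling, accepting a worse proposal
iff ``exp(-dD / T) > u`` with u uniform on [0, 1].  The best solution
across restarts is polished with a derivative-free Nelder-Mead step.

Derived morphometric measures: bump height H = 2A and bump width
L = 1 / f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import ParameterError
from .config import RunConfig
from .dentation import Silhouette2D

_TWO_PI = 2.0 * np.pi


@dataclass
class SASchedule:
    """Simulated-annealing schedule.

    Costs are normalized by the silhouette variance before annealing, so
    the initial temperature t0 is dimensionless.  Proposal steps are
    Gaussian, one randomly chosen parameter per move, with per-parameter
    scales multiplied by sqrt(T) so moves shrink as the system cools;
    frequency is proposed in log-space to explore octaves evenly.
    """

    t0: float = 1.0
    cooling: float = 0.95
    iters_per_temp: int = 50
    t_min: float = 1e-4
    restarts: int = 4
    proposal_scales: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.t0 > 0 or not self.t_min > 0:
            raise ParameterError("t0 and t_min must be positive")
        if not 0 < self.cooling < 1:
            raise ParameterError("cooling must lie in (0, 1)")
        if self.iters_per_temp < 1 or self.restarts < 1:
            raise ParameterError("iters_per_temp and restarts must be >= 1")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "SASchedule":
        return cls(t0=cfg.sa_t0, cooling=cfg.sa_cooling,
                   iters_per_temp=cfg.sa_iters_per_temp, t_min=cfg.sa_t_min,
                   restarts=cfg.sa_restarts, seed=cfg.seed)


@dataclass
class FitBounds:
    """Feasible box for the fit parameters.

    Amplitude and frequency bounds bracket physiological dentation with
    margin; the bias bound is derived from the silhouette's own y-range.
    """

    A: tuple = (0.0, 2.0)
    f: tuple = (0.02, 0.5)
    b: tuple | None = None  # defaults to silhouette y-range +- 2 mm

    def resolve_b(self, y: np.ndarray) -> tuple:
        if self.b is not None:
            return self.b
        return (float(y.min()) - 2.0, float(y.max()) + 2.0)

    def validate(self):
        for name in ("A", "f"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ParameterError(f"bounds for {name} are empty: ({lo}, {hi})")
        if self.A[0] < 0:
            raise ParameterError("amplitude lower bound must be >= 0")
        if self.f[0] <= 0:
            raise ParameterError("frequency lower bound must be positive")
        if self.b is not None and not self.b[0] < self.b[1]:
            raise ParameterError(f"bounds for b are empty: {self.b}")


@dataclass
class SinusoidFit:
    """Fitted sinusoid parameters with derived dentation measures."""

    A_mm: float
    w_rad_per_mm: float
    phi_rad: float
    b_mm: float
    cost_J: float
    n_samples: int
    seed: int
    converged: bool
    reason: str = ""

    @property
    def f_bpm(self) -> float:
        """Frequency in bumps per mm, f = w / 2pi."""
        return self.w_rad_per_mm / _TWO_PI

    @property
    def H_mm(self) -> float:
        """Dentation (bump) height, H = 2A."""
        return 2.0 * self.A_mm

    @property
    def L_mm(self) -> float:
        """Dentation (bump) width, L = 1 / f."""
        f = self.f_bpm
        if f == 0:
            raise ParameterError("bump width L = 1/f is undefined for f = 0")
        return 1.0 / f

    def predict(self, x) -> np.ndarray:
        return (self.A_mm * np.sin(self.w_rad_per_mm * np.asarray(x)
                                   + self.phi_rad) + self.b_mm)

    def to_dict(self) -> dict:
        return {"A_mm": self.A_mm, "w_rad_per_mm": self.w_rad_per_mm,
                "phi_rad": self.phi_rad, "b_mm": self.b_mm,
                "f_bpm": self.f_bpm, "H_mm": self.H_mm, "L_mm": self.L_mm,
                "cost_J": self.cost_J, "n_samples": self.n_samples,
                "seed": self.seed, "converged": self.converged,
                "reason": self.reason}


def sin_objective(params, sil: Silhouette2D) -> float:
    """Mean squared residual of the sinusoid model on a silhouette."""
    A, w, phi, b = params
    r = sil.y_mm - (A * np.sin(w * sil.x_mm + phi) + b)
    return float(np.mean(r * r))


def _canonical(A, w, phi, b):
    """Normalize to A >= 0, w >= 0, phi in [0, 2pi)."""
    if w < 0:
        w, phi = -w, np.pi - phi
    if A < 0:
        A, phi = -A, phi + np.pi
    return A, w, phi % _TWO_PI, b


def fit_sinusoid_sa(sil: Silhouette2D, bounds: FitBounds | None = None,
                    schedule: SASchedule | None = None) -> SinusoidFit:
    """Fit the sinusoid by simulated annealing plus a local polish.

    A flat silhouette (variance below 1e-10) short-circuits to A = 0
    with the frequency pinned at its lower bound, flagged ``reason='flat'``.
    """
    bounds = bounds or FitBounds()
    schedule = schedule or SASchedule()
    bounds.validate()
    x, y = sil.x_mm, sil.y_mm
    n = len(x)
    var_y = float(np.var(y))
    if var_y < 1e-10:
        return SinusoidFit(A_mm=0.0, w_rad_per_mm=_TWO_PI * bounds.f[0],
                           phi_rad=0.0, b_mm=float(np.mean(y)),
                           cost_J=float(np.mean((y - np.mean(y)) ** 2)),
                           n_samples=n, seed=schedule.seed, converged=True,
                           reason="flat")

    b_lo, b_hi = bounds.resolve_b(y)
    A_lo, A_hi = bounds.A
    lf_lo, lf_hi = np.log(bounds.f[0]), np.log(bounds.f[1])
    std_y = np.sqrt(var_y)
    scales = {"A": 0.8 * std_y, "logf": 0.25, "phi": 0.7, "b": 0.8 * std_y}
    if schedule.proposal_scales:
        scales.update(schedule.proposal_scales)

    def cost(p):
        # p = (A, logf, phi, b), cost normalized by silhouette variance
        A, lf, phi, b = p
        w = _TWO_PI * np.exp(lf)
        r = y - (A * np.sin(w * x + phi) + b)
        return float(np.mean(r * r)) / var_y

    best_p, best_c = None, np.inf
    for restart in range(schedule.restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence((schedule.seed, restart)))
        p = np.array([
            rng.uniform(A_lo, min(A_hi, A_lo + 4 * std_y)),
            rng.uniform(lf_lo, lf_hi),
            rng.uniform(0, _TWO_PI),
            rng.uniform(max(b_lo, np.mean(y) - 2 * std_y),
                        min(b_hi, np.mean(y) + 2 * std_y)),
        ])
        c = cost(p)
        if c < best_c:
            best_p, best_c = p.copy(), c
        T = schedule.t0
        names = ("A", "logf", "phi", "b")
        while T > schedule.t_min:
            for _ in range(schedule.iters_per_temp):
                k = rng.integers(4)
                q = p.copy()
                q[k] += rng.normal(0.0, scales[names[k]] * np.sqrt(T))
                if k == 0:
                    q[0] = np.clip(q[0], A_lo, A_hi)
                elif k == 1:
                    q[1] = np.clip(q[1], lf_lo, lf_hi)
                elif k == 2:
                    q[2] = q[2] % _TWO_PI
                else:
                    q[3] = np.clip(q[3], b_lo, b_hi)
                cq = cost(q)
                dD = cq - c
                # accept better moves always; worse moves iff exp(-dD/T) > u
                if dD <= 0 or np.exp(-dD / T) > rng.uniform():
                    p, c = q, cq
                    if c < best_c:
                        best_p, best_c = p.copy(), c
            T *= schedule.cooling

    # derivative-free local polish of the best-ever SA solution
    A0, lf0, phi0, b0 = best_p
    p0 = np.array([A0, _TWO_PI * np.exp(lf0), phi0, b0])
    res = minimize(lambda p: sin_objective(p, sil), p0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000,
                            "maxfev": 8000})
    cand = _canonical(*res.x)
    polished_cost = sin_objective(cand, sil)
    sa_cost = best_c * var_y
    in_bounds = (A_lo - 1e-9 <= cand[0] <= A_hi + 1e-9
                 and b_lo - 1e-9 <= cand[3] <= b_hi + 1e-9)
    if in_bounds and polished_cost <= sa_cost + 1e-15:
        A, w, phi, b = cand
        final_cost = polished_cost
        converged = bool(res.success)
        reason = "" if res.success else "polish did not converge"
    else:  # polish wandered off; keep the SA solution
        A, w, phi, b = _canonical(A0, _TWO_PI * np.exp(lf0), phi0, b0)
        final_cost = sa_cost
        converged = False
        reason = "polish rejected"
    f = w / _TWO_PI
    if not (bounds.f[0] - 1e-9 <= f <= bounds.f[1] + 1e-9):
        f = float(np.clip(f, bounds.f[0], bounds.f[1]))
        w = _TWO_PI * f
        final_cost = sin_objective((A, w, phi, b), sil)
        converged = False
        reason = "frequency clipped to bounds"
    return SinusoidFit(A_mm=float(A), w_rad_per_mm=float(w),
                       phi_rad=float(phi % _TWO_PI), b_mm=float(b),
                       cost_J=float(final_cost), n_samples=n,
                       seed=schedule.seed, converged=converged, reason=reason)


def derived_measures(fit: SinusoidFit) -> tuple[float, float]:
    """Bump height and width: (H, L) = (2A, 1/f)."""
    return fit.H_mm, fit.L_mm
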