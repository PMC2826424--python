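"""Diploid gene-regulatory ODE models with autoregulatory feedback.

Each allele i of a locus produces mRNA at rate ``alpha_i * R_i(u)`` and the
product decays at relative rate ``gamma_i``:

    dx_i/dt = alpha_i * R_i(u) - gamma_i * x_i,      u = sum_j w_j * x_j,

where the sum runs over the alleles present (two for biallelic genotypes, one
for hemizygotes) and the weights ``w_j`` model coding variation in the
regulator (w = 1 when the allele products are functionally identical).  The
dose-response function R maps the regulatory input to [0, 1]:

* ``hill_up``:    u^p / (u^p + theta^p)      (positive autoregulation)
* ``hill_down``:  theta^p / (u^p + theta^p)  (negative autoregulation)
* ``bump_up``:    exp(-(u - mu)^2 / (2 sigma^2))   (peak-shaped, max 1 at mu)
* ``bump_down``:  1 - bump_up                      (trough-shaped)
* a constant value in [0, 1] models constitutive expression (no feedback).

The stable equilibrium total concentration is taken as the genotypic value.
At equilibrium ``x_i = (alpha_i / gamma_i) R_i(u)``, so equilibria are the
roots of the scalar function

    g(u) = sum_i w_i (alpha_i / gamma_i) R_i(u) - u

on [0, sum_i w_i alpha_i / gamma_i].  ``find_equilibria`` enumerates these
roots exhaustively; ``steady_state`` returns the equilibrium reached from a
given initial condition.  When all degradation rates are equal the weighted
total u itself obeys the autonomous scalar flow du/dt = h(u) - gamma*u, so the
attractor reached from u0 is the nearest root of g in the flow direction and
is found by root bracketing (exactly equivalent to time integration).  With
unequal degradation rates the system is integrated numerically and the result
polished against the nearest root of g.

A two-locus feedback loop couples a polymorphic locus 1 to a nonpolymorphic
locus 2: locus-1 alleles respond to the locus-2 total and vice versa, with the
loop sign equal to the product of the two action signs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import brentq

from .metrics import PhenotypeQuintet

__all__ = [
    "ResponseSpec",
    "AlleleParams",
    "GenotypeSystem",
    "TwoLocusSystem",
    "Equilibrium",
    "SolverOptions",
    "ConvergenceError",
    "response",
    "find_equilibria",
    "steady_state",
    "genotype_quintet",
    "two_locus_quintets",
]

_HILL_KINDS = ("hill_up", "hill_down")
_BUMP_KINDS = ("bump_up", "bump_down")
RESPONSE_KINDS = _HILL_KINDS + _BUMP_KINDS


class ConvergenceError(RuntimeError):
    """The dynamics did not settle to a stable state within t_max."""


@dataclass(frozen=True)
class ResponseSpec:
    """Dose-response function specification; values always lie in [0, 1].

    ``constant_value``, when set, short-circuits the functional form and
    models constitutive control (no feedback).
    """

    kind: str
    theta: Optional[float] = None
    p: Optional[float] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    constant_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in RESPONSE_KINDS:
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.constant_value is not None:
            if not 0.0 <= self.constant_value <= 1.0:
                raise ValueError("constant_value must lie in [0, 1]")
            return
        if self.kind in _HILL_KINDS:
            if self.theta is None or self.theta <= 0:
                raise ValueError("hill response needs threshold theta > 0")
            if self.p is None or self.p < 1:
                raise ValueError("hill response needs steepness p >= 1")
        else:
            if self.mu is None or self.mu <= 0:
                raise ValueError("bump response needs peak location mu > 0")
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("bump response needs width sigma > 0")

    def __call__(self, u):
        return response(self, u)

    def derivative(self, u):
        """dR/du, with the same broadcasting as the response itself."""
        u_arr = np.asarray(u, dtype=float)
        if self.constant_value is not None:
            out = np.zeros_like(u_arr)
        elif self.kind in _HILL_KINDS:
            up = u_arr ** self.p
            tp = self.theta ** self.p
            denom = (up + tp) ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                unm1 = np.where(u_arr > 0, u_arr ** (self.p - 1.0), 0.0 if self.p > 1 else 1.0)
            out = self.p * tp * unm1 / denom
            if self.kind == "hill_down":
                out = -out
        else:
            z = (u_arr - self.mu) / self.sigma
            bump = np.exp(-0.5 * z * z)
            out = -z / self.sigma * bump
            if self.kind == "bump_down":
                out = -out
        return out if np.ndim(u) else float(out)


def response(spec: ResponseSpec, u):
    """Evaluate a dose-response function at input u >= 0 (scalar or array)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("regulatory input must be >= 0")
    if spec.constant_value is not None:
        out = np.full_like(u_arr, spec.constant_value)
    elif spec.kind in _HILL_KINDS:
        up = u_arr ** spec.p
        tp = spec.theta ** spec.p
        out = up / (up + tp)
        if spec.kind == "hill_down":
            out = 1.0 - out
    else:
        z = (u_arr - spec.mu) / spec.sigma
        out = np.exp(-0.5 * z * z)
        if spec.kind == "bump_down":
            out = 1.0 - out
    return out if np.ndim(u) else float(out)


@dataclass(frozen=True)
class AlleleParams:
    """Regulatory parameters of one allele.

    alpha: maximum transcription rate (> 0)
    gamma: relative degradation rate (> 0)
    response: dose-response specification
    w: coding-variation weight on the regulatory input (1 = no coding variation)
    """

    alpha: float
    gamma: float
    response: ResponseSpec
    w: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "w"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class GenotypeSystem:
    """A 1-allele (hemizygote) or 2-allele ODE system for a single locus."""

    alleles: tuple[AlleleParams, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2):
            raise ValueError("a genotype system has 1 or 2 alleles")

    # -- parameter arrays ---------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        return np.array([a.w for a in self.alleles])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a.alpha for a in self.alleles])

    @property
    def gammas(self) -> np.ndarray:
        return np.array([a.gamma for a in self.alleles])

    # -- dynamics -----------------------------------------------------------
    def u_of(self, state: Sequence[float]) -> float:
        """Weighted regulatory input u = sum_i w_i x_i."""
        return float(np.dot(self.weights, np.asarray(state, dtype=float)))

    def rhs(self, state: Sequence[float]) -> np.ndarray:
        """Time derivatives dx_i/dt at the given per-allele state."""
        state = np.asarray(state, dtype=float)
        if state.shape != (len(self.alleles),):
            raise ValueError(
                f"state must have {len(self.alleles)} components, got shape {state.shape}"
            )
        if np.any(state < 0):
            raise ValueError("state must be componentwise >= 0")
        u = self.u_of(state)
        resp = np.array([a.response(u) for a in self.alleles])
        return self.alphas * resp - self.gammas * state

    def jacobian(self, state: Sequence[float]) -> np.ndarray:
        u = self.u_of(state)
        dresp = np.array([a.response.derivative(u) for a in self.alleles])
        return np.diag(-self.gammas) + np.outer(self.alphas * dresp, self.weights)

    # -- equilibrium structure ----------------------------------------------
    def u_cap(self) -> float:
        """Upper bound on the equilibrium regulatory input."""
        return float(np.sum(self.weights * self.alphas / self.gammas))

    def g(self, u):
        """Scalar fixed-point function g(u) = sum_i w_i (a_i/g_i) R_i(u) - u."""
        u_arr = np.asarray(u, dtype=float)
        acc = np.zeros_like(u_arr)
        for a in self.alleles:
            acc = acc + a.w * (a.alpha / a.gamma) * response(a.response, u_arr)
        out = acc - u_arr
        return out if np.ndim(u) else float(out)

    def state_at(self, u_star: float) -> np.ndarray:
        """Per-allele equilibrium state implied by the regulatory input u*."""
        return np.array([(a.alpha / a.gamma) * response(a.response, u_star) for a in self.alleles])


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of a genotype system.

    state: per-allele concentrations; total: phenotype (sum of products);
    stable: all Jacobian eigenvalues have real part below -1e-9;
    u_star: the equilibrium regulatory input.
    """

    state: tuple[float, ...]
    total: float
    stable: bool
    u_star: float


@dataclass(frozen=True)
class SolverOptions:
    """Numerical options for steady-state computation.

    eps: relative rate criterion ||dx/dt|| < eps * (1 + ||x||) for convergence
    t_max: give up (ConvergenceError) if not converged by this time
    t_chunk: initial integration chunk length (doubled per retry)
    stability_tol: eigenvalue real-part threshold for calling a point stable
    init_scale: scale of random initial conditions.  One uniform unit draw is
        made per gene-copy slot of a replicate and shared by all five genotype
        systems; each system places coordinate i at ``unit_i * alpha_i /
        gamma_i`` (its invariant box) when init_scale is None, or at
        ``unit_i * init_scale / gamma_i`` when a number is given.
    n_grid: grid resolution of the exhaustive root scan
    """

    eps: float = 1e-9
    t_max: float = 1e4
    t_chunk: float = 100.0
    stability_tol: float = -1e-9
    init_scale: Optional[float] = None
    n_grid: int = 4096


DEFAULT_SOLVER = SolverOptions()


def _scan_roots(fun, lo: float, hi: float, n_grid: int) -> list[float]:
    """All roots of a scalar function on [lo, hi] via grid scan + brentq.

    The grid mixes geometric spacing (resolves structure near lo) with linear
    spacing.  Tangential double roots inside one grid cell can be missed; the
    resolution is chosen so this is negligible for the response shapes used.
    """
    span = hi - lo
    if span <= 0:
        return []
    n_geom = max(n_grid // 4, 8)
    grid = np.unique(
        np.concatenate(
            [
                [lo],
                lo + span * np.geomspace(1e-12, 1.0, n_geom),
                np.linspace(lo, hi, n_grid - n_geom),
            ]
        )
    )
    vals = fun(grid)
    roots: list[float] = []
    tol0 = 1e-12 * (1.0 + abs(hi))
    if abs(vals[0]) <= tol0:
        roots.append(grid[0])
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0 and i > 0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(fun, grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe near-coincident roots
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-9 * (1.0 + abs(r)):
            dedup.append(r)
    return dedup


def _equilibrium_at(sys: GenotypeSystem, u_star: float, opts: SolverOptions) -> Equilibrium:
    state = sys.state_at(u_star)
    eig = np.linalg.eigvals(sys.jacobian(state))
    stable = bool(np.max(eig.real) < opts.stability_tol)
    return Equilibrium(
        state=tuple(float(x) for x in state),
        total=float(np.sum(state)),
        stable=stable,
        u_star=float(u_star),
    )


def find_equilibria(sys: GenotypeSystem, opts: SolverOptions = DEFAULT_SOLVER) -> list[Equilibrium]:
    """All equilibria of a genotype system, sorted by u*.

    Roots of the scalar reduction g(u) = 0 are scanned exhaustively on
    [0, u_cap]; each is expanded to the per-allele state and classified by the
    Jacobian eigenvalues of the full system.
    """
    cap = sys.u_cap()
    roots = _scan_roots(sys.g, 0.0, cap * (1.0 + 1e-12) + 1e-12, opts.n_grid)
    return [_equilibrium_at(sys, r, opts) for r in roots]


def _flow_attractor(sys: GenotypeSystem, u0: float, opts: SolverOptions) -> float:
    """Attractor of the scalar flow du/dt ~ g(u) reached from u0.

    Valid when all degradation rates are equal: u then obeys an autonomous
    scalar ODE whose sign agrees with g, so the trajectory moves monotonically
    to the nearest root of g in the direction of sign(g(u0)).
    """
    g0 = sys.g(u0)
    if g0 == 0.0:
        return u0
    cap = sys.u_cap()
    if g0 > 0:
        lo, hi = u0, cap + 1.0  # g(hi) < 0 since h(u) <= cap*gamma_scale
        t = np.concatenate([np.geomspace(1e-9, 0.1, 96), np.linspace(0.1, 1.0, 160)])
        grid = lo + (hi - lo) * t
        vals = sys.g(grid)
        idx = np.flatnonzero(vals <= 0)
        if idx.size == 0:  # numerically impossible; fall back to cap
            return cap
        j = idx[0]
        a = lo if j == 0 else grid[j - 1]
        b = grid[j]
        if vals[j] == 0.0:
            return float(b)
    else:
        lo, hi = 0.0, u0
        t = np.concatenate([np.geomspace(1e-9, 0.1, 96), np.linspace(0.1, 1.0, 160)])
        grid = u0 - u0 * t  # decreasing from just below u0 to 0
        vals = sys.g(grid)
        idx = np.flatnonzero(vals >= 0)
        if idx.size == 0:
            # g < 0 on (0, u0): the flow descends to the boundary equilibrium 0
            return 0.0
        j = idx[0]
        a = u0 if j == 0 else grid[j - 1]
        b = grid[j]
        if vals[j] == 0.0:
            return float(b)
    return brentq(sys.g, min(a, b), max(a, b), xtol=1e-13, rtol=8.9e-16)


def _integrate_to_rest(
    sys: GenotypeSystem, init: np.ndarray, opts: SolverOptions
) -> np.ndarray:
    """Integrate the full per-allele system until the relative rate criterion."""

    def rhs_t(x, _t):
        x = np.maximum(x, 0.0)
        u = float(np.dot(sys.weights, x))
        resp = np.array([a.response(u) for a in sys.alleles])
        return sys.alphas * resp - sys.gammas * x

    x = np.asarray(init, dtype=float)
    t_done = 0.0
    chunk = opts.t_chunk
    while t_done < opts.t_max:
        chunk = min(chunk, opts.t_max - t_done)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = odeint(rhs_t, x, [0.0, chunk], rtol=1e-10, atol=1e-12, mxstep=10000)
        x = np.maximum(traj[-1], 0.0)
        t_done += chunk
        rate = rhs_t(x, 0.0)
        if np.linalg.norm(rate) < opts.eps * (1.0 + np.linalg.norm(x)):
            return x
        chunk *= 2.0
    raise ConvergenceError(f"no stable state reached by t = {opts.t_max}")


def steady_state(
    sys: GenotypeSystem,
    init: Sequence[float],
    opts: SolverOptions = DEFAULT_SOLVER,
) -> Equilibrium:
    """Equilibrium reached from ``init``, polished against the roots of g.

    With equal degradation rates the weighted total follows an autonomous
    scalar flow and the attractor is found exactly by root bracketing; with
    unequal rates the system is integrated numerically (raising
    ``ConvergenceError`` on sustained oscillation or slow transients past
    t_max) and the end state snapped to the nearest root of g.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (len(sys.alleles),):
        raise ValueError("init has wrong dimension")
    if np.any(init < 0):
        raise ValueError("init must be componentwise >= 0")
    gammas = sys.gammas
    if np.ptp(gammas) == 0.0:
        u_star = _flow_attractor(sys, sys.u_of(init), opts)
        return _equilibrium_at(sys, u_star, opts)
    x_end = _integrate_to_rest(sys, init, opts)
    u_end = sys.u_of(x_end)
    roots = _scan_roots(sys.g, 0.0, sys.u_cap() + 1e-12, opts.n_grid)
    if not roots:
        raise ConvergenceError("no fixed point found for converged trajectory")
    u_star = min(roots, key=lambda r: abs(r - u_end))
    if abs(u_star - u_end) > 0.05 * (1.0 + abs(u_star)):
        raise ConvergenceError("trajectory settled far from any fixed point")
    return _equilibrium_at(sys, u_star, opts)


def _init_for(
    alleles: tuple[AlleleParams, ...], units: np.ndarray, opts: SolverOptions
) -> np.ndarray:
    if opts.init_scale is None:
        scales = np.array([a.alpha / a.gamma for a in alleles])
    else:
        scales = np.array([opts.init_scale / a.gamma for a in alleles])
    return units[: len(alleles)] * scales


def genotype_quintet(
    allele1: AlleleParams,
    allele2: AlleleParams,
    opts: SolverOptions = DEFAULT_SOLVER,
    rng=None,
) -> PhenotypeQuintet:
    """Phenotype quintet of a single autoregulated locus.

    Builds the five genotype systems (homozygote 11, heterozygote 12,
    homozygote 22, hemizygote 1, hemizygote 2) and solves each by following
    the dynamics from a random initial condition.  One random condition is
    drawn per call (one uniform unit draw per gene-copy slot, scaled to each
    system's invariant region, see :class:`SolverOptions`), so basin choices
    are consistent across the five genotype systems of a parameter set.
    Raises ``ConvergenceError`` if any member fails to converge.
    """
    if rng is None:
        rng = np.random.default_rng()
    units = rng.uniform(0.0, 1.0, size=2)
    totals = []
    for alleles, slots in (
        ((allele1, allele1), (0, 1)),
        ((allele1, allele2), (0, 1)),
        ((allele2, allele2), (0, 1)),
        ((allele1,), (0,)),
        ((allele2,), (1,)),
    ):
        sys = GenotypeSystem(alleles)
        eq = steady_state(sys, _init_for(alleles, units[list(slots)], opts), opts)
        totals.append(eq.total)
    x11, x12, x22, h1, h2 = totals
    return PhenotypeQuintet(x11, x12, x22, h1, h2)


# ---------------------------------------------------------------------------
# two-element feedback loops
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoLocusSystem:
    """Mutual regulation between a polymorphic locus 1 and a uniform locus 2.

    Locus-1 alleles (1 for locus-1 hemizygotes, else 2) are transcribed at
    ``alpha_i * R_i(y_total)``; the two identical locus-2 alleles at
    ``beta * S(x_total)``.  The action signs are encoded by the response kinds
    (hill_up = activation, hill_down = inhibition); the loop sign is their
    product.
    """

    locus1_alleles: tuple[AlleleParams, ...]
    locus2_allele: AlleleParams

    def __post_init__(self) -> None:
        if len(self.locus1_alleles) not in (1, 2):
            raise ValueError("locus 1 carries 1 or 2 alleles")

    @property
    def action_signs(self) -> tuple[int, int]:
        """(sign of locus2 -> locus1, sign of locus1 -> locus2)."""
        s1 = 1 if self.locus1_alleles[0].response.kind == "hill_up" else -1
        s2 = 1 if self.locus2_allele.response.kind == "hill_up" else -1
        return (s1, s2)

    @property
    def loop_sign(self) -> int:
        s1, s2 = self.action_signs
        return s1 * s2

    def rhs(self, state: np.ndarray) -> np.ndarray:
        n1 = len(self.locus1_alleles)
        x, y = state[:n1], state[n1:]
        ytot = float(np.sum(y))
        xtot = float(np.sum(x))
        dx = np.array(
            [a.alpha * a.response(ytot) - a.gamma * xi for a, xi in zip(self.locus1_alleles, x)]
        )
        l2 = self.locus2_allele
        dy = l2.alpha * l2.response(xtot) - l2.gamma * y
        return np.concatenate([dx, dy])

    def y_fixed_point_fun(self, y):
        """Scalar reduction in the locus-2 total: y - 2 (beta/kappa) S(X(y))."""
        y_arr = np.asarray(y, dtype=float)
        xtot = np.zeros_like(y_arr)
        for a in self.locus1_alleles:
            xtot = xtot + (a.alpha / a.gamma) * response(a.response, y_arr)
        l2 = self.locus2_allele
        out = 2.0 * (l2.alpha / l2.gamma) * response(l2.response, xtot) - y_arr
        return out if np.ndim(y) else float(out)

    def x_total_at(self, ytot: float) -> float:
        return float(sum((a.alpha / a.gamma) * a.response(ytot) for a in self.locus1_alleles))


def _two_locus_steady(
    sys: TwoLocusSystem, init: np.ndarray, opts: SolverOptions
) -> tuple[float, float]:
    """(x_total, y_total) at the equilibrium reached from init."""

    def rhs_t(s, _t):
        return sys.rhs(np.maximum(s, 0.0))

    s = np.asarray(init, dtype=float)
    t_done = 0.0
    chunk = opts.t_chunk
    while t_done < opts.t_max:
        chunk = min(chunk, opts.t_max - t_done)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = odeint(rhs_t, s, [0.0, chunk], rtol=1e-10, atol=1e-12, mxstep=10000)
        s = np.maximum(traj[-1], 0.0)
        t_done += chunk
        rate = rhs_t(s, 0.0)
        if np.linalg.norm(rate) < opts.eps * (1.0 + np.linalg.norm(s)):
            break
        chunk *= 2.0
    else:
        raise ConvergenceError(f"two-locus system not converged by t = {opts.t_max}")
    n1 = len(sys.locus1_alleles)
    ytot_end = float(np.sum(s[n1:]))
    l2 = sys.locus2_allele
    y_cap = 2.0 * l2.alpha / l2.gamma + 1e-12
    roots = _scan_roots(sys.y_fixed_point_fun, 0.0, y_cap, opts.n_grid)
    if not roots:
        raise ConvergenceError("no two-locus fixed point found")
    y_star = min(roots, key=lambda r: abs(r - ytot_end))
    if abs(y_star - ytot_end) > 0.05 * (1.0 + abs(y_star)):
        raise ConvergenceError("two-locus trajectory settled far from any fixed point")
    return sys.x_total_at(y_star), y_star


def two_locus_quintets(
    allele1a: AlleleParams,
    allele1b: AlleleParams,
    locus2_allele: AlleleParams,
    opts: SolverOptions = DEFAULT_SOLVER,
    rng=None,
) -> tuple[PhenotypeQuintet, PhenotypeQuintet]:
    """Phenotype quintets assayed at both loci of a two-element loop.

    Genetic variation sits only in the locus-1 alleles; hemizygotes knock out
    one locus-1 allele while locus 2 stays biallelic.  Returns the quintets at
    locus 1 and at locus 2, indexed by the five locus-1 genotype
    configurations.  The locus-1 quintet holds equilibrium totals.  For the
    locus-2 quintet the hemizygote entries are per-gene-copy values (half the
    locus-2 total in each hemizygous background): locus 2 contributes two
    identical copies in every configuration, and with this reference the
    locus-2 interaction values vanish exactly when the loop is inactive.
    """
    if rng is None:
        rng = np.random.default_rng()
    units = rng.uniform(0.0, 1.0, size=4)  # two locus-1 slots, two locus-2 slots
    totals1, totals2 = [], []
    for l1, slots in (
        ((allele1a, allele1a), (0, 1)),
        ((allele1a, allele1b), (0, 1)),
        ((allele1b, allele1b), (0, 1)),
        ((allele1a,), (0,)),
        ((allele1b,), (1,)),
    ):
        sys = TwoLocusSystem(l1, locus2_allele)
        l2 = locus2_allele
        if opts.init_scale is None:
            scales = np.array([a.alpha / a.gamma for a in l1] + [l2.alpha / l2.gamma] * 2)
        else:
            scales = np.array(
                [opts.init_scale / a.gamma for a in l1] + [opts.init_scale / l2.gamma] * 2
            )
        init = np.concatenate([units[list(slots)], units[2:]]) * scales
        xtot, ytot = _two_locus_steady(sys, init, opts)
        totals1.append(xtot)
        totals2.append(ytot)
    q1 = PhenotypeQuintet(totals1[0], totals1[1], totals1[2], totals1[3], totals1[4])
    q2 = PhenotypeQuintet(totals2[0], totals2[1], totals2[2], 0.5 * totals2[3], 0.5 * totals2[4])
    return q1, q2
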