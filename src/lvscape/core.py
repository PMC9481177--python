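"""Cooperative Lotka-Volterra systems and their stationary-point landscape.

The dynamical model is

    du_i/dt = u_i * (alpha_i - u_i + g * sum_j gamma_ij u_j),

a cooperative system: every off-diagonal interaction weight ``gamma_ij`` is
nonnegative, so each component can only help the others grow.  Under the
coupling bound ``g * rho(gamma) < 1`` (``rho`` the spectral radius) every
principal submatrix of ``I - g*gamma`` is an invertible M-matrix, each
candidate support yields at most one nonnegative equilibrium, and the system
has a unique globally asymptotically stable solution (GASS) whose support is
the union of the supports of all feasible equilibria.

Supports are represented internally as bit masks (bit ``i`` set means
component ``i`` is strictly positive) which keeps exhaustive enumeration over
all ``2**n`` candidate supports cheap for small ``n``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: eigenvalue real parts in (-TOL_EIG, TOL_EIG) are treated as marginal
TOL_EIG = 1e-9
#: equilibrium components below this are not counted as positive
TOL_FEAS = 1e-12


class NonCooperativeError(ValueError):
    """Raised when an interaction matrix has a negative off-diagonal entry."""


class AttractorConditionError(ValueError):
    """Raised when ``g * rho(gamma) >= 1`` and the attractor theory no longer applies."""


class GassError(RuntimeError):
    """Raised when the union-of-supports point is infeasible or unstable."""


class MarginalStabilityWarning(UserWarning):
    """Emitted when an eigenvalue real part sits inside the stability tolerance band."""


def spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(m))))


@dataclass(frozen=True)
class LVSystem:
    """A cooperative Lotka-Volterra system.

    Parameters
    ----------
    alpha
        Intrinsic growth parameters, shape ``(n,)``.
    gamma
        Interaction weights, shape ``(n, n)``, zero diagonal, nonnegative
        off-diagonal entries.
    g
        Global coupling that scales ``gamma``; default 0.27.
    """

    alpha: np.ndarray
    gamma: np.ndarray
    g: float = 0.27

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float).ravel())
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        if self.gamma.shape != (self.n, self.n):
            raise ValueError(
                f"gamma must be ({self.n}, {self.n}), got {self.gamma.shape}"
            )

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    def rhs(self, u: np.ndarray) -> np.ndarray:
        """Right-hand side of the ODE at state ``u``."""
        u = np.asarray(u, dtype=float)
        return u * (self.alpha - u + self.g * (self.gamma @ u))

    def jacobian(self, u: np.ndarray) -> np.ndarray:
        """Jacobian of the right-hand side at state ``u``."""
        u = np.asarray(u, dtype=float)
        coupling = self.g * self.gamma
        jac = u[:, None] * coupling
        np.fill_diagonal(jac, self.alpha - 2.0 * u + coupling @ u)
        return jac


@dataclass
class StationaryPoint:
    """A nonnegative equilibrium of an :class:`LVSystem`.

    ``support`` is the set of component indices strictly positive at the
    equilibrium; ``level`` is the support size, which orders the landscape
    into energy levels (the origin sits at level 0).
    """

    support: frozenset
    u_star: np.ndarray
    level: int
    stable: bool | None = None
    is_gass: bool = False
    eig_real: np.ndarray | None = None

    @property
    def mask(self) -> int:
        return mask_of(self.support)


def mask_of(support) -> int:
    m = 0
    for i in support:
        m |= 1 << int(i)
    return m


def support_of(mask: int) -> frozenset:
    return frozenset(i for i in range(mask.bit_length()) if mask >> i & 1)


def validate_system(system: LVSystem) -> LVSystem:
    """Check cooperativity and the attractor-existence coupling bound.

    Returns the system unchanged if ``gamma`` has a zero diagonal, no
    negative off-diagonal entries, and ``g * rho(gamma) < 1``.
    """
    if not np.all(np.isfinite(system.alpha)) or not np.all(np.isfinite(system.gamma)):
        raise ValueError("non-finite system parameters")
    if np.any(np.abs(np.diag(system.gamma)) > 0):
        raise NonCooperativeError("gamma must have a zero diagonal")
    off = system.gamma - np.diag(np.diag(system.gamma))
    if np.any(off < 0):
        raise NonCooperativeError("non-cooperative system: negative interaction weight")
    if system.g < 0:
        raise ValueError("coupling g must be nonnegative")
    if system.g * spectral_radius(system.gamma) >= 1.0:
        raise AttractorConditionError(
            "attractor existence condition violated: g * spectral_radius(gamma) >= 1"
        )
    return system


def simulate_forward(
    system: LVSystem, u0: np.ndarray, h: float, steps: int
) -> np.ndarray:
    """Explicit-Euler trajectory of ``steps`` transitions from ``u0``.

    Returns a ``(steps + 1, n)`` array whose first row is ``u0``.  The same
    discretisation is inverted by :func:`lvscape.transform.lvt_transform`, so
    the pair forms an exact round trip in the noiseless case.
    """
    u0 = np.asarray(u0, dtype=float).ravel()
    if u0.shape[0] != system.n:
        raise ValueError("u0 has wrong length")
    if np.any(u0 <= 0):
        raise ValueError("u0 must be strictly positive")
    if h <= 0:
        raise ValueError("step size h must be positive")
    out = np.empty((steps + 1, system.n))
    out[0] = u0
    u = u0.copy()
    for t in range(steps):
        u = u + h * system.rhs(u)
        if np.any(u < 0):
            raise ValueError("step size too large: trajectory left the positive orthant")
        out[t + 1] = u
    return out


class SupportSolver:
    """Precomputed inverses of all principal submatrices of ``I - g*gamma``.

    The submatrices depend only on the interaction structure, not on
    ``alpha``, so one solver can be reused across every timepoint of a
    trajectory that shares a connectivity matrix.
    """

    def __init__(self, gamma: np.ndarray, g: float):
        gamma = np.asarray(gamma, dtype=float)
        self.n = gamma.shape[0]
        self.gamma = gamma
        self.g = g
        a_full = np.eye(self.n) - g * gamma
        self._idx: list[np.ndarray] = []
        self._inv: list[np.ndarray | None] = []
        for mask in range(1 << self.n):
            idx = np.flatnonzero([(mask >> i) & 1 for i in range(self.n)])
            self._idx.append(idx)
            if idx.size == 0:
                self._inv.append(None)
            else:
                self._inv.append(np.linalg.inv(a_full[np.ix_(idx, idx)]))

    def indices(self, mask: int) -> np.ndarray:
        return self._idx[mask]

    def inverse(self, mask: int) -> np.ndarray:
        return self._inv[mask]

    def solve(self, mask: int, alpha: np.ndarray) -> np.ndarray | None:
        """Equilibrium restricted to the support ``mask``; ``None`` if infeasible."""
        idx = self._idx[mask]
        if idx.size == 0:
            return np.zeros(0)
        u_s = self._inv[mask] @ alpha[idx]
        if np.all(u_s > TOL_FEAS):
            return u_s
        return None

    def feasible(self, alpha: np.ndarray) -> dict[int, np.ndarray]:
        """All feasible support masks with their restricted equilibria."""
        out: dict[int, np.ndarray] = {0: np.zeros(0)}
        for mask in range(1, 1 << self.n):
            u_s = self.solve(mask, alpha)
            if u_s is not None:
                out[mask] = u_s
        return out


_solver_cache: dict[tuple, SupportSolver] = {}


def get_solver(system: LVSystem) -> SupportSolver:
    """Memoised :class:`SupportSolver` for the system's interaction structure."""
    key = (system.gamma.tobytes(), system.gamma.shape[0], float(system.g))
    solver = _solver_cache.get(key)
    if solver is None:
        if len(_solver_cache) > 32:
            _solver_cache.clear()
        solver = SupportSolver(system.gamma, system.g)
        _solver_cache[key] = solver
    return solver


def _point_from_mask(
    system: LVSystem, mask: int, u_s: np.ndarray, solver: SupportSolver
) -> StationaryPoint:
    u = np.zeros(system.n)
    idx = solver.indices(mask)
    u[idx] = u_s
    return StationaryPoint(
        support=support_of(mask), u_star=u, level=int(idx.size)
    )


def stationary_point_for_support(system: LVSystem, support) -> StationaryPoint | None:
    """Solve ``(I - g*gamma)[S, S] u_S = alpha_S`` for one candidate support.

    Returns the equilibrium if every component of ``u_S`` is strictly
    positive, otherwise ``None`` (infeasible support).
    """
    validate_system(system)
    solver = get_solver(system)
    mask = mask_of(support)
    u_s = solver.solve(mask, system.alpha)
    if mask != 0 and u_s is None:
        return None
    return _point_from_mask(system, mask, u_s if u_s is not None else np.zeros(0), solver)


def classify_stability(
    system: LVSystem, point: StationaryPoint
) -> tuple[bool, np.ndarray]:
    """Linear stability from the Jacobian spectrum at the equilibrium.

    Returns ``(stable, eigenvalue real parts)``; stable means every real
    part is below ``-TOL_EIG``.  Real parts inside the tolerance band emit a
    :class:`MarginalStabilityWarning`.
    """
    eig = np.linalg.eigvals(system.jacobian(point.u_star))
    re = np.sort(eig.real)[::-1]
    if np.any(np.abs(re) < TOL_EIG):
        warnings.warn(
            "marginal eigenvalue at stationary point; stability call is degenerate",
            MarginalStabilityWarning,
            stacklevel=2,
        )
    stable = bool(np.all(re < -TOL_EIG))
    point.stable = stable
    point.eig_real = re
    return stable, re


def enumerate_stationary_points(
    system: LVSystem, stability: bool = True
) -> list[StationaryPoint]:
    """All feasible equilibria over the ``2**n`` candidate supports.

    The list is sorted by (level, lexicographic support); the origin is
    always present.  With ``stability=True`` each point carries its Jacobian
    verdict.
    """
    validate_system(system)
    solver = get_solver(system)
    feas = solver.feasible(system.alpha)
    points = [
        _point_from_mask(system, mask, u_s, solver) for mask, u_s in feas.items()
    ]
    points.sort(key=lambda p: (p.level, tuple(sorted(p.support))))
    if stability:
        for p in points:
            classify_stability(system, p)
    return points


def find_gass(
    system: LVSystem, points: list[StationaryPoint] | None = None
) -> StationaryPoint:
    """The globally asymptotically stable solution.

    In a cooperative system its support is the union of all feasible
    supports; the matching enumerated point must exist and be linearly
    stable, otherwise the coupling-bound invariant has been violated.
    """
    if points is None:
        points = enumerate_stationary_points(system, stability=False)
    union = 0
    for p in points:
        union |= p.mask
    for p in points:
        if p.mask == union:
            stable, _ = classify_stability(system, p)
            if not stable:
                raise GassError("GASS identification failed: union-support point unstable")
            p.is_gass = True
            return p
    raise GassError("GASS identification failed: union support infeasible")


def invasion_rate(system: LVSystem, point: StationaryPoint, k: int) -> float:
    """Per-capita growth rate of an absent component at an equilibrium.

    For ``k`` outside the support this is ``alpha_k + g * sum_j gamma_kj
    u*_j``; a positive rate means component ``k`` can invade, so the support
    extended by ``k`` admits a feasible equilibrium.
    """
    if k in point.support:
        raise ValueError(f"component {k} is present at this stationary point")
    return float(
        system.alpha[k] + system.g * (system.gamma[k] @ point.u_star)
    )
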