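"""Information Structures and their topology measures.

The Information Structure (IS) of a cooperative Lotka-Volterra system is the
graph of all its nonnegative stationary points: the skeleton of the global
attractor.  Points are stratified into energy levels by support size, with
the origin at level 0 and the globally asymptotically stable solution (GASS)
at the top.  Scalar measures summarise its shape:

* **NoEL** — number of energy levels, ``|GASS support| + 1``.
* **Frondosity** — fraction of the ``2**(NoEL-1)`` possible nodes that are
  actually present.
* **Cooperation** — nodes where a component that cannot persist alone is
  carried by others; counted in three ways (values A, B, C) plus the highest
  level at which cooperation occurs.
* **Criticality** — the smallest perturbation of a single ``alpha_i`` that
  changes the GASS support, i.e. the distance to the nearest bifurcation
  that reshapes the attractor.

Edges of the IS are presentational: they are the covering pairs of the
support-inclusion order, standing in for the heteroclinic connections that
the measures themselves never use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .core import (
    LVSystem,
    StationaryPoint,
    SupportSolver,
    classify_stability,
    enumerate_stationary_points,
    find_gass,
    get_solver,
    support_of,
    validate_system,
)

_DERIV_TOL = 1e-12


@dataclass
class InformationStructure:
    """The full attractor graph of one system snapshot."""

    points: list[StationaryPoint]
    edges: list[tuple[int, int]]
    gass_index: int

    @property
    def gass(self) -> StationaryPoint:
        return self.points[self.gass_index]

    @property
    def noel(self) -> int:
        return len(self.gass.support) + 1

    def to_dict(self) -> dict:
        """JSON-ready document: points (support, values, level, stability) + edges."""
        return {
            "points": [
                {
                    "support": sorted(p.support),
                    "u_star": [float(x) for x in p.u_star],
                    "level": p.level,
                    "stable": p.stable,
                    "is_gass": p.is_gass,
                }
                for p in self.points
            ],
            "edges": [list(e) for e in self.edges],
            "gass_index": self.gass_index,
            "noel": self.noel,
        }


@dataclass
class ISMeasures:
    """Scalar topology measures of one Information Structure."""

    noel: int
    frondosity: float
    criticality: float
    coop_highest_level: int
    coop_A: float
    coop_B: float
    coop_C: float

    def as_dict(self) -> dict:
        return asdict(self)


def _covering_edges(masks: list[int]) -> list[tuple[int, int]]:
    """Covering pairs of the support-inclusion order among existing points."""
    mask_set = set(masks)
    edges = []
    for a_i, a in enumerate(masks):
        for b_i, b in enumerate(masks):
            if a == b or (a & b) != a:
                continue
            # a strictly below b: covering iff nothing sits strictly between
            covering = True
            for c in mask_set:
                if c != a and c != b and (a & c) == a and (c & b) == c:
                    covering = False
                    break
            if covering:
                edges.append((a_i, b_i))
    return edges


def build_is(system: LVSystem, stability: bool = True) -> InformationStructure:
    """Enumerate the stationary points, identify the GASS, attach edges."""
    points = enumerate_stationary_points(system, stability=stability)
    gass = find_gass(system, points)
    gass_index = next(i for i, p in enumerate(points) if p.is_gass)
    edges = _covering_edges([p.mask for p in points])
    return InformationStructure(points=points, edges=edges, gass_index=gass_index)


def noel(is_: InformationStructure) -> int:
    """Number of energy levels: ``|GASS support| + 1``."""
    return is_.noel


def frondosity(is_: InformationStructure) -> float:
    """Node count relative to the ``2**(NoEL-1)`` maximum for this NoEL."""
    return _frondosity(len(is_.points), is_.noel)


def _frondosity(n_points: int, noel_value: int) -> float:
    return n_points / float(2 ** (noel_value - 1))


def cooperation_nodes(is_: InformationStructure) -> list[tuple[int, int]]:
    """Pairs ``(component, point index)`` where cooperation happens.

    A component cooperates when it belongs to the GASS but never appears
    alone at level 1; its cooperation nodes are the inclusion-minimal points
    that contain it.  One component may map to several nodes.
    """
    masks = [p.mask for p in is_.points]
    return [
        (k, masks.index(m))
        for k, m in _cooperation_pairs(masks, is_.gass.mask)
    ]


def _cooperation_pairs(masks: list[int], gass_mask: int) -> list[tuple[int, int]]:
    level1 = {m.bit_length() - 1 for m in masks if m.bit_count() == 1}
    pairs: list[tuple[int, int]] = []
    for k in support_of(gass_mask):
        if k in level1:
            continue
        bit = 1 << k
        containers = [m for m in masks if m & bit]
        minimal = [
            m
            for m in containers
            if not any(c != m and (c & m) == c for c in containers)
        ]
        pairs.extend((k, m) for m in sorted(minimal))
    return pairs


def cooperation_values(
    is_: InformationStructure,
) -> tuple[int, float, float, float]:
    """``(highest level, value A, value B, value C)`` from the cooperation nodes.

    A credits every cooperation node with the level of the companion
    sub-node it proceeds from (node level minus one); B credits each
    cooperating component only at the lowest level where it first appears;
    C does the same but weights first appearances at level ``l`` by
    ``2**(l-1)``, emphasising components that need more partners.
    """
    masks = [p.mask for p in is_.points]
    return _cooperation_values(masks, is_.gass.mask)


def _cooperation_values(
    masks: list[int], gass_mask: int
) -> tuple[int, float, float, float]:
    pairs = _cooperation_pairs(masks, gass_mask)
    if not pairs:
        return 0, 0.0, 0.0, 0.0
    levels = [m.bit_count() for _, m in pairs]
    highest = max(levels)
    coop_a = float(sum(lv - 1 for lv in levels))
    first_level: dict[int, int] = {}
    for (k, _), lv in zip(pairs, levels):
        first_level[k] = min(first_level.get(k, lv), lv)
    coop_b = float(sum(lv - 1 for lv in first_level.values()))
    coop_c = float(sum(2 ** (lv - 1) for lv in first_level.values()))
    return highest, coop_a, coop_b, coop_c


def criticality(system: LVSystem, solver: SupportSolver | None = None) -> float:
    """Distance of the ``alpha`` vector to the nearest GASS-changing bifurcation.

    Perturbing a single ``alpha_i`` by ``delta`` moves the restricted GASS
    equilibrium affinely, so the support can only change where (a) a GASS
    component crosses zero or (b) the invasion rate of an absent component
    crosses zero.  The smallest positive magnitude over all components and
    both signs is returned; ``inf`` if no direction has a finite threshold.
    """
    validate_system(system)
    if solver is None:
        solver = get_solver(system)
    feas = solver.feasible(system.alpha)
    gass_mask = 0
    for m in feas:
        gass_mask |= m
    return _criticality_from_gass(system.alpha, solver, gass_mask)


def _criticality_from_gass(
    alpha: np.ndarray, solver: SupportSolver, gass_mask: int
) -> float:
    n = solver.n
    idx = solver.indices(gass_mask)
    absent = [k for k in range(n) if not (gass_mask >> k) & 1]
    best = math.inf
    if idx.size:
        inv = solver.inverse(gass_mask)
        u_s = inv @ alpha[idx]
        # invasion rates of absent components at the GASS
        rates = {
            k: alpha[k] + solver.g * (solver.gamma[k, idx] @ u_s) for k in absent
        }
        gamma_abs = {k: solver.g * solver.gamma[k, idx] for k in absent}
        for pos in range(idx.size):
            v = inv[:, pos]  # d u_S / d alpha_i, entrywise nonnegative
            # decreasing alpha_i drives GASS components to zero
            feasible_dirs = v > _DERIV_TOL
            if np.any(feasible_dirs):
                cand = np.min(u_s[feasible_dirs] / v[feasible_dirs])
                best = min(best, abs(cand))
            # increasing alpha_i lifts absent components' invasion rates
            for k in absent:
                d = float(gamma_abs[k] @ v)
                if d > _DERIV_TOL:
                    best = min(best, abs(-rates[k] / d))
    else:
        rates = {k: float(alpha[k]) for k in absent}
    # perturbing an absent component's own alpha raises its invasion rate 1:1
    for k in absent:
        best = min(best, abs(rates[k]))
    return best


def measures(system: LVSystem, solver: SupportSolver | None = None) -> ISMeasures:
    """All scalar measures of the instantaneous IS, without building edges.

    This is the per-timepoint fast path: feasibility of all supports is
    solved against cached submatrix inverses and every measure is read off
    the resulting mask set.
    """
    validate_system(system)
    if solver is None:
        solver = get_solver(system)
    return _measures_fast(system.alpha, solver)[0]


def _measures_fast(
    alpha: np.ndarray, solver: SupportSolver
) -> tuple[ISMeasures, int]:
    """Measures plus the GASS mask for one ``alpha`` snapshot."""
    feas = solver.feasible(alpha)
    masks = list(feas)
    gass_mask = 0
    for m in masks:
        gass_mask |= m
    noel_value = gass_mask.bit_count() + 1
    highest, coop_a, coop_b, coop_c = _cooperation_values(masks, gass_mask)
    crit = _criticality_from_gass(alpha, solver, gass_mask)
    m = ISMeasures(
        noel=noel_value,
        frondosity=_frondosity(len(masks), noel_value),
        criticality=crit,
        coop_highest_level=highest,
        coop_A=coop_a,
        coop_B=coop_b,
        coop_C=coop_c,
    )
    return m, gass_mask
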