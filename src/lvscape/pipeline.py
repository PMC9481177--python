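"""Per-subject sweep: from an alpha trajectory to the 15 summary features.

Each transition of an :class:`~lvscape.transform.AlphaTrajectory` defines an
instantaneous LV system (the connectivity is fixed, ``alpha`` varies); the
sweep computes the Information-Structure measures at every timepoint and
aggregates them across time into the subject's feature vector:

mean and standard deviation of NoEL, frondosity, highest cooperation level
and the three cooperation values; median and standard deviation of
criticality (the median is robust to the occasional far-from-bifurcation
outlier); and synchronicity, the fraction of timepoints whose attractor has
an extreme number of levels (all networks present in, or absent from, the
GASS).

Standard deviations are population standard deviations (divisor ``N``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SupportSolver, support_of
from .structure import ISMeasures, _measures_fast
from .transform import AlphaTrajectory, YEO7_LABELS
from . import structure as _structure
from .core import LVSystem, get_solver, validate_system

log = logging.getLogger(__name__)

#: canonical order of the 15 subject-level features
FEATURE_NAMES = (
    "noel_mean",
    "noel_sd",
    "frondosity_mean",
    "frondosity_sd",
    "criticality_median",
    "criticality_sd",
    "synchronicity",
    "coop_level_mean",
    "coop_level_sd",
    "coop_a_mean",
    "coop_a_sd",
    "coop_b_mean",
    "coop_b_sd",
    "coop_c_mean",
    "coop_c_sd",
)

#: network pairs whose GASS differentiation is reported by default
DEFAULT_PAIRS = (("DMN", "Frontoparietal"), ("DMN", "DorsalAttention"))


@dataclass
class SubjectSummary:
    """The across-time feature vector of one subject."""

    features: dict
    differentiation: dict = field(default_factory=dict)
    n_timepoints: int = 0
    n_infinite_criticality: int = 0

    def as_series(self) -> pd.Series:
        s = pd.Series({k: self.features[k] for k in FEATURE_NAMES})
        for k, v in self.differentiation.items():
            s[f"diff_{k[0]}_{k[1]}"] = v
        return s


def timepoint_measures(
    alpha_row: np.ndarray, sc: np.ndarray, g: float
) -> ISMeasures:
    """IS measures of the instantaneous system defined by one alpha row."""
    system = validate_system(LVSystem(alpha=alpha_row, gamma=sc, g=g))
    return _structure.measures(system)


def sweep_trajectory(
    alphas: AlphaTrajectory,
) -> tuple[pd.DataFrame, list[frozenset]]:
    """Measures for every transition, plus the GASS support sequence.

    Feasibility at each timepoint is solved against submatrix inverses
    cached once per connectivity matrix, which keeps the full enumeration
    over ``2**n`` supports affordable across a whole recording.
    """
    system0 = validate_system(
        LVSystem(alpha=alphas.alphas[0], gamma=alphas.sc, g=alphas.g)
    )
    solver = get_solver(system0)
    rows = []
    supports: list[frozenset] = []
    for alpha_row in alphas.alphas:
        m, gass_mask = _measures_fast(np.asarray(alpha_row, float), solver)
        rows.append(m.as_dict())
        supports.append(support_of(gass_mask))
    return pd.DataFrame(rows), supports


def synchronicity(noel_sequence, n: int) -> float:
    """Fraction of timepoints with extreme NoEL (1 or ``n + 1``)."""
    seq = np.asarray(list(noel_sequence), dtype=int)
    if seq.size == 0:
        raise ValueError("empty NoEL sequence")
    if np.any((seq < 1) | (seq > n + 1)):
        raise ValueError("NoEL values must lie in [1, n + 1]")
    return float(np.mean((seq == 1) | (seq == n + 1)))


def pairwise_differentiation(gass_supports, a: int, b: int) -> float:
    """Fraction of timepoints where exactly one of two networks is in the GASS."""
    if a == b:
        raise ValueError("differentiation needs two distinct networks")
    supports = list(gass_supports)
    if not supports:
        raise ValueError("empty support sequence")
    hits = sum(((a in s) != (b in s)) for s in supports)
    return hits / len(supports)


def subject_summary(
    alphas: AlphaTrajectory,
    pairs=DEFAULT_PAIRS,
) -> SubjectSummary:
    """Aggregate the per-timepoint measures into the 15 subject features.

    Timepoints whose criticality is infinite (no finite bifurcation in any
    perturbation direction) are excluded from the criticality median and
    standard deviation; their count is logged and reported.
    """
    if alphas.n_transitions < 2:
        raise ValueError("need at least two transitions to aggregate")
    frame, supports = sweep_trajectory(alphas)
    n = alphas.n
    feats: dict = {}
    for name in ("noel", "frondosity", "coop_highest_level", "coop_A", "coop_B", "coop_C"):
        key = {
            "noel": "noel",
            "frondosity": "frondosity",
            "coop_highest_level": "coop_level",
            "coop_A": "coop_a",
            "coop_B": "coop_b",
            "coop_C": "coop_c",
        }[name]
        col = frame[name].to_numpy(dtype=float)
        feats[f"{key}_mean"] = float(np.mean(col))
        feats[f"{key}_sd"] = float(np.std(col))
    crit = frame["criticality"].to_numpy(dtype=float)
    finite = np.isfinite(crit)
    n_inf = int(np.sum(~finite))
    if n_inf:
        log.info("excluding %d timepoints with infinite criticality", n_inf)
    crit_finite = crit[finite]
    if crit_finite.size == 0:
        feats["criticality_median"] = math.inf
        feats["criticality_sd"] = 0.0
    else:
        feats["criticality_median"] = float(np.median(crit_finite))
        feats["criticality_sd"] = float(np.std(crit_finite))
    feats["synchronicity"] = synchronicity(frame["noel"], n)
    labels = list(alphas.labels)
    diffs = {}
    for a_name, b_name in pairs:
        if a_name in labels and b_name in labels:
            a, b = labels.index(a_name), labels.index(b_name)
            diffs[(a_name, b_name)] = pairwise_differentiation(supports, a, b)
    return SubjectSummary(
        features=feats,
        differentiation=diffs,
        n_timepoints=alphas.n_transitions,
        n_infinite_criticality=n_inf,
    )
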