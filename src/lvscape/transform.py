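"""The Lotka-Volterra Transform (LVT).

The LVT inverts the explicit-Euler discretisation of the cooperative LV
equations: given an observed positive network timeseries ``u`` and a fixed
connectivity matrix, it returns at every transition the intrinsic growth
parameters ``alpha(t)`` that exactly reproduce the observed step,

    alpha_i(t) = (u_i(t+1) - u_i(t)) / (h * u_i(t))
                 + u_i(t) - g * sum_j gamma_ij u_j(t).

The step size ``h`` plays the role of the sampling interval of the
discretised model and scales proportionally with the repetition time (TR):
``h = 3.55e-4`` at TR = 2000 ms.  The coupling ``g`` (default 0.27) weights
the connectivity against the intrinsic terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: reference step size at the reference repetition time
H_BASE = 3.55e-4
TR_BASE_MS = 2000.0
#: default global coupling applied to the connectivity matrix
G_DEFAULT = 0.27

#: canonical 7-network cortical parcellation order
YEO7_LABELS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "DMN",
)


@dataclass
class TimeSeries:
    """Positive-valued network activity, one column per network."""

    values: np.ndarray  # (T, n)
    tr_ms: float = TR_BASE_MS
    labels: tuple = YEO7_LABELS

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = tuple(self.labels)[: self.values.shape[1]]
        if self.values.shape[0] < 2:
            raise ValueError("a timeseries needs at least two timepoints")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class AlphaTrajectory:
    """Per-transition growth parameters recovered by the LVT."""

    alphas: np.ndarray  # (T-1, n)
    h: float
    g: float
    sc: np.ndarray
    labels: tuple = YEO7_LABELS

    def __post_init__(self) -> None:
        self.alphas = np.atleast_2d(np.asarray(self.alphas, dtype=float))
        self.sc = np.asarray(self.sc, dtype=float)
        self.labels = tuple(self.labels)[: self.alphas.shape[1]]

    @property
    def n(self) -> int:
        return self.alphas.shape[1]

    @property
    def n_transitions(self) -> int:
        return self.alphas.shape[0]


def h_for_tr(tr_ms: float) -> float:
    """Discretisation step for a given repetition time, proportional to TR."""
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    return H_BASE * (tr_ms / TR_BASE_MS)


def normalize_timeseries(
    raw: np.ndarray,
    lo: float = 0.05,
    hi: float = 1.0,
    tr_ms: float = TR_BASE_MS,
    labels=YEO7_LABELS,
) -> TimeSeries:
    """Map a raw (possibly zero-centred) series into the positive band ``[lo, hi]``.

    A single affine map per subject sends the global minimum across all
    networks to ``lo`` and the global maximum to ``hi``.  Using one map for
    the whole matrix, rather than one per column, preserves the
    between-network amplitude relations that the attractor membership
    depends on.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw timeseries contains non-finite values")
    if not (hi > lo > 0):
        raise ValueError("need hi > lo > 0")
    rmin, rmax = float(raw.min()), float(raw.max())
    if rmax == rmin:
        raise ValueError("degenerate timeseries: constant matrix cannot be normalised")
    scaled = lo + (raw - rmin) * (hi - lo) / (rmax - rmin)
    return TimeSeries(values=scaled, tr_ms=tr_ms, labels=labels)


def lvt_transform(
    ts: TimeSeries,
    sc: np.ndarray,
    h: float | None = None,
    g: float = G_DEFAULT,
) -> AlphaTrajectory:
    """Invert the discretised LV dynamics into per-transition ``alpha`` values.

    For every ``t``, plugging ``alpha(t)`` back into one explicit-Euler step
    from ``u(t)`` reproduces ``u(t+1)`` to machine precision; this
    reconstruction contract is the transform's defining property.
    """
    sc = np.asarray(sc, dtype=float)
    if sc.shape != (ts.n, ts.n):
        raise ValueError(f"connectivity must be ({ts.n}, {ts.n}), got {sc.shape}")
    if np.any(sc - np.diag(np.diag(sc)) < 0):
        raise ValueError("connectivity must be nonnegative off the diagonal")
    if h is None:
        h = h_for_tr(ts.tr_ms)
    u = ts.values
    if np.any(u <= 0):
        raise ValueError("LVT requires positive activity")
    u_now = u[:-1]
    u_next = u[1:]
    alphas = (u_next - u_now) / (h * u_now) + u_now - g * (u_now @ sc.T)
    return AlphaTrajectory(alphas=alphas, h=h, g=g, sc=sc, labels=ts.labels)


def reconstruct_step(
    u_now: np.ndarray, alpha: np.ndarray, sc: np.ndarray, h: float, g: float
) -> np.ndarray:
    """One explicit-Euler step; the forward counterpart of the transform."""
    u_now = np.asarray(u_now, dtype=float)
    return u_now + h * u_now * (alpha - u_now + g * (sc @ u_now))
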