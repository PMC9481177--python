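"""Ground-truthed synthetic cohorts for end-to-end testing of the pipeline.

The generator emulates the statistical structure the analysis assumes: a
fixed symmetric nonnegative connectivity matrix shared by the cohort,
per-subject latent growth-parameter processes drawn from group archetypes,
and positive observed timeseries produced by the same explicit-Euler forward
model the transform inverts, plus additive Gaussian observation noise.

Archetypes encode qualitatively distinct dynamical regimes:

* ``near_bifurcation`` — growth parameters straddle the attractor-membership
  thresholds (some dip negative), giving variable attractor membership,
  cooperation, and small distances to bifurcation;
* ``saturated`` — all parameters stay well above zero, so the attractor
  always contains every network (extreme NoEL, frondosity 1, no
  cooperation);
* ``intermediate`` — between the two.

Because the forward model advances by one Euler step of size ``h`` per
repetition time, observed increments are of order ``h``; the inverse
transform divides by ``h``, so observation noise on the series is amplified
by ``~1/h`` in the recovered parameters.  The default noise level is chosen
small on that scale (see ``noise_sd``), keeping the recovered trajectories
informative; the noiseless case round-trips exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import LVSystem, spectral_radius, validate_system
from .transform import (
    AlphaTrajectory,
    G_DEFAULT,
    TR_BASE_MS,
    TimeSeries,
    YEO7_LABELS,
    h_for_tr,
    reconstruct_step,
)

ARCHETYPES = ("near_bifurcation", "intermediate", "saturated")

#: default additive observation noise on the series (see module docstring)
NOISE_SD_DEFAULT = 1e-6
#: observed values are clamped at this floor after adding noise
POSITIVE_FLOOR = 0.025


def _load_archetype_params() -> dict:
    text = (
        importlib.resources.files("lvscape") / "config" / "archetypes.yaml"
    ).read_text()
    return yaml.safe_load(text)


_ARCHETYPE_PARAMS = _load_archetype_params()


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    groups: tuple  # of (name, archetype, n_subjects)
    T: int = 100
    tr_ms: float = TR_BASE_MS
    noise_sd: float = NOISE_SD_DEFAULT
    sc_density: float = 0.5
    g: float = G_DEFAULT
    n_networks: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 10:
            raise ValueError("T must be >= 10")
        for name, archetype, n_subjects in self.groups:
            if archetype not in ARCHETYPES:
                raise ValueError(f"unknown archetype {archetype!r}")
            if n_subjects < 1:
                raise ValueError(f"group {name!r} needs at least one subject")


def generate_sc(
    n: int, density: float, seed: int, g: float = G_DEFAULT, margin: float = 0.6
) -> np.ndarray:
    """Random symmetric nonnegative connectivity with a guaranteed coupling margin.

    Off-diagonal weights are lognormal, present with probability
    ``density``, and modulated by a spread of per-network strength factors
    (structural connectomes are strongly heterogeneous: some networks are
    far more weakly coupled than others, and that heterogeneity is what
    lets individual networks join or leave the attractor independently).
    The matrix is rescaled so ``g * spectral_radius`` equals ``margin``
    (< 1), keeping every generated system inside the validity region of the
    attractor theory with room for perturbation.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(mean=0.0, sigma=0.6, size=(n, n))
    strength = rng.permutation(np.geomspace(0.35, 1.3, n))
    weights = weights * strength[:, None] * strength[None, :]
    present = rng.random((n, n)) < density
    sc = np.triu(weights * present, k=1)
    sc = sc + sc.T
    rho = spectral_radius(sc)
    if rho > 0:
        sc *= margin / (g * rho)
    return sc


def generate_alpha_process(
    archetype: str, T: int, n: int, seed: int
) -> np.ndarray:
    """Mean-reverting bounded random walk of growth parameters, shape ``(T, n)``.

    Each network gets a long-run mean drawn from the archetype's range; the
    walk reverts toward it at rate ``revert`` with innovations scaled so the
    stationary spread is the archetype's ``sd``, and is clipped to the
    archetype's bounds.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    p = _ARCHETYPE_PARAMS[archetype]
    rng = np.random.default_rng(seed)
    mu = rng.uniform(p["mu_lo"], p["mu_hi"], size=n)
    theta = float(p["revert"])
    # innovation scale giving stationary sd `sd` for an AR(1) with decay 1-theta
    step_sd = p["sd"] * np.sqrt(1.0 - (1.0 - theta) ** 2)
    out = np.empty((T, n))
    x = rng.normal(mu, p["sd"])
    for t in range(T):
        x = np.clip(x, p["clip_lo"], p["clip_hi"])
        out[t] = x
        x = x + theta * (mu - x) + rng.normal(0.0, step_sd, size=n)
    return out


def generate_subject(
    archetype: str,
    sc: np.ndarray,
    seed: int,
    T: int = 100,
    tr_ms: float = TR_BASE_MS,
    noise_sd: float = NOISE_SD_DEFAULT,
    g: float = G_DEFAULT,
) -> tuple[TimeSeries, AlphaTrajectory]:
    """One subject: observed series plus the latent ground-truth trajectory.

    The series starts from a random positive state and advances by one
    explicit-Euler step of size ``h(tr_ms)`` per repetition time using the
    latent ``alpha`` row for that transition; Gaussian observation noise is
    added and the result clamped to a positive floor.
    """
    n = sc.shape[0]
    rng = np.random.default_rng(seed)
    alphas = generate_alpha_process(
        archetype, T - 1, n, seed=int(rng.integers(2**31))
    )
    h = h_for_tr(tr_ms)
    u = rng.uniform(0.1, 1.0, size=n)
    clean = np.empty((T, n))
    clean[0] = u
    for t in range(T - 1):
        u = reconstruct_step(u, alphas[t], sc, h, g)
        clean[t + 1] = u
    observed = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    observed = np.maximum(observed, POSITIVE_FLOOR)
    ts = TimeSeries(values=observed, tr_ms=tr_ms, labels=YEO7_LABELS[:n])
    truth = AlphaTrajectory(alphas=alphas, h=h, g=g, sc=sc, labels=YEO7_LABELS[:n])
    return ts, truth


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    series: TimeSeries
    truth: AlphaTrajectory


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], np.ndarray]:
    """All subjects of a cohort plus the shared connectivity matrix.

    Determinism contract: identical specs (including the seed) reproduce
    byte-identical outputs.  Per-subject seeds are spawned from the spec
    seed, so adding a group never reshuffles earlier subjects' data.
    """
    sc_seed = int(
        np.random.SeedSequence([spec.seed, 0]).generate_state(1)[0] % 2**31
    )
    sc = generate_sc(spec.n_networks, spec.sc_density, seed=sc_seed, g=spec.g)
    validate_system(
        LVSystem(alpha=np.zeros(spec.n_networks), gamma=sc, g=spec.g)
    )
    subjects: list[SyntheticSubject] = []
    counter = 0
    for name, archetype, n_subjects in spec.groups:
        for j in range(n_subjects):
            seed = int(
                np.random.SeedSequence([spec.seed, counter + 1]).generate_state(1)[0]
                % 2**31
            )
            series, truth = generate_subject(
                archetype,
                sc,
                seed=seed,
                T=spec.T,
                tr_ms=spec.tr_ms,
                noise_sd=spec.noise_sd,
                g=spec.g,
            )
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{name}_{j:03d}", group=name, series=series, truth=truth
                )
            )
            counter += 1
    return subjects, sc
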