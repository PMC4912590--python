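"""Overdamped Langevin dynamics of a single periodic dihedral coordinate.

The all-atom problem is reduced to its analyzed observable: one urea
torsion phi moving on a cosine-series free-energy surface U(phi).  The
dynamics is the high-friction (overdamped) limit

    d(phi) = -(D / k_B T) U'(phi) dt + sqrt(2 D dt) eta,

integrated by Euler-Maruyama with periodic wrapping; its stationary
distribution is Boltzmann, which is all the umbrella-sampling/WHAM
estimator chain downstream requires.  Angles are in degrees, energies in
kcal/mol, time in ps, D in deg^2/ps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "KB_KCAL",
    "CosineTerm",
    "DihedralPotential",
    "fit_double_well",
    "get_preset",
    "SimConfig",
    "TrajectorySample",
    "UmbrellaWindow",
    "bias_constant",
    "make_umbrella_protocol",
    "run_langevin",
    "run_umbrella_protocol",
    "count_transitions",
    "kramers_rate",
    "kramers_estimate",
]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/mol/K

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class CosineTerm:
    amplitude: float  # kcal/mol, >= 0
    periodicity: int  # positive integer
    phase_deg: float = 0.0


@dataclass(frozen=True)
class DihedralPotential:
    """Cosine-series torsional potential U(phi) = sum A_j (1 + cos(n_j phi - d_j))."""

    terms: tuple = field(default_factory=tuple)
    name: str = "custom"

    def energy(self, phi_deg):
        phi = np.asarray(phi_deg, dtype=float) * _DEG
        u = np.zeros_like(phi)
        for t in self.terms:
            u = u + t.amplitude * (1.0 + np.cos(t.periodicity * phi - t.phase_deg * _DEG))
        return u if u.shape else float(u)

    def gradient(self, phi_deg):
        """dU/dphi in kcal/mol per degree."""
        phi = np.asarray(phi_deg, dtype=float) * _DEG
        g = np.zeros_like(phi)
        for t in self.terms:
            g = g - t.amplitude * t.periodicity * np.sin(t.periodicity * phi - t.phase_deg * _DEG)
        g = g * _DEG
        return g if g.shape else float(g)

    def curvature(self, phi_deg):
        """d2U/dphi2 in kcal/mol per degree^2."""
        phi = np.asarray(phi_deg, dtype=float) * _DEG
        c = np.zeros_like(phi)
        for t in self.terms:
            c = c - t.amplitude * t.periodicity**2 * np.cos(t.periodicity * phi - t.phase_deg * _DEG)
        c = c * _DEG**2
        return c if c.shape else float(c)


def fit_double_well(delta: float, barrier: float, name: str = "custom") -> DihedralPotential:
    """Two-term cosine series with prescribed cis offset and trans barrier.

    Solves U(phi) = A1 (1 - cos phi) + A2 (1 - cos 2 phi) for amplitudes
    such that U(180) - U(0) = ``delta`` and the interior maximum relative
    to the trans minimum at 0 deg equals ``barrier`` (both kcal/mol).  The
    transition-state angle is whatever the two-term fit implies.
    """
    if barrier <= delta or barrier <= 0:
        raise ValueError("barrier must exceed the cis-trans offset and be positive")
    a1 = delta / 2.0
    s = barrier - a1  # = 2*A2 + delta^2/(32 A2) at the interior maximum
    disc = s * s - delta * delta / 4.0
    if disc < 0:
        raise ValueError("no two-term fit for these constraints")
    a2 = (s + np.sqrt(disc)) / 4.0
    pot = DihedralPotential(
        terms=(
            CosineTerm(a1, 1, 180.0),
            CosineTerm(a2, 2, 180.0),
        ),
        name=name,
    )
    return pot


_PRESETS = {
    # vacuum umbrella-sampling profile: cis offset 4.1, barrier 14.0 kcal/mol
    "paper_vacuum": (4.1, 14.0),
    # explicit-solvent profile: cis offset 5.7, barrier 14.8 kcal/mol
    "paper_solution": (5.7, 14.8),
}


def get_preset(name: str) -> DihedralPotential:
    """Named potentials: paper_vacuum, paper_solution, flat."""
    if name == "flat":
        return DihedralPotential(terms=(), name="flat")
    try:
        delta, barrier = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; options: flat, {', '.join(_PRESETS)}")
    return fit_double_well(delta, barrier, name=name)


@dataclass(frozen=True)
class SimConfig:
    """Langevin integrator settings.

    Defaults: D = 100 deg^2/ps and dt = 0.02 ps make the harmonic-window
    relaxation time (~0.5 ps at the default bias strength) much shorter
    than a production run while keeping the Euler-Maruyama discretization
    bias on stationary moments at the percent level.  The default stride
    of 20 steps (0.4 ps between stored snapshots, about one window
    relaxation time) keeps stored snapshots approximately decorrelated.
    """

    temperature: float = 300.0  # K
    diffusion: float = 100.0  # deg^2/ps
    dt: float = 0.02  # ps
    equilibration_steps: int = 2000
    n_snapshots: int = 10000
    stride: int = 20  # integrator steps per stored snapshot
    seed: int = 0
    start_angle: Optional[float] = None

    def __post_init__(self):
        for name in ("temperature", "diffusion", "dt", "stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_snapshots <= 0 or self.equilibration_steps < 0:
            raise ValueError("invalid step counts")

    @property
    def kbt(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class TrajectorySample:
    angles: np.ndarray  # wrapped, degrees
    dt: float
    temperature: float
    seed: int
    stride: int


@dataclass
class UmbrellaWindow:
    """Harmonic bias V(phi) = k * wrap(phi - center)^2 (minimum image)."""

    center: float  # degrees
    k: float  # kcal/mol/deg^2
    samples: Optional[TrajectorySample] = None

    def bias(self, phi_deg):
        d = wrap_angle(np.asarray(phi_deg, dtype=float) - self.center)
        return self.k * d * d

    def bias_gradient(self, phi_deg):
        d = wrap_angle(np.asarray(phi_deg, dtype=float) - self.center)
        return 2.0 * self.k * d


class SimulationInstability(RuntimeError):
    pass


def bias_constant(height: float = 200.0, half_range: float = 180.0,
                  mode: str = "harmonic") -> float:
    """Force constant k (kcal/mol/deg^2) from a "height over range" spec.

    ``harmonic`` reads the spec as a harmonic restraint reaching ``height``
    kcal/mol at a displacement of ``half_range`` degrees, i.e.
    k = height / half_range^2.  ``slope`` reads it as a constant force of
    height/half_range kcal/mol/deg matched by the harmonic gradient at
    half_range, i.e. k = height / (2 half_range^2).
    """
    if mode == "harmonic":
        return height / half_range**2
    if mode == "slope":
        return height / (2.0 * half_range**2)
    raise ValueError("mode must be 'harmonic' or 'slope'")


def make_umbrella_protocol(
    n_windows: int = 121,
    shift: float = 3.0,
    k: Optional[float] = None,
    bias_height: float = 200.0,
    bias_half_range: float = 180.0,
    bias_mode: str = "harmonic",
) -> list[UmbrellaWindow]:
    """Evenly shifted umbrella windows: centers -180 + i*shift.

    The default 121 windows with a 3 degree shift span the full circle
    (both representations of the cis state are included).  A protocol not
    covering the circle triggers a warning but is allowed.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if k is None:
        k = bias_constant(bias_height, bias_half_range, bias_mode)
    centers = -180.0 + shift * np.arange(n_windows)
    if shift * (n_windows - 1) < 360.0 - shift:
        warnings.warn("umbrella protocol does not cover the full circle")
    return [UmbrellaWindow(center=float(wrap_angle(c)) if c != 180.0 else 180.0, k=float(k))
            for c in centers]


def _integrate(
    pot: DihedralPotential,
    centers: Optional[np.ndarray],
    k: float,
    starts: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized Euler-Maruyama over parallel replicas; returns (n_snapshots, m)."""
    m = starts.size
    phi = starts.astype(float).copy()
    kbt = cfg.kbt
    mob = cfg.diffusion / kbt  # deg^2 / (kcal/mol) / ps
    noise = np.sqrt(2.0 * cfg.diffusion * cfg.dt)
    n_steps = cfg.equilibration_steps + cfg.n_snapshots * cfg.stride
    out = np.empty((cfg.n_snapshots, m))
    snap = 0
    for step in range(1, n_steps + 1):
        force = -pot.gradient(phi)
        if centers is not None:
            force = force - 2.0 * k * wrap_angle(phi - centers)
        drift = mob * force * cfg.dt
        if np.any(np.abs(drift) > 60.0):
            raise SimulationInstability(
                "single-step deterministic drift exceeded 60 deg; reduce dt or D"
            )
        dphi = drift + noise * rng.standard_normal(m)
        phi = wrap_angle(phi + dphi)
        if step > cfg.equilibration_steps and (step - cfg.equilibration_steps) % cfg.stride == 0:
            out[snap] = phi
            snap += 1
    return out


def run_langevin(
    pot: DihedralPotential,
    bias: Optional[UmbrellaWindow] = None,
    cfg: SimConfig = SimConfig(),
) -> TrajectorySample:
    """Sample one trajectory; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.start_angle is not None:
        start = cfg.start_angle
    elif bias is not None:
        start = bias.center
    else:
        start = 0.0
    centers = np.array([bias.center]) if bias is not None else None
    k = bias.k if bias is not None else 0.0
    angles = _integrate(pot, centers, k, np.array([float(start)]), cfg, rng)[:, 0]
    return TrajectorySample(
        angles=angles, dt=cfg.dt, temperature=cfg.temperature,
        seed=cfg.seed, stride=cfg.stride,
    )


def run_umbrella_protocol(
    pot: DihedralPotential,
    windows: Sequence[UmbrellaWindow],
    cfg: SimConfig = SimConfig(),
) -> list[UmbrellaWindow]:
    """Sample every window (all replicas integrated in lockstep).

    Returns new UmbrellaWindow objects carrying their TrajectorySample.
    All windows share the force constant of the first window.
    """
    ks = {w.k for w in windows}
    if len(ks) != 1:
        raise ValueError("all windows must share one force constant")
    k = ks.pop()
    centers = np.array([w.center for w in windows])
    rng = np.random.default_rng(cfg.seed)
    traj = _integrate(pot, centers, k, centers.copy(), cfg, rng)
    out = []
    for i, w in enumerate(windows):
        out.append(
            UmbrellaWindow(
                center=w.center,
                k=k,
                samples=TrajectorySample(
                    angles=traj[:, i], dt=cfg.dt, temperature=cfg.temperature,
                    seed=cfg.seed, stride=cfg.stride,
                ),
            )
        )
    return out


def count_transitions(
    angles: Sequence[float], trans_tol: float = 30.0, cis_tol: float = 30.0
) -> int:
    """Count full cis<->trans basin crossings with hysteresis.

    A crossing is registered only when the trajectory fully enters the
    opposite basin (trans: |phi| <= trans_tol; cis: |phi| >= 180 - cis_tol);
    excursions into the barrier region that fall back do not count.
    """
    a = np.abs(wrap_angle(np.asarray(angles, dtype=float)))
    labels = np.where(a <= trans_tol, 0, np.where(a >= 180.0 - cis_tol, 1, -1))
    resolved = labels[labels >= 0]
    if resolved.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(resolved)))


def kramers_rate(
    barrier: float,
    curvature_min: float,
    curvature_barrier: float,
    diffusion: float,
    temperature: float,
) -> float:
    """High-friction Kramers escape rate over one barrier, per ps.

    rate = D sqrt(U''_min |U''_barrier|) / (2 pi k_B T) * exp(-barrier/k_B T)
    with curvatures in kcal/mol/deg^2 and D in deg^2/ps.
    """
    kbt = KB_KCAL * temperature
    pref = diffusion * np.sqrt(curvature_min * abs(curvature_barrier)) / (2.0 * np.pi * kbt)
    return float(pref * np.exp(-barrier / kbt))


def _extrema(pot: DihedralPotential, grid_step: float = 0.05):
    """Locate minima and maxima of U on the circle by dense-grid scan."""
    phi = np.arange(-180.0, 180.0, grid_step)
    u = pot.energy(phi)
    n = u.size
    left = np.roll(u, 1)
    right = np.roll(u, -1)
    minima = np.where((u < left) & (u <= right))[0]
    maxima = np.where((u > left) & (u >= right))[0]
    return phi, u, minima, maxima


def kramers_estimate(pot: DihedralPotential, cfg: SimConfig = SimConfig()) -> float:
    """Order-of-magnitude unbiased transition rate out of the global minimum.

    Sums the Kramers escape rates over the barriers adjacent (left/right
    on the circle) to the global minimum.  Raises for potentials without
    at least two minima separated by barriers.
    """
    phi, u, minima, maxima = _extrema(pot)
    if minima.size < 2 or maxima.size < 1:
        raise ValueError("potential has no double-well structure")
    gmin = minima[np.argmin(u[minima])]
    rate = 0.0
    cmin = pot.curvature(phi[gmin])
    for mx in maxima:
        barrier = u[mx] - u[gmin]
        rate += kramers_rate(
            barrier, cmin, pot.curvature(phi[mx]), cfg.diffusion, cfg.temperature
        )
    return rate
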