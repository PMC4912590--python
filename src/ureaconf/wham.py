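"""Periodic weighted-histogram analysis (WHAM) and PMF feature extraction.

Window histograms over a shared periodic grid are re-weighted into one
unbiased probability profile by the standard self-consistent iteration

    p_b  proportional to  (sum_i n_ib) / (sum_i N_i exp((f_i - V_i(phi_b)) / kT))
    f_i = -kT ln sum_b p_b exp(-V_i(phi_b) / kT)

with all bias evaluations using minimum-image angular distances, so the
dihedral's periodicity is respected.  The free energy is -kT ln p_b,
shifted so its minimum is zero.  Errors come from Monte-Carlo subset
resampling of snapshots within each window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .geometry import wrap_angle
from .sim import KB_KCAL, UmbrellaWindow, TrajectorySample

__all__ = [
    "WhamInput",
    "PMFProfile",
    "PMFFeatures",
    "build_wham_input",
    "boltzmann_invert",
    "wham_solve",
    "pmf_features",
    "bootstrap_errors",
]


@dataclass
class WhamInput:
    bin_centers: np.ndarray  # (B,) degrees, periodic grid
    counts: np.ndarray  # (W, B) histogram counts
    centers: np.ndarray  # (W,) window centers, degrees
    ks: np.ndarray  # (W,) force constants, kcal/mol/deg^2
    temperature: float  # K

    @property
    def bias_matrix(self) -> np.ndarray:
        """V_i(phi_b), (W, B), minimum-image harmonic bias."""
        d = wrap_angle(self.bin_centers[None, :] - self.centers[:, None])
        return self.ks[:, None] * d * d

    @property
    def n_snapshots(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class PMFFeatures:
    trans_angle: float
    cis_angle: float
    delta_g: float  # G(cis min) - G(trans min), kcal/mol
    barrier: float  # max along the lower path from trans to cis, kcal/mol
    ts_angle: float  # positive representative, degrees
    cis_is_local_min: bool = True


@dataclass
class PMFProfile:
    angles: np.ndarray  # bin centers, degrees
    free_energy: np.ndarray  # kcal/mol, min-shifted to 0
    errors: Optional[np.ndarray] = None
    features: Optional[PMFFeatures] = None
    iterations: int = 0
    residual: float = 0.0
    residual_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    window_free_energies: Optional[np.ndarray] = None


def _grid(bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    n_bins = int(round(360.0 / bin_width))
    if abs(n_bins * bin_width - 360.0) > 1e-9 or n_bins < 2:
        raise ValueError("bin width must evenly divide 360 degrees")
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    centers = edges[:-1] + bin_width / 2.0
    return edges, centers


def build_wham_input(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 3.0,
    temperature: Optional[float] = None,
) -> WhamInput:
    """Bin every window's samples onto a shared periodic grid.

    Empty windows are excluded with a warning.  The temperature defaults
    to the (common) simulation temperature carried by the samples.
    """
    dropped = [
        w.center for w in windows
        if w.samples is None or w.samples.angles.size == 0
    ]
    if dropped:
        warnings.warn(f"excluding empty windows at centers {dropped}")
    windows = [w for w in windows if w.samples is not None and w.samples.angles.size]
    if not windows:
        raise ValueError("no windows with samples")
    temps = {w.samples.temperature for w in windows}
    if temperature is None:
        if len(temps) != 1:
            raise ValueError("windows sampled at different temperatures")
        temperature = temps.pop()
    edges, centers = _grid(bin_width)
    counts = np.stack(
        [np.histogram(wrap_angle(w.samples.angles), bins=edges)[0] for w in windows]
    ).astype(float)
    return WhamInput(
        bin_centers=centers,
        counts=counts,
        centers=np.array([w.center for w in windows], dtype=float),
        ks=np.array([w.k for w in windows], dtype=float),
        temperature=float(temperature),
    )


def boltzmann_invert(counts: np.ndarray, temperature: float) -> np.ndarray:
    """Direct inversion F_b = -kT ln(n_b / N), shifted to min 0."""
    counts = np.asarray(counts, dtype=float)
    kbt = KB_KCAL * temperature
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(counts / counts.sum())
    return f - f.min()


def wham_solve(
    inp: WhamInput,
    tol: float = 1e-7,
    max_iter: int = 200000,
    f_init: Optional[np.ndarray] = None,
) -> PMFProfile:
    """Self-consistent WHAM solution on the periodic grid.

    Iterates until the window free energies change by less than ``tol``
    kcal/mol (sup-norm).  Bins with zero total counts are uncovered and a
    hard error; zero-count bins never arise in practice for protocols that
    tile the circle.  A single window with identically zero bias is the
    degenerate case whose exact solution is the direct Boltzmann inversion
    of its histogram, and is returned as such.
    """
    kbt = KB_KCAL * inp.temperature
    counts = inp.counts
    total = counts.sum(axis=0)
    uncovered = np.where(total == 0)[0]
    if uncovered.size:
        raise ValueError(
            f"uncovered bins at angles {inp.bin_centers[uncovered].tolist()}"
        )
    bias = inp.bias_matrix
    if counts.shape[0] == 1 and not np.any(bias):
        f = boltzmann_invert(counts[0], inp.temperature)
        return PMFProfile(
            angles=inp.bin_centers.copy(), free_energy=f,
            iterations=0, residual=0.0,
            window_free_energies=np.zeros(1),
        )
    n_i = counts.sum(axis=1)
    log_ni = np.log(n_i)
    log_total = np.log(total)
    neg_beta_v = -bias / kbt  # (W, B)
    g = np.zeros(counts.shape[0]) if f_init is None else np.asarray(f_init) / kbt
    trace = []
    for it in range(1, max_iter + 1):
        denom = logsumexp(log_ni[:, None] + g[:, None] + neg_beta_v, axis=0)
        log_p = log_total - denom
        log_p -= logsumexp(log_p)
        g_new = -logsumexp(log_p[None, :] + neg_beta_v, axis=1)
        resid = kbt * np.max(np.abs(g_new - g))
        trace.append(resid)
        g = g_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {resid:.3e})"
        )
    f_profile = -kbt * log_p
    f_profile = f_profile - f_profile.min()
    return PMFProfile(
        angles=inp.bin_centers.copy(),
        free_energy=f_profile,
        iterations=it,
        residual=float(resid),
        residual_trace=np.array(trace),
        window_free_energies=kbt * (g - g[0]),
    )


def _argmin_near(angles, f, ref, half_width=90.0):
    mask = np.abs(wrap_angle(angles - ref)) <= half_width
    idx = np.where(mask)[0]
    return idx[np.argmin(f[idx])]


def pmf_features(
    angles: np.ndarray,
    free_energy: np.ndarray,
    trans_ref: float = 0.0,
    cis_ref: float = 180.0,
) -> PMFFeatures:
    """Extract minima, cis-trans offset, barrier and transition state.

    The trans (cis) minimum is the grid argmin within +-90 deg of the
    reference; the barrier is the maximum along the lower-energy of the
    two periodic paths connecting the minima, measured from the trans
    minimum; symmetric +-phi transition states are reported as the
    positive representative.  If the cis-side argmin is not a local
    minimum of the profile, the offset is evaluated at ``cis_ref`` and
    flagged.
    """
    angles = np.asarray(angles, dtype=float)
    f = np.asarray(free_energy, dtype=float)
    order = np.argsort(angles)
    angles, f = angles[order], f[order]
    n = angles.size
    i_trans = _argmin_near(angles, f, trans_ref)
    i_cis = _argmin_near(angles, f, cis_ref)
    cis_local = bool(
        f[i_cis] <= f[(i_cis - 1) % n] and f[i_cis] <= f[(i_cis + 1) % n]
    )
    if not cis_local:
        i_cis = int(np.argmin(np.abs(wrap_angle(angles - cis_ref))))
    # two periodic paths from trans to cis
    if i_trans <= i_cis:
        path1 = np.arange(i_trans, i_cis + 1)
        path2 = np.concatenate([np.arange(i_cis, n), np.arange(0, i_trans + 1)])
    else:
        path1 = np.arange(i_cis, i_trans + 1)
        path2 = np.concatenate([np.arange(i_trans, n), np.arange(0, i_cis + 1)])
    max1, max2 = f[path1].max(), f[path2].max()
    if max1 <= max2:
        barrier_idx = path1[np.argmax(f[path1])]
        barrier = max1
    else:
        barrier_idx = path2[np.argmax(f[path2])]
        barrier = max2
    return PMFFeatures(
        trans_angle=float(angles[i_trans]),
        cis_angle=float(angles[i_cis]),
        delta_g=float(f[i_cis] - f[i_trans]),
        barrier=float(barrier - f[i_trans]),
        ts_angle=float(abs(angles[barrier_idx])),
        cis_is_local_min=cis_local,
    )


def bootstrap_errors(
    windows: Sequence[UmbrellaWindow],
    n_subsets: int = 10,
    subset_fraction: float = 1.0,
    replace: bool = True,
    seed: int = 0,
    bin_width: float = 3.0,
    temperature: Optional[float] = None,
    tol: float = 1e-7,
    max_iter: int = 200000,
) -> tuple[np.ndarray, dict, list]:
    """Monte-Carlo subset errors for the WHAM profile and its features.

    For each of ``n_subsets`` replicates every window's snapshots are
    resampled (with replacement by default, at ``subset_fraction`` of the
    original count), WHAM is re-solved (warm-started from the full-data
    solution), and the standard deviation across replicates is reported
    per bin and per feature.  Deterministic given ``seed``.
    """
    full_inp = build_wham_input(windows, bin_width, temperature)
    full = wham_solve(full_inp, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    profiles = []
    feats = []
    for _ in range(n_subsets):
        counts = []
        for w in windows:
            a = w.samples.angles
            m = max(1, int(round(subset_fraction * a.size)))
            idx = rng.choice(a.size, size=m, replace=replace)
            edges, _ = _grid(bin_width)
            counts.append(np.histogram(wrap_angle(a[idx]), bins=edges)[0])
        inp = WhamInput(
            bin_centers=full_inp.bin_centers,
            counts=np.asarray(counts, dtype=float),
            centers=full_inp.centers,
            ks=full_inp.ks,
            temperature=full_inp.temperature,
        )
        try:
            prof = wham_solve(inp, tol=tol, max_iter=max_iter,
                              f_init=full.window_free_energies)
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"bootstrap subset skipped: {err}")
            continue
        profiles.append(prof.free_energy)
        feats.append(pmf_features(prof.angles, prof.free_energy))
    if len(profiles) < 3:
        raise RuntimeError("fewer than 3 usable bootstrap subsets")
    profiles = np.asarray(profiles)
    per_bin = profiles.std(axis=0, ddof=1)
    feature_errors = {}
    for name in ("delta_g", "barrier", "ts_angle", "trans_angle", "cis_angle"):
        values = np.array([getattr(ft, name) for ft in feats])
        if name.endswith("angle"):
            # angles live on the circle; spread via minimum-image deviations
            values = wrap_angle(values - values[0])
        feature_errors[name] = float(np.std(values, ddof=1))
    return per_bin, feature_errors, feats
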