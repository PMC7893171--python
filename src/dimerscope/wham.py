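"""Multi-restraint umbrella sampling unbiasing (binless WHAM).

The umbrella windows restrain up to three coordinates simultaneously:
the protomer separation d (harmonic, kJ/mol/nm^2) and the two
orientation dihedrals phi1 and phi3 (harmonic on the wrapped angle
difference, kJ/mol/deg^2 by default). Because the bias depends on three
coordinates while the free-energy axis is one, the unbiasing is done in
the binless (per-sample bias) formulation: the self-consistent window
free energies

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_j N_j exp(f_j - u_j(x_n))

are solved over all pooled samples, with u = bias/kT, and each sample
receives the weight w_n ~ 1 / sum_j N_j exp(f_j - u_j(x_n)). The
potential of mean force along d is then the weighted histogram
F(d) = -kT ln(p(d)/dd), offset so its minimum is zero. A conventional
binned distance-only WHAM is provided for cross-checking.

The nonlinear system is solved by damped self-consistent iterations
accelerated with Newton steps on the equivalent convex objective
(whose Hessian is only n_windows x n_windows); fixing f_1 = 0 makes
the solution unique and the solver deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .geometry import wrap_angle

__all__ = [
    "RestraintSpec",
    "UmbrellaWindow",
    "WhamResult",
    "PMFProfile",
    "ContactProfile",
    "bias_energy",
    "wham",
    "binned_wham_distance",
    "pmf_profile",
    "bootstrap_pmf",
    "convergence_blocks",
    "dissociation_dG",
    "unbiased_observable_profile",
]


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic restraints on (d, phi1, phi3); any subset may be active.

    Distance: U = 1/2 k_d (d - d0)^2 with k_d in kJ/mol/nm^2.
    Dihedrals: U = 1/2 k_phi (dphi)^2 with dphi wrapped into
    (-180, 180] degrees before squaring; k_phi in kJ/mol/deg^2 unless
    ``angle_unit`` is "rad".
    """

    d0: float | None = None
    k_d: float = 0.0
    phi1_0: float | None = None
    k_phi1: float = 0.0
    phi3_0: float | None = None
    k_phi3: float = 0.0
    angle_unit: str = "deg"
    offset: float = 0.0   # constant added to the bias (gauge freedom)

    def __post_init__(self):
        for k in (self.k_d, self.k_phi1, self.k_phi3):
            if k < 0:
                raise ValueError("force constants must be >= 0")
        if self.angle_unit not in ("deg", "rad"):
            raise ValueError("angle_unit must be 'deg' or 'rad'")

    def _k_phi_deg(self, k: float) -> float:
        # convert kJ/mol/rad^2 -> kJ/mol/deg^2 if needed
        if self.angle_unit == "rad":
            return k * (np.pi / 180.0) ** 2
        return k

    def energy(self, d, phi1=None, phi3=None) -> np.ndarray:
        """Total bias energy (kJ/mol); vectorized over samples."""
        u = np.full_like(np.asarray(d, dtype=float), self.offset)
        if self.k_d > 0:
            if self.d0 is None:
                raise ValueError("k_d set but d0 missing")
            u = u + 0.5 * self.k_d * (np.asarray(d, float) - self.d0) ** 2
        if self.k_phi1 > 0:
            if self.phi1_0 is None or phi1 is None:
                raise ValueError("phi1 restraint requires phi1 samples and center")
            dphi = wrap_angle(np.asarray(phi1, float) - self.phi1_0)
            u = u + 0.5 * self._k_phi_deg(self.k_phi1) * dphi**2
        if self.k_phi3 > 0:
            if self.phi3_0 is None or phi3 is None:
                raise ValueError("phi3 restraint requires phi3 samples and center")
            dphi = wrap_angle(np.asarray(phi3, float) - self.phi3_0)
            u = u + 0.5 * self._k_phi_deg(self.k_phi3) * dphi**2
        return u


def bias_energy(sample, restraints: RestraintSpec) -> float:
    """Bias energy of a single (d, phi1, phi3) sample in kJ/mol."""
    d, phi1, phi3 = sample
    return float(restraints.energy(np.asarray([d]), np.asarray([phi1]),
                                   np.asarray([phi3]))[0])


@dataclass
class UmbrellaWindow:
    """One umbrella window: restraint plus per-frame samples."""

    restraint: RestraintSpec
    d: np.ndarray
    phi1: np.ndarray | None = None
    phi3: np.ndarray | None = None
    time: np.ndarray | None = None          # ns
    observable: np.ndarray | None = None    # e.g. residue contact count
    equilibration_discard: float = 0.0      # fraction of initial samples

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        for name in ("phi1", "phi3", "time", "observable"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.d.shape:
                    raise ValueError(f"{name} shape {v.shape} != d shape {self.d.shape}")
                setattr(self, name, v)
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite d samples")
        if not 0.0 <= self.equilibration_discard < 1.0:
            raise ValueError("equilibration_discard must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.d.size

    def equilibrated(self) -> "UmbrellaWindow":
        """Drop the initial ``equilibration_discard`` fraction of samples."""
        k = int(np.floor(self.equilibration_discard * self.n_samples))
        if self.n_samples - k < 1:
            raise ValueError("no samples left after equilibration discard")
        if k == 0:
            return self
        return replace(
            self,
            d=self.d[k:],
            phi1=None if self.phi1 is None else self.phi1[k:],
            phi3=None if self.phi3 is None else self.phi3[k:],
            time=None if self.time is None else self.time[k:],
            observable=None if self.observable is None else self.observable[k:],
            equilibration_discard=0.0,
        )


@dataclass
class WhamResult:
    """Pooled unbiased sample weights and window free energies."""

    weights: np.ndarray          # normalized, one per pooled sample
    f: np.ndarray                # window free energies, kT units, f[0] = 0
    d: np.ndarray                # pooled distance samples
    window_index: np.ndarray     # which window each pooled sample came from
    time: np.ndarray | None
    observable: np.ndarray | None
    temperature: float
    n_iter: int
    residual: float


def _pool(windows, discard=None):
    wins = []
    for w in windows:
        if discard is not None:
            w = replace(w, equilibration_discard=discard)
        w = w.equilibrated()
        if w.n_samples < 1:
            raise ValueError("empty window after equilibration discard")
        wins.append(w)
    d = np.concatenate([w.d for w in wins])
    idx = np.concatenate([np.full(w.n_samples, i) for i, w in enumerate(wins)])
    phi1 = [w.phi1 for w in wins]
    phi3 = [w.phi3 for w in wins]
    phi1 = None if any(p is None for p in phi1) else np.concatenate(phi1)
    phi3 = None if any(p is None for p in phi3) else np.concatenate(phi3)
    times = [w.time for w in wins]
    times = None if any(t is None for t in times) else np.concatenate(times)
    obs = [w.observable for w in wins]
    obs = None if any(o is None for o in obs) else np.concatenate(obs)
    return wins, d, phi1, phi3, times, obs, idx


def _check_overlap(wins):
    """Warn when adjacent windows (by d0) share no sampled d-range."""
    order = sorted(range(len(wins)),
                   key=lambda i: np.inf if wins[i].restraint.d0 is None
                   else wins[i].restraint.d0)
    for a, b in zip(order[:-1], order[1:]):
        lo_a, hi_a = wins[a].d.min(), wins[a].d.max()
        lo_b, hi_b = wins[b].d.min(), wins[b].d.max()
        if hi_a < lo_b or hi_b < lo_a:
            warnings.warn(
                f"umbrella windows {a} and {b} share no sampled d-range; "
                "the PMF may be disconnected there",
                RuntimeWarning,
                stacklevel=3,
            )


def wham(windows, temperature: float = 310.0, tol: float = 1e-10,
         max_iter: int = 100_000, discard: float | None = None,
         f_init=None) -> WhamResult:
    """Solve the binless multi-restraint WHAM equations.

    ``tol`` is the self-consistency threshold on max|delta f_i| in kT.
    ``discard`` overrides every window's equilibration fraction;
    ``f_init`` warm-starts the window free energies (kT units).
    Deterministic given the inputs.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("at least one window required")
    wins, d, phi1, phi3, times, obs, idx = _pool(windows, discard)
    _check_overlap(wins)
    kbt = kt(temperature)
    n_win = len(wins)
    n_counts = np.array([w.n_samples for w in wins], dtype=float)
    # reduced bias u[i, n] of every pooled sample in every window's potential
    u = np.empty((n_win, d.size))
    for i, w in enumerate(wins):
        u[i] = w.restraint.energy(d, phi1, phi3) / kbt
    log_n = np.log(n_counts)

    def neg_log_denom(f):
        # -log sum_j N_j exp(f_j - u_jn) for each sample
        return -logsumexp(log_n[:, None] + f[:, None] - u, axis=0)

    if n_win > 1:
        f = np.zeros(n_win) if f_init is None else np.asarray(f_init, float).copy()
        f = f - f[0]
        # damped self-consistent warm-up toward the fixed point
        for _ in range(20):
            log_w = neg_log_denom(f)
            f_new = -logsumexp(-u + log_w[None, :], axis=1)
            f_new = f_new - f_new[0]
            if np.max(np.abs(f_new - f)) < 1e-12:
                f = f_new
                break
            f = 0.8 * f_new + 0.2 * f
            f = f - f[0]
        # Newton refinement: the Hessian is only n_win x n_win and the
        # objective convex, so a few steps reach machine precision
        for _ in range(50):
            log_den = -neg_log_denom(f)
            p = np.exp(log_n[:, None] + f[:, None] - u - log_den[None, :])
            grad = p.sum(axis=1) - n_counts
            hess = np.diag(p.sum(axis=1)) - p @ p.T
            # remove the additive-constant null direction by pinning f_0
            try:
                step = np.linalg.solve(hess[1:, 1:], -grad[1:])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            step = np.clip(step, -2.0, 2.0)
            f = f + np.concatenate([[0.0], step])
            f = f - f[0]
            if np.max(np.abs(step)) < 1e-13:
                break
    else:
        f = np.zeros(1)

    # damped self-consistent polish to the requested tolerance
    residual = np.inf
    n_iter = 0
    damping = 0.8
    while n_iter < max_iter:
        log_w = neg_log_denom(f)
        f_new = -logsumexp(-u + log_w[None, :], axis=1)
        f_new = f_new - f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = damping * f_new + (1.0 - damping) * f
        f = f - f[0]
        n_iter += 1
        if residual < tol:
            break
    if residual >= tol:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kT > tol {tol:.1e})"
        )
    log_w = neg_log_denom(f)
    log_w = log_w - logsumexp(log_w)
    return WhamResult(
        weights=np.exp(log_w), f=f, d=d, window_index=idx, time=times,
        observable=obs, temperature=temperature, n_iter=n_iter,
        residual=residual,
    )


def binned_wham_distance(windows, temperature: float = 310.0,
                         bin_width: float = 0.02, tol: float = 1e-10,
                         max_iter: int = 100_000):
    """Classic binned, distance-only WHAM (cross-check implementation).

    Only the distance restraint of each window is honoured; use on data
    whose bias depends on d alone. Returns (bin_centers, F) with the
    minimum-offset convention.
    """
    wins = [w.equilibrated() for w in windows]
    kbt = kt(temperature)
    d_all = np.concatenate([w.d for w in wins])
    edges = np.arange(d_all.min(), d_all.max() + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.array([np.histogram(w.d, bins=edges)[0] for w in wins], dtype=float)
    n_counts = hist.sum(axis=1)
    u = np.array([w.restraint.energy(centers) / kbt for w in wins])
    f = np.zeros(len(wins))
    total = hist.sum(axis=0)
    for it in range(max_iter):
        denom = np.einsum("i,ib->b", n_counts, np.exp(f[:, None] - u))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        f_new = -np.log(np.einsum("ib,b->i", np.exp(-u), p))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    denom = np.einsum("i,ib->b", n_counts, np.exp(f[:, None] - u))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, total / denom, np.nan)
        fe = -kbt * np.log(p)
    fe -= np.nanmin(fe)
    return centers, fe


@dataclass
class PMFProfile:
    """Binned free energy along separation with bootstrap errors."""

    bin_centers: np.ndarray
    free_energy: np.ndarray       # kJ/mol, NaN in empty bins
    se: np.ndarray | None         # kJ/mol bootstrap standard errors
    temperature: float
    offset: str                   # "min" or "none"
    f_windows: np.ndarray         # window free energies (kT)
    counts: np.ndarray            # raw samples per bin
    n_eff: np.ndarray             # Kish effective sample count per bin
    bin_width: float

    @property
    def d_min(self) -> float:
        """Bin center of the global free-energy minimum."""
        i = np.nanargmin(self.free_energy)
        return float(self.bin_centers[i])

    def empty_interior_bins(self) -> np.ndarray:
        sampled = np.flatnonzero(self.counts > 0)
        if sampled.size == 0:
            return np.array([], dtype=int)
        inner = np.arange(sampled[0], sampled[-1] + 1)
        return inner[self.counts[inner] == 0]


def _bin_sums(d, edges, weights=None):
    """Per-bin sums with np.histogram bin semantics.

    Direct bincount accumulation: numpy's weighted histogram goes
    through a cumulative sum, which silently cancels bins whose total
    weight is ~1e-16 of the pooled weight — exactly the regime of a
    PMF plateau 20 kT above the well.
    """
    idx = np.searchsorted(edges, d, side="right") - 1
    idx = np.where(d == edges[-1], edges.size - 2, idx)
    valid = (idx >= 0) & (idx <= edges.size - 2)
    return np.bincount(idx[valid],
                       weights=None if weights is None else weights[valid],
                       minlength=edges.size - 1)


def pmf_profile(result: WhamResult, bin_width: float = 0.1,
                offset: str = "min", d_range=None) -> PMFProfile:
    """Weighted-histogram free energy F(d) = -kT ln(p(d)/dd)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = result.d
    w = result.weights
    lo, hi = (d.min(), d.max()) if d_range is None else d_range
    edges = np.arange(lo, hi + bin_width * (1 - 1e-12), bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts = _bin_sums(d, edges)
    if counts.max() == d.size:
        raise ValueError("degenerate axis: all samples fall in one bin")
    p = _bin_sums(d, edges, w)
    wsq = _bin_sums(d, edges, w**2)
    with np.errstate(divide="ignore"):
        n_eff = np.where(wsq > 0, p**2 / np.where(wsq > 0, wsq, 1.0), 0.0)
    kbt = kt(result.temperature)
    with np.errstate(divide="ignore"):
        fe = np.where(p > 0, -kbt * np.log(p / bin_width), np.nan)
    if offset == "min":
        fe = fe - np.nanmin(fe)
    elif offset != "none":
        raise ValueError("offset must be 'min' or 'none'")
    profile = PMFProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]), free_energy=fe, se=None,
        temperature=result.temperature, offset=offset, f_windows=result.f,
        counts=counts, n_eff=n_eff, bin_width=bin_width,
    )
    empty = profile.empty_interior_bins()
    if empty.size:
        warnings.warn(
            f"{empty.size} empty interior bin(s) in the PMF; not interpolated",
            RuntimeWarning,
            stacklevel=2,
        )
    return profile


def _resample_windows(windows, rng):
    out = []
    for w in windows:
        w = w.equilibrated()
        sel = rng.integers(0, w.n_samples, size=w.n_samples)
        sel.sort()
        out.append(replace(
            w,
            d=w.d[sel],
            phi1=None if w.phi1 is None else w.phi1[sel],
            phi3=None if w.phi3 is None else w.phi3[sel],
            time=None if w.time is None else w.time[sel],
            observable=None if w.observable is None else w.observable[sel],
        ))
    return out


def bootstrap_pmf(windows, n_boot: int = 10, seed: int = 0,
                  temperature: float = 310.0, bin_width: float = 0.1,
                  tol: float = 1e-8, discard: float | None = None):
    """Bootstrap standard errors of the PMF by resampling frames
    within each window; returns (PMFProfile with se, replicate matrix).

    The default of 10 replicates follows the error analysis protocol of
    the study this package reproduces; seed-deterministic.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    windows = [w if discard is None else replace(w, equilibration_discard=discard)
               for w in windows]
    base = wham(windows, temperature=temperature, tol=tol)
    d_range = (base.d.min(), base.d.max())
    profile = pmf_profile(base, bin_width=bin_width, d_range=d_range)
    rng = np.random.default_rng(seed)
    reps = np.full((n_boot, profile.bin_centers.size), np.nan)
    for b in range(n_boot):
        rewin = _resample_windows(windows, rng)
        res = wham(rewin, temperature=temperature, tol=tol, f_init=base.f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof_b = pmf_profile(res, bin_width=bin_width, d_range=d_range)
        reps[b, :prof_b.free_energy.size] = prof_b.free_energy
    profile.se = np.nanstd(reps, axis=0, ddof=1)
    return profile, reps


def convergence_blocks(windows, block_length: float, temperature: float = 310.0,
                       bin_width: float = 0.1, threshold: float = 2.0,
                       tol: float = 1e-8):
    """PMFs over contiguous time blocks plus a convergence verdict.

    Samples must carry timestamps. Returns (profiles, max_dev, converged)
    where max_dev is the largest per-bin |difference| between the last
    two block profiles (kJ/mol) and converged is True when it is below
    ``threshold``.
    """
    windows = [w.equilibrated() for w in windows]
    if any(w.time is None for w in windows):
        raise ValueError("convergence_blocks requires per-sample timestamps")
    t_min = min(w.time.min() for w in windows)
    t_max = max(w.time.max() for w in windows)
    if block_length > (t_max - t_min) * (1 + 1e-6) or block_length <= 0:
        raise ValueError(
            f"block_length {block_length} incompatible with data span "
            f"[{t_min}, {t_max}]"
        )
    edges = np.arange(t_min, t_max + block_length, block_length)
    d_lo = min(w.d.min() for w in windows)
    d_hi = max(w.d.max() for w in windows)
    profiles = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        block = []
        for w in windows:
            sel = (w.time >= lo) & (w.time < hi) if hi < t_max else \
                  (w.time >= lo) & (w.time <= hi)
            if sel.sum() == 0:
                continue
            block.append(replace(
                w, d=w.d[sel],
                phi1=None if w.phi1 is None else w.phi1[sel],
                phi3=None if w.phi3 is None else w.phi3[sel],
                time=w.time[sel],
                observable=None if w.observable is None else w.observable[sel],
            ))
        if not block:
            continue
        res = wham(block, temperature=temperature, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            profiles.append(pmf_profile(res, bin_width=bin_width,
                                        d_range=(d_lo, d_hi)))
    if len(profiles) < 2:
        return profiles, 0.0, True
    a, b = profiles[-2].free_energy, profiles[-1].free_energy
    both = np.isfinite(a) & np.isfinite(b)
    max_dev = float(np.max(np.abs(a[both] - b[both]))) if both.any() else np.inf
    return profiles, max_dev, max_dev < threshold


def dissociation_dG(profile: PMFProfile, plateau_range) -> tuple[float, float]:
    """Free energy of dissociation from the PMF plateau.

    Returns (dG, flatness): dG is the mean free energy over
    ``plateau_range`` minus the global-minimum value (zero under the
    "min" offset); flatness is max - min over the plateau, a diagnostic
    for profiles lacking a true asymptote.
    """
    lo, hi = plateau_range
    sel = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) \
        & np.isfinite(profile.free_energy)
    if not sel.any():
        raise ValueError(f"plateau range [{lo}, {hi}] is unsampled")
    plateau = profile.free_energy[sel]
    f_min = np.nanmin(profile.free_energy)
    dg = float(plateau.mean() - f_min)
    flatness = float(plateau.max() - plateau.min())
    if flatness > 0.25 * max(abs(dg), 1.0):
        warnings.warn(
            f"plateau is not flat (spread {flatness:.2f} kJ/mol); "
            "the dissociation free energy is ill-defined",
            RuntimeWarning,
            stacklevel=2,
        )
    return dg, flatness


@dataclass
class ContactProfile:
    """Bias-corrected mean observable vs distance from the PMF minimum."""

    bin_centers: np.ndarray       # of (d - d_min), nm
    mean: np.ndarray              # weighted mean observable per bin
    se: np.ndarray | None
    d_min: float
    bin_width: float


def unbiased_observable_profile(result: WhamResult, bin_width: float = 0.1,
                                reference: float | None = None,
                                n_boot: int = 10, seed: int = 0,
                                windows=None, temperature: float = 310.0):
    """Weighted (unbiased) mean of a per-sample observable in distance
    bins relative to the PMF minimum.

    ``reference`` defaults to the distance of the PMF global minimum
    computed from ``result`` at the same bin width. Bootstrap errors
    (resampling frames within windows, rerunning the unbiasing) are
    produced when the original ``windows`` are supplied.
    """
    if result.observable is None:
        raise ValueError("windows carry no per-sample observable")
    if reference is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reference = pmf_profile(result, bin_width=bin_width).d_min
    rel = result.d - reference
    edges = np.arange(rel.min(), rel.max() + bin_width * (1 - 1e-12), bin_width)
    if edges.size < 2:
        edges = np.array([rel.min(), rel.min() + bin_width])
    centers = 0.5 * (edges[:-1] + edges[1:])

    def profile_of(res, rel_d):
        wsum = _bin_sums(rel_d, edges, res.weights)
        csum = _bin_sums(rel_d, edges, res.weights * res.observable)
        with np.errstate(invalid="ignore"):
            return np.where(wsum > 0, csum / np.where(wsum > 0, wsum, 1.0), np.nan)

    mean = profile_of(result, rel)
    se = None
    if windows is not None and n_boot >= 2:
        rng = np.random.default_rng(seed)
        reps = np.full((n_boot, centers.size), np.nan)
        for b in range(n_boot):
            rewin = _resample_windows(windows, rng)
            res_b = wham(rewin, temperature=temperature, tol=1e-8,
                         f_init=result.f)
            reps[b] = profile_of(res_b, res_b.d - reference)
        se = np.nanstd(reps, axis=0, ddof=1)
    return ContactProfile(bin_centers=centers, mean=mean, se=se,
                          d_min=float(reference), bin_width=bin_width)


# ------------------------------------------------------------- window I/O

def write_window_dir(windows, path, temperature: float = 310.0,
                     equilibration_discard: float = 0.0,
                     fmt: str = "tsv") -> None:
    """Write windows as a directory: manifest.yaml + per-window samples.

    ``fmt="tsv"`` stores plain tables (column order: time d phi1 phi3
    [observable]); ``fmt="npz"`` stores the same arrays in compressed
    numpy containers for large runs.
    """
    import os

    import yaml

    if fmt not in ("tsv", "npz"):
        raise ValueError("fmt must be 'tsv' or 'npz'")
    os.makedirs(path, exist_ok=True)
    manifest = {
        "temperature": float(temperature),
        "equilibration_discard": float(equilibration_discard),
        "windows": [],
    }
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.{fmt}"
        r = w.restraint
        entry = {"file": fname, "angle_unit": r.angle_unit}
        for key in ("d0", "k_d", "phi1_0", "k_phi1", "phi3_0", "k_phi3"):
            val = getattr(r, key)
            if val is not None:
                entry[key] = float(val)
        manifest["windows"].append(entry)
        arrays = {"time": np.zeros_like(w.d) if w.time is None else w.time,
                  "d": w.d}
        for name in ("phi1", "phi3", "observable"):
            v = getattr(w, name)
            if v is not None:
                arrays[name] = v
        if fmt == "npz":
            np.savez_compressed(os.path.join(path, fname), **arrays)
        else:
            header = "\t".join(arrays)
            with open(os.path.join(path, fname), "w") as fh:
                fh.write(f"# {header}\n")
                np.savetxt(fh, np.column_stack(list(arrays.values())),
                           fmt="%.8g", delimiter="\t")
    with open(os.path.join(path, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_window_dir(path):
    """Read a window directory; returns (windows, temperature).

    Restraint force constants are mandatory in the manifest — there are
    no hidden defaults for them.
    """
    import os

    import yaml

    with open(os.path.join(path, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    temperature = float(manifest.get("temperature", 310.0))
    discard = float(manifest.get("equilibration_discard", 0.0))
    windows = []
    for i, entry in enumerate(manifest["windows"]):
        if "d0" in entry and "k_d" not in entry:
            raise ValueError(
                f"window {i}: restraint center d0 given without force "
                "constant k_d; force constants are mandatory"
            )
        restraint = RestraintSpec(
            d0=entry.get("d0"), k_d=float(entry.get("k_d", 0.0)),
            phi1_0=entry.get("phi1_0"), k_phi1=float(entry.get("k_phi1", 0.0)),
            phi3_0=entry.get("phi3_0"), k_phi3=float(entry.get("k_phi3", 0.0)),
            angle_unit=entry.get("angle_unit", "deg"),
        )
        fpath = os.path.join(path, entry["file"])
        if fpath.endswith(".npz"):
            with np.load(fpath) as npz:
                cols = {name: npz[name] for name in npz.files}
        else:
            with open(fpath) as fh:
                header = fh.readline().lstrip("#").split()
                data = np.loadtxt(fh, ndmin=2)
            cols = {name: data[:, k] for k, name in enumerate(header)}
        windows.append(UmbrellaWindow(
            restraint=restraint, d=cols["d"],
            phi1=cols.get("phi1"), phi3=cols.get("phi3"),
            time=cols.get("time"), observable=cols.get("observable"),
            equilibration_discard=discard,
        ))
    return windows, temperature
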