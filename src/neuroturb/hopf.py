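"""Hopf (Stuart-Landau) whole-brain model on an anatomy-constrained network.

Each region is a Stuart-Landau oscillator — the normal form of a supercritical
Hopf bifurcation — with bifurcation parameter ``a`` (noisy fixed point for
a < 0, limit cycle of radius sqrt(a) for a > 0) and intrinsic angular
frequency ``omega_j``.  Regions are diffusively coupled through an anatomical
matrix built from an exponential distance rule (EDR) with optional long-range
connectome exceptions, scaled by the global coupling ``G``:

    dx_j = [(a_j - x_j^2 - y_j^2) x_j - omega_j y_j
            + G * sum_k C_jk (x_k - x_j)] dt + sigma sqrt(dt) xi
    dy_j = [(a_j - x_j^2 - y_j^2) y_j + omega_j x_j
            + G * sum_k C_jk (y_k - y_j)] dt + sigma sqrt(dt) xi'

``G`` is fitted per group by matching the model's functional connectivity as
a function of Euclidean distance to the empirical curve (minimum mean squared
error over distance bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import welch

from .geometry import ParcelGeometry
from .turbulence import BoldTimeseries

DEFAULT_EDR_DECAY = 0.18  # per mm; fitted primate EDR rate of the framework


@dataclass(frozen=True)
class CouplingMatrix:
    """Anatomical coupling ``C_jk``: EDR kernel with long-range exceptions."""

    C: np.ndarray
    edr_decay: float
    longrange_source: str = "synthetic"  # {synthetic, file, none}

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if np.abs(np.diagonal(C)).max(initial=0.0) > 0:
            raise ValueError("coupling matrix must have a zero diagonal")
        if C.min(initial=0.0) < 0 or C.max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("coupling weights must lie in [0, 1]")
        object.__setattr__(self, "C", C)

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class HopfParams:
    """Parameters of the coupled Stuart-Landau network.

    ``a`` may be a scalar (shared bifurcation parameter) or a per-region
    vector, which is how in-silico perturbations shift individual regions.
    """

    omegas: np.ndarray          # intrinsic angular frequencies, rad/s
    G: float                    # global coupling >= 0
    duration: float             # simulated seconds (excluding transient)
    a: float | np.ndarray = -0.02
    noise_sigma: float = 0.01
    dt: float = 0.1             # integration step, s
    seed: int = 0

    def __post_init__(self) -> None:
        omegas = np.atleast_1d(np.asarray(self.omegas, dtype=float))
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        object.__setattr__(self, "omegas", omegas)


@dataclass(frozen=True)
class FitResult:
    """Outcome of the global-coupling sweep."""

    g_grid: np.ndarray
    error_curve: np.ndarray
    g_opt: float
    n_reps_per_g: int

    def __post_init__(self) -> None:
        g_grid = np.asarray(self.g_grid, dtype=float)
        err = np.asarray(self.error_curve, dtype=float)
        if g_grid.shape != err.shape:
            raise ValueError("g_grid and error_curve must align")
        if not np.any(np.isclose(g_grid, self.g_opt)):
            raise ValueError("g_opt must be an element of g_grid")
        finite = err[np.isfinite(err)]
        if finite.size and not np.isclose(
            err[int(np.argmin(err))], finite.min()
        ):
            raise ValueError("g_opt must attain the minimum error")
        object.__setattr__(self, "g_grid", g_grid)
        object.__setattr__(self, "error_curve", err)


def build_coupling(
    geom: ParcelGeometry,
    connectome: np.ndarray | None = None,
    edr_decay: float = DEFAULT_EDR_DECAY,
) -> CouplingMatrix:
    """EDR kernel ``exp(-edr_decay * d_jk)`` with connectome exceptions on top.

    A supplied connectome (e.g. from diffusion MRI) is normalized to a maximum
    of 1 and merged by elementwise maximum — long-range fibers override the
    exponential decay where they are stronger.
    """
    if edr_decay <= 0:
        raise ValueError("edr_decay must be positive")
    C = np.exp(-edr_decay * geom.dist)
    np.fill_diagonal(C, 0.0)
    source = "none"
    if connectome is not None:
        sc = np.asarray(connectome, dtype=float)
        if sc.shape != C.shape:
            raise ValueError("connectome shape must match the geometry")
        if not np.allclose(sc, sc.T, atol=1e-9):
            raise ValueError("connectome must be symmetric")
        if sc.min() < 0:
            raise ValueError("connectome must be non-negative")
        if sc.max() > 0:
            sc = sc / sc.max()
        sc = sc.copy()
        np.fill_diagonal(sc, 0.0)
        C = np.maximum(C, sc)
        source = "file"
    return CouplingMatrix(C=C, edr_decay=edr_decay, longrange_source=source)


def estimate_frequencies(
    bold: BoldTimeseries, band: tuple[float, float] = (0.008, 0.08)
) -> np.ndarray:
    """Per-region intrinsic angular frequencies from the averaged periodogram.

    Welch power spectra are evaluated per region; ``omega_j = 2 pi f_peak``
    with the peak restricted to ``band`` (clipped at Nyquist).
    """
    if bold.n_volumes < 64:
        raise ValueError("need at least 64 volumes for a stable spectral peak")
    fs = 1.0 / bold.tr
    freqs, power = welch(bold.data, fs=fs, nperseg=min(bold.n_volumes, 128), axis=1)
    lo, hi = band
    hi = min(hi, fs / 2.0)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} Hz is empty below Nyquist {fs / 2:g} Hz")
    banded = power[:, mask]
    peak = freqs[mask][np.argmax(banded, axis=1)]
    return 2.0 * np.pi * peak


def simulate(
    params: HopfParams,
    coupling: CouplingMatrix,
    out_tr: float,
    *,
    transient: float = 20.0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> BoldTimeseries:
    """Euler-Maruyama integration of the coupled Stuart-Landau network.

    The ``x`` component is recorded every ``out_tr`` seconds after discarding
    the initial ``transient`` seconds.  With a fixed seed the output is fully
    deterministic.

    Raises
    ------
    RuntimeError
        On divergence (any ``|x| > 1e6``), reporting the failing step.
    """
    n = coupling.n_regions
    omegas = np.broadcast_to(params.omegas, (n,)).astype(float)
    a = np.broadcast_to(np.asarray(params.a, dtype=float), (n,)).copy()
    dt = params.dt
    sample_every = out_tr / dt
    if abs(sample_every - round(sample_every)) > 1e-9:
        raise ValueError("out_tr must be an integer multiple of dt")
    sample_every = int(round(sample_every))
    n_transient = int(round(transient / dt))
    n_record = int(round(params.duration / out_tr))
    n_steps = n_transient + n_record * sample_every

    rng = np.random.default_rng(params.seed)
    if init is None:
        x = 0.1 * rng.standard_normal(n)
        y = 0.1 * rng.standard_normal(n)
    else:
        x = np.asarray(init[0], dtype=float).copy()
        y = np.asarray(init[1], dtype=float).copy()

    S = params.G * coupling.C
    deg = S.sum(axis=1)
    sig = params.noise_sigma * np.sqrt(dt)

    out = np.empty((n, n_record))
    rec = 0
    for step in range(1, n_steps + 1):
        r2 = x * x + y * y
        shrink = a - r2
        dx = (shrink * x - omegas * y + S @ x - deg * x) * dt
        dy = (shrink * y + omegas * x + S @ y - deg * y) * dt
        if sig > 0:
            noise = rng.standard_normal((2, n))
            dx += sig * noise[0]
            dy += sig * noise[1]
        x = x + dx
        y = y + dy
        if np.max(np.abs(x)) > 1e6:
            raise RuntimeError(
                f"simulation diverged at step {step} (t = {step * dt:.1f} s)"
            )
        if step > n_transient and (step - n_transient) % sample_every == 0:
            out[:, rec] = x
            rec += 1
    return BoldTimeseries(data=out[:, :rec], tr=out_tr)


def fc_vs_distance(
    bold: BoldTimeseries,
    geom: ParcelGeometry,
    bin_mm: float = 5.0,
    fit_range: tuple[float, float] = (5.0, 80.0),
    min_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean pairwise Pearson FC in Euclidean-distance bins.

    Returns ``(bin_centers, mean_correlations)`` for the populated bins inside
    ``fit_range``; empty bins are reported via a warning.
    """
    if geom.n_regions != bold.n_regions:
        raise ValueError("geometry / series size mismatch")
    corr = np.corrcoef(bold.data)
    iu = np.triu_indices(bold.n_regions, k=1)
    c, d = corr[iu], geom.dist[iu]
    keep = np.isfinite(c)
    c, d = c[keep], d[keep]

    r_min, r_max = fit_range
    edges = np.arange(r_min, r_max + bin_mm, bin_mm)
    centers, means, empty = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d >= lo) & (d < hi)
        if mask.any():
            centers.append(0.5 * (lo + hi))
            means.append(float(c[mask].mean()))
        else:
            empty.append(0.5 * (lo + hi))
    if empty:
        warnings.warn(f"empty distance bins at centers {empty}", stacklevel=2)
    if len(centers) < min_bins:
        raise ValueError(
            f"need >= {min_bins} populated distance bins in {fit_range}, "
            f"got {len(centers)}"
        )
    return np.asarray(centers), np.asarray(means)


def fit_G(
    empirical: list[BoldTimeseries],
    geom: ParcelGeometry,
    coupling: CouplingMatrix,
    params_template: HopfParams,
    g_grid: np.ndarray,
    n_reps: int = 5,
    *,
    out_tr: float = 2.0,
    bin_mm: float = 5.0,
    fit_range: tuple[float, float] = (5.0, 80.0),
) -> FitResult:
    """Sweep the global coupling and pick the FC-vs-distance optimum.

    The empirical target is the subject-averaged FC-vs-distance curve; for
    each ``G`` the model curve is averaged over ``n_reps`` seeds and scored by
    the mean squared difference across distance bins.  Ties break toward the
    smallest ``G`` (closer to subcritical).
    """
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.size == 0 or np.any(np.diff(g_grid) <= 0):
        raise ValueError("g_grid must be non-empty and strictly ascending")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not empirical:
        raise ValueError("need at least one empirical series")

    target = np.mean(
        [fc_vs_distance(ts, geom, bin_mm, fit_range)[1] for ts in empirical], axis=0
    )

    errors = np.full(g_grid.shape, np.inf)
    for gi, g in enumerate(g_grid):
        curves = []
        for rep in range(n_reps):
            seed = int(
                np.random.SeedSequence(
                    [int(params_template.seed), gi, rep]
                ).generate_state(1)[0]
                % 2**31
            )
            try:
                sim = simulate(
                    replace(params_template, G=float(g), seed=seed),
                    coupling,
                    out_tr,
                )
                curves.append(fc_vs_distance(sim, geom, bin_mm, fit_range)[1])
            except RuntimeError as exc:
                warnings.warn(f"G={g:g} rep {rep}: {exc}", stacklevel=2)
        if curves:
            model = np.mean(curves, axis=0)
            errors[gi] = float(np.mean((model - target) ** 2))
    if not np.any(np.isfinite(errors)):
        raise RuntimeError("every simulation failed across the whole G grid")
    g_opt = float(g_grid[int(np.argmin(errors))])  # argmin -> smallest G on ties
    return FitResult(g_grid=g_grid, error_curve=errors, g_opt=g_opt, n_reps_per_g=n_reps)
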