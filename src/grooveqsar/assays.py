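"""Binding-assay mathematics: tight-binding titrations, fluorescence
polarization, and cell doubling time.

The photoluminescence titration holds the ligand at a fixed total
concentration L (10 uM in the reference experiment) while dsDNA duplex is
added stepwise.  Because the dissociation constants of interest (tens to
hundreds of nM) lie far below L, ligand depletion is material and the
hyperbolic approximation fails; the exact 1:1 quadratic isotherm is used:

    [LD] = ((L + D + Kd) - sqrt((L + D + Kd)^2 - 4 L D)) / 2

Observed intensity is modelled as F = F0 + Fmax * [LD] / L.  Saturation
stoichiometry is read from two intersecting lines on the intensity versus
D/L molar-ratio plot: the initial-rise line fitted to sub-stoichiometric
points and the horizontal saturation plateau; a 1:1 binder breaks at 1.0.
Because the reference titration stops at the equivalence point, the
plateau level is taken from the fitted isotherm's asymptote F0 + Fmax
rather than from (nonexistent) post-saturation points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "FPMeasurement",
    "GrowthCounts",
    "bound_complex",
    "simulate_titration",
    "fit_titration",
    "fit_breakpoint",
    "fluorescence_polarization",
    "doubling_time",
]


@dataclass
class TitrationSeries:
    """Constant-ligand titration: intensity vs total dsDNA concentration."""

    ligand_total: float  # mol/L
    dna_total: np.ndarray  # mol/L, strictly increasing
    intensity: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.dna_total = np.asarray(self.dna_total, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.dna_total.shape != self.intensity.shape or self.dna_total.size < 4:
            raise ValueError("titration needs >=4 matched (dna, intensity) points")
        if np.any(self.dna_total < 0):
            raise ValueError("dna_total must be non-negative")
        if np.any(np.diff(self.dna_total) <= 0):
            raise ValueError("dna_total must be strictly increasing")
        if not (self.ligand_total > 0):
            raise ValueError("ligand_total must be positive")

    def ratio(self) -> np.ndarray:
        """dsDNA:ligand molar ratio axis."""
        return self.dna_total / self.ligand_total


@dataclass
class BindingFit:
    kd: float  # mol/L
    fmax: float
    f0: float
    saturation_ratio: float  # dsDNA:ligand at the breakpoint
    residual_sd: float

    def __post_init__(self) -> None:
        if not (self.kd > 0 and self.fmax > 0 and self.saturation_ratio > 0):
            raise ValueError("kd, fmax and saturation_ratio must be positive")


@dataclass
class FPMeasurement:
    """One fluorescence-polarization well: S, P intensities and G factor."""

    S: float
    P: float
    G: float = 1.0

    def __post_init__(self) -> None:
        if self.S < 0 or self.P < 0:
            raise ValueError("S and P intensities must be non-negative")

    @property
    def fp(self) -> float:
        return fluorescence_polarization(self.S, self.P, self.G)


@dataclass
class GrowthCounts:
    """Viable cell counts at 48 h and 72 h after seeding."""

    n_t48: float
    n_t72: float

    def __post_init__(self) -> None:
        if self.n_t48 <= 0 or self.n_t72 <= 0:
            raise ValueError("cell counts must be positive")

    @property
    def shrinking(self) -> bool:
        return self.n_t72 < self.n_t48

    @property
    def doubling_time(self) -> float:
        return doubling_time(self.n_t48, self.n_t72)


def bound_complex(L_total: float, D_total, kd: float):
    """Exact 1:1 complex concentration under ligand depletion.

    ``[LD] = ((L + D + Kd) - sqrt((L + D + Kd)^2 - 4 L D)) / 2``; the root
    is clipped into [0, min(L, D)] against rounding at the tight-binding
    limit.  ``D_total`` may be a scalar or array.
    """
    D = np.asarray(D_total, dtype=float)
    if L_total < 0 or np.any(D < 0):
        raise ValueError("concentrations must be non-negative")
    if not (kd > 0):
        raise ValueError("kd must be positive")
    b = L_total + D + kd
    disc = b * b - 4.0 * L_total * D
    ld = (b - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    ld = np.clip(ld, 0.0, np.minimum(L_total, D))
    return float(ld) if np.isscalar(D_total) else ld


def simulate_titration(
    L_total: float,
    dna_series,
    kd: float,
    fmax: float,
    f0: float,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> TitrationSeries:
    """Simulate intensity = f0 + fmax*[LD]/L with multiplicative noise.

    Noise is Gaussian with coefficient of variation ``noise_cv`` applied
    multiplicatively to each intensity; deterministic for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    D = np.asarray(dna_series, dtype=float)
    ld = bound_complex(L_total, D, kd)
    intensity = f0 + fmax * ld / L_total
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_cv * rng.standard_normal(D.shape))
    return TitrationSeries(ligand_total=L_total, dna_total=D, intensity=intensity)


def fit_breakpoint(x: np.ndarray, y: np.ndarray) -> float:
    """Knot of a rise-then-plateau two-segment piecewise-linear fit.

    The model ``y = a + b min(x, bp)`` (a rising segment meeting a flat
    plateau at ``bp``) is fit by least squares for each candidate knot on a
    grid over ``x``'s interior, then refined by bounded scalar minimization
    around the best grid cell.  Ties break toward the smaller knot.

    Note: when the data stop at or before the true saturation point the
    knot estimate is biased low by the isotherm's corner rounding (width
    ~ sqrt(Kd L)/L on the ratio axis); :func:`fit_titration` therefore
    reads the saturation stoichiometry from the asymptote intersection
    instead and uses this knot only to delimit the initial-rise region.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def sse(bp: float) -> float:
        design = np.column_stack([np.ones_like(x), np.minimum(x, bp)])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r)

    lo, hi = x[1], x[-1]
    if hi <= lo:
        raise ValueError("too few interior points for a breakpoint fit")
    grid = np.linspace(lo, hi, 201)
    sses = np.array([sse(b) for b in grid])
    i = int(np.argmin(sses))  # argmin takes the first minimum: smaller ratio wins ties
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(a, b), method="bounded")
    return float(res.x) if res.fun <= sses[i] else float(grid[i])


def fit_titration(series: TitrationSeries) -> BindingFit:
    """Fit (Kd, Fmax, F0) under the quadratic model and read the
    saturation stoichiometry.

    Kd is optimized in log10 space for conditioning.  The saturation
    stoichiometry is the D/L ratio at which the initial-rise line (least
    squares over the sub-stoichiometric points, delimited by the
    piecewise-linear knot) meets the saturation plateau ``F0 + Fmax`` of
    the fitted isotherm.  For a 1:1 binder this intersection sits at
    ``(L + Kd)/L ~ 1``; a binder consuming two ligands per duplex would
    read ~0.5.
    """
    y = series.intensity
    if np.allclose(y, y[0]):
        raise ValueError("all intensities equal; nothing to fit")
    if series.dna_total.max() < series.ligand_total * (1.0 - 1e-9):
        raise ValueError("series must reach at least stoichiometric dsDNA")
    L = series.ligand_total

    def model(D, log10_kd, fmax, f0):
        return f0 + fmax * bound_complex(L, D, 10.0 ** log10_kd) / L

    span = float(y.max() - y.min())
    p0 = (math.log10(L / 100.0), span, float(y.min()))
    try:
        popt, _ = optimize.curve_fit(
            model,
            series.dna_total,
            y,
            p0=p0,
            bounds=([math.log10(L) - 9.0, 1e-12, -np.inf], [math.log10(L) + 3.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"titration fit did not converge: {exc}") from exc
    log10_kd, fmax, f0 = popt
    resid = y - model(series.dna_total, *popt)

    x = series.ratio()
    knot = fit_breakpoint(x, y)
    rise = x <= 0.5 * knot
    if rise.sum() < 3:
        rise = x <= x[min(2, len(x) - 1)]
    design = np.column_stack([np.ones(int(rise.sum())), x[rise]])
    a_rise, b_rise = np.linalg.lstsq(design, y[rise], rcond=None)[0]
    if b_rise <= 0:
        raise RuntimeError("titration fit diagnostics: initial rise has non-positive slope")
    saturation_ratio = float((f0 + fmax - a_rise) / b_rise)

    return BindingFit(
        kd=10.0 ** log10_kd,
        fmax=float(fmax),
        f0=float(f0),
        saturation_ratio=saturation_ratio,
        residual_sd=float(np.std(resid, ddof=1)) if y.size > 1 else 0.0,
    )


def fluorescence_polarization(S: float, P: float, G: float = 1.0) -> float:
    """FP in millipolarization units: ``1000 (S - G P) / (S + G P)``."""
    denom = S + G * P
    if denom == 0:
        raise ValueError("S + G*P is zero; polarization undefined")
    return 1000.0 * (S - G * P) / denom


def doubling_time(n_t48: float, n_t72: float) -> float:
    """Doubling time in hours from counts at 48 h and 72 h.

    ``24 * ln(2) / ln(n_t72 / n_t48)``.  A shrinking population yields a
    negative value (flagged by :attr:`GrowthCounts.shrinking`); equal
    counts are an error since the formula diverges.
    """
    if n_t48 <= 0 or n_t72 <= 0:
        raise ValueError("cell counts must be positive")
    if n_t72 == n_t48:
        raise ValueError("no growth between 48 h and 72 h; doubling time undefined")
    return 24.0 * math.log(2.0) / math.log(n_t72 / n_t48)
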