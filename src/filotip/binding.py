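"""Single-site ligand-depletion (quadratic) binding model and Kd fitting.

Microscale-thermophoresis titrations keep the fluorescent partner at a fixed
concentration ``A0`` (20 nM by default in this workflow) while the unlabeled
ligand ``L0`` is serially diluted.  Because ``A0`` is not negligible relative
to Kd, the bound-complex concentration [AL] must be solved from the exact
mass-action quadratic rather than the hyperbolic approximation:

    [AL] = 1/2 * ((A0 + L0 + Kd) - sqrt((A0 + L0 + Kd)^2 - 4*A0*L0))

The measured signal is affine in the bound fraction,

    signal(L0) = F_free + (F_bound - F_free) * [AL] / A0,

and :func:`fit_kd` estimates (Kd, F_free, F_bound) by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._util import as_1d_float
from .errors import ArgumentError, DegenerateAmplitudeError, NoBindingError

KD_BOUNDS_M = (1e-12, 1.0)  # plausible molar range for the optimizer


@dataclass
class Titration:
    """A ligand titration: fixed fluorescent partner, varying ligand.

    Parameters
    ----------
    a0:
        Concentration of the fluorescent (labeled) partner, molar.
    l0:
        Total added ligand concentrations, molar (any order; order is kept).
    signal:
        Measured fluorescence (raw ratio or normalized) per ligand point.
    """

    a0: float
    l0: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.l0 = as_1d_float(self.l0, "l0", min_len=4)
        self.signal = as_1d_float(self.signal, "signal", min_len=4)
        if self.l0.size != self.signal.size:
            raise ArgumentError("l0 and signal must have equal length")
        if np.any(self.l0 < 0):
            raise ArgumentError("ligand concentrations must be >= 0")
        if not self.a0 > 0:
            raise ArgumentError("a0 must be > 0")


@dataclass
class BindingFit:
    """Result of the quadratic-depletion least-squares fit."""

    kd: float            # molar
    f_free: float
    f_bound: float
    residual_sse: float
    converged: bool
    n_points: int
    kd_ci: tuple[float, float] | None = None  # bootstrap 95% CI, molar


def complex_concentration(a0, l0, kd):
    """Bound-complex concentration [AL] from the mass-action quadratic.

    Uses the numerically stable form 2*a0*l0 / (b + sqrt(b^2 - 4*a0*l0))
    with b = a0 + l0 + kd, which avoids cancellation when a0*l0 << b^2.
    Accepts scalars or arrays for ``l0``.
    """
    a0 = float(a0)
    kd = float(kd)
    l0_arr = np.asarray(l0, dtype=float)
    if a0 <= 0 or kd <= 0 or np.any(l0_arr < 0):
        raise ArgumentError("require a0 > 0, kd > 0, l0 >= 0")
    b = a0 + l0_arr + kd
    disc = b * b - 4.0 * a0 * l0_arr
    disc = np.maximum(disc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        al = np.where(l0_arr > 0, 2.0 * a0 * l0_arr / (b + np.sqrt(disc)), 0.0)
    al = np.minimum(al, np.minimum(a0, l0_arr))
    return al if al.ndim else float(al)


def delta_fnorm(f1, f0):
    """Normalized MST signal: fluorescence after / before IR-laser heating."""
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ArgumentError("F0 must be > 0")
    out = np.asarray(f1, dtype=float) / f0
    return out if out.ndim else float(out)


def binding_signal(l0, a0, kd, f_free, f_bound):
    """Forward model: signal as an affine function of the bound fraction."""
    frac = complex_concentration(a0, l0, kd) / a0
    return f_free + (f_bound - f_free) * frac


def _linear_amplitudes(phi: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # For fixed Kd the model is linear in (f_free, f_bound): y = f_free*(1-phi) + f_bound*phi
    design = np.column_stack([1.0 - phi, phi])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_kd(
    titration: Titration,
    init: float | str = "auto",
    n_boot: int = 0,
    seed: int | None = None,
) -> BindingFit:
    """Estimate (Kd, F_free, F_bound) from a titration by least squares.

    ``init="auto"`` profiles the SSE over a log-spaced Kd grid (the model is
    linear in the two amplitudes for fixed Kd) and refines the best seed with
    a bounded trust-region solver on log10(Kd).  A flat titration — fitted
    amplitude below three times the residual noise — raises
    :class:`NoBindingError` rather than returning a meaningless Kd.

    With ``n_boot > 0`` a case-resampling bootstrap percentile 95% CI for Kd
    is attached.
    """
    l0, y, a0 = titration.l0, titration.signal, titration.a0
    if np.unique(l0).size < 4:
        raise ArgumentError("need at least 4 distinct ligand concentrations")

    def sse_at(log10_kd: float) -> tuple[float, float, float]:
        phi = complex_concentration(a0, l0, 10.0**log10_kd) / a0
        return _linear_amplitudes(phi, y)

    lo, hi = np.log10(KD_BOUNDS_M[0]), np.log10(KD_BOUNDS_M[1])
    if init == "auto":
        span = np.log10(max(l0.max(), a0)) - np.log10(max(l0[l0 > 0].min(), 1e-12))
        if span < 2:
            raise ArgumentError(
                "auto initialization needs ligand concentrations spanning "
                ">= 2 orders of magnitude"
            )
        grid = np.linspace(lo, hi, 61)
    else:
        if not KD_BOUNDS_M[0] <= float(init) <= KD_BOUNDS_M[1]:
            raise ArgumentError("init Kd outside bounds")
        grid = np.array([np.log10(float(init))])
    best = min(((sse_at(g)[2], g) for g in grid), key=lambda t: t[0])
    ff0, fb0, _ = sse_at(best[1])

    def residuals(theta):
        log_kd, ff, fb = theta
        return binding_signal(l0, a0, 10.0**log_kd, ff, fb) - y

    scale = max(np.ptp(y), np.max(np.abs(y)), 1.0)
    res = least_squares(
        residuals,
        x0=[best[1], ff0, fb0],
        bounds=([lo, -10 * scale, -10 * scale], [hi, 10 * scale, 10 * scale]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    log_kd, f_free, f_bound = res.x
    sse = float(res.fun @ res.fun)

    dof = max(l0.size - 3, 1)
    sigma = np.sqrt(sse / dof)
    # realized signal swing over the measured range, not the raw amplitude:
    # a boundary Kd can pair a tiny bound-fraction range with a huge |dF|
    phi = complex_concentration(a0, l0, 10.0**log_kd) / a0
    amplitude = abs(f_bound - f_free) * float(np.ptp(phi))
    if amplitude <= max(3.0 * sigma, 1e-9 * scale):
        raise NoBindingError(
            "titration signal is flat relative to its noise "
            f"(amplitude {amplitude:.3g}, residual sd {sigma:.3g}); no binding detected"
        )

    kd_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        kds = []
        for _ in range(int(n_boot)):
            idx = rng.integers(0, l0.size, l0.size)
            if np.unique(l0[idx]).size < 4:
                continue
            try:
                boot = fit_kd(Titration(a0, l0[idx], y[idx]), init=10.0**log_kd)
            except (NoBindingError, ArgumentError):
                continue
            kds.append(boot.kd)
        if kds:
            kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))

    return BindingFit(
        kd=float(10.0**log_kd),
        f_free=float(f_free),
        f_bound=float(f_bound),
        residual_sse=sse,
        converged=bool(res.success),
        n_points=int(l0.size),
        kd_ci=kd_ci,
    )


def pool_titrations(titrations: list[Titration]) -> Titration:
    """Concatenate replicate titrations into one point cloud for fitting.

    Pooling the raw points of independent replicates (rather than averaging
    per concentration) is the default aggregation for replicate experiments.
    """
    if not titrations:
        raise ArgumentError("no titrations to pool")
    a0s = {t.a0 for t in titrations}
    if len(a0s) != 1:
        raise ArgumentError("pooled titrations must share the same a0")
    return Titration(
        a0=titrations[0].a0,
        l0=np.concatenate([t.l0 for t in titrations]),
        signal=np.concatenate([t.signal for t in titrations]),
    )


def make_titration_signal(l0, a0, kd, f_free, f_bound):
    """Noiseless forward signal; exposed for generators and tests."""
    if f_free == f_bound:
        raise DegenerateAmplitudeError("F_free == F_bound gives a flat titration")
    return binding_signal(l0, a0, kd, f_free, f_bound)
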