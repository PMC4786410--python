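"""Small-angle scattering curve analysis.

Implements the standard dilute-solution toolbox: Guinier analysis, a
regularized indirect Fourier transform to the pair-distance distribution
P(r), molecular mass from the absolute-scale forward scattering

    M = I(0) N_A / (c (delta_rho vbar)^2),

the empirical broad-peak model

    I(q) = A / q^n + C / (1 + (|q - q0| xi)^m) + B,

multi-Gaussian peak fitting for ordered (e.g. liquid-crystalline-like)
phases, and the d-spacing conversion d = 2 pi / q.

Units: q in 1/Angstrom, I in 1/cm (absolute scale), lengths in Angstrom,
scattering length densities in 1/cm^2, concentration accepted in mg/mL and
converted internally to g/cm^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import integrate, signal

logger = logging.getLogger(__name__)

N_AVOGADRO = 6.02214076e23


@dataclass
class ScatteringCurve:
    """A 1-D scattering profile: q (1/A), I (1/cm), per-point sigma."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where provided")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.sigma if self.sigma is not None else np.ones_like(self.q)


@dataclass
class PairDistribution:
    """P(r) solution with its real-space invariants."""

    r: np.ndarray
    p: np.ndarray
    d_max: float
    r_g: float
    i0: float
    alpha: float = float("nan")


@dataclass
class MassInputs:
    """Inputs for the absolute-intensity mass determination.

    ``c_mg_ml`` in mg/mL; scattering length densities in cm^-2; ``vbar`` in
    cm^3/g.
    """

    c_mg_ml: float
    rho_prot: float
    rho_solv: float
    vbar: float = 0.73

    def __post_init__(self) -> None:
        if self.c_mg_ml <= 0 or self.vbar <= 0:
            raise ValueError("concentration and partial specific volume must be positive")

    @property
    def delta_rho(self) -> float:
        return self.rho_prot - self.rho_solv


@dataclass
class BroadPeakParams:
    """Fitted parameters of the empirical broad-peak model (with SDs)."""

    a: float
    n: float
    c: float
    q0: float
    xi: float
    m: float
    b: float
    a_sd: float = float("nan")
    n_sd: float = float("nan")
    c_sd: float = float("nan")
    q0_sd: float = float("nan")
    xi_sd: float = float("nan")
    m_sd: float = float("nan")
    b_sd: float = float("nan")

    @property
    def d0(self) -> float:
        """Correlation d-spacing of the peak, 2 pi / q0 (Angstrom)."""
        return d_spacing(self.q0)


def d_spacing(q: float) -> float:
    """Real-space correlation distance d = 2 pi / q (Angstrom for q in 1/A)."""
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * np.pi / q


def guinier_fit(
    curve: ScatteringCurve, q_rg_max: float = 1.3, min_points: int = 5
) -> dict:
    """Guinier analysis: ln I = ln I(0) - (R_g^2 / 3) q^2 at low q.

    The window q * R_g <= ``q_rg_max`` is iterated to self-consistency
    starting from the first ``min_points`` points.  Returns a dict with
    ``rg``, ``i0``, their SDs and the window used.  A non-decaying curve
    (non-negative slope) is an error.
    """
    if len(curve) < min_points:
        raise ValueError("too few points for a Guinier fit")
    mask = curve.i > 0
    q, i = curve.q[mask], curve.i[mask]
    n_window = min_points
    rg = None
    for _ in range(50):
        qw, iw = q[:n_window], i[:n_window]
        slope, intercept = np.polyfit(qw ** 2, np.log(iw), 1)
        if slope >= 0:
            raise ValueError("no Guinier decay: non-negative slope in ln I vs q^2")
        rg_new = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q * rg_new, q_rg_max))
        if n_new < min_points:
            n_new = min_points
        if rg is not None and n_new == n_window:
            break
        rg, n_window = rg_new, n_new
    qw, iw = q[:n_window], i[:n_window]
    x, y = qw ** 2, np.log(iw)
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    slope, intercept = coeffs
    if slope >= 0:
        raise ValueError("no Guinier decay: non-negative slope in ln I vs q^2")
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    slope_sd, intercept_sd = np.sqrt(np.diag(cov))
    return {
        "rg": rg,
        "rg_sd": float(1.5 * slope_sd / rg) if rg > 0 else float("nan"),
        "i0": i0,
        "i0_sd": float(i0 * intercept_sd),
        "n_points": int(n_window),
        "q_max": float(qw[-1]),
    }


def pr_transform(
    curve: ScatteringCurve,
    d_max: float,
    alpha: float | None = None,
    n_r: int = 101,
) -> PairDistribution:
    """Regularized indirect Fourier transform to the pair-distance
    distribution.

    The model is I(q) = 4 pi sum_j P(r_j) sinc(q r_j) dr on an ``n_r``-point
    r grid over [0, d_max], with the endpoint constraints P(0) = P(d_max) = 0
    imposed exactly and a second-derivative smoothness penalty of weight
    ``alpha``.  When ``alpha`` is None it is chosen by an L-curve criterion
    (the corner of log residual norm vs log penalty norm over a log-spaced
    scan).  Negative excursions of P(r) are permitted but logged.

    Real-space invariants follow from the solution:
    R_g^2 = int r^2 P dr / (2 int P dr), I(0) = 4 pi int P dr.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if d_max < np.pi / curve.q[-1]:
        logger.warning("d_max %.1f below the resolution limit pi/q_max = %.1f",
                       d_max, np.pi / curve.q[-1])
    r = np.linspace(0.0, d_max, n_r)
    dr = r[1] - r[0]
    qr = np.outer(curve.q, r)
    kernel = 4.0 * np.pi * dr * np.sinc(qr / np.pi)  # np.sinc is sin(pi x)/(pi x)
    # endpoint constraints: drop the first and last basis points
    k = kernel[:, 1:-1]
    w = curve.weights
    a_mat = k * w[:, None]
    b_vec = curve.i * w
    n_p = k.shape[1]
    d2 = np.zeros((n_p, n_p))
    idx = np.arange(n_p)
    d2[idx, idx] = -2.0
    d2[idx[:-1], idx[:-1] + 1] = 1.0
    d2[idx[1:], idx[1:] - 1] = 1.0

    scale = np.linalg.norm(a_mat.T @ a_mat)

    def solve(alpha_val):
        lhs = a_mat.T @ a_mat + alpha_val * scale * (d2.T @ d2)
        rhs = a_mat.T @ b_vec
        try:
            return np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            logger.warning("ill-conditioned IFT system: raising regularization")
            return np.linalg.solve(lhs + 10 * alpha_val * scale * np.eye(n_p), rhs)

    if alpha is None:
        alphas = np.logspace(-10, -2, 25)
        resid_norms, pen_norms = [], []
        for a in alphas:
            p_try = solve(a)
            resid_norms.append(np.log10(np.linalg.norm(a_mat @ p_try - b_vec) + 1e-300))
            pen_norms.append(np.log10(np.linalg.norm(d2 @ p_try) + 1e-300))
        # L-curve corner: maximum curvature of the (residual, penalty) path
        x, y = np.asarray(resid_norms), np.asarray(pen_norms)
        dx, dy = np.gradient(x), np.gradient(y)
        ddx, ddy = np.gradient(dx), np.gradient(dy)
        denom = np.power(dx * dx + dy * dy, 1.5)
        with np.errstate(divide="ignore", invalid="ignore"):
            curvature = np.abs(dx * ddy - dy * ddx) / denom
        curvature[~np.isfinite(curvature)] = 0.0
        alpha = float(alphas[int(np.argmax(curvature))])

    p_inner = solve(alpha)
    p = np.concatenate([[0.0], p_inner, [0.0]])
    if np.any(p < -0.01 * np.max(np.abs(p), initial=0.0)):
        logger.warning("P(r) has negative excursions; consider a larger d_max or alpha")

    integral = integrate.simpson(p, x=r)
    if integral <= 0:
        rg = 0.0
        i0 = 0.0
    else:
        rg = float(np.sqrt(integrate.simpson(r * r * p, x=r) / (2.0 * integral)))
        i0 = float(4.0 * np.pi * integral)
    return PairDistribution(r=r, p=p, d_max=float(d_max), r_g=rg, i0=i0, alpha=float(alpha))


def mass_from_i0(i0: float, inputs: MassInputs) -> float:
    """Molecular mass in kDa from the absolute forward scattering.

    M = I(0) N_A / (c (delta_rho vbar)^2) with c in g/cm^3.
    """
    c = inputs.c_mg_ml * 1e-3  # mg/mL -> g/cm^3
    contrast = inputs.delta_rho * inputs.vbar  # cm^-2 * cm^3/g = cm/g
    m_da = i0 * N_AVOGADRO / (c * contrast ** 2)
    return m_da / 1000.0


def i0_from_mass(mass_kda: float, inputs: MassInputs) -> float:
    """Forward model: the I(0) a particle of the given mass would produce.

    Exact inverse of :func:`mass_from_i0`; used by the synthetic generator.
    """
    c = inputs.c_mg_ml * 1e-3
    contrast = inputs.delta_rho * inputs.vbar
    return mass_kda * 1000.0 * c * contrast ** 2 / N_AVOGADRO


def broad_peak_model(q, a, n, c, q0, xi, m, b):
    """I(q) = A/q^n + C/(1 + (|q - q0| xi)^m) + B."""
    return a / q ** n + c / (1.0 + (np.abs(q - q0) * xi) ** m) + b


def broad_peak_fit(
    curve: ScatteringCurve, initial: dict | None = None
) -> BroadPeakParams:
    """Fit the empirical broad-peak model by weighted least squares.

    ``initial`` may override any of the starting values a, n, c, q0, xi, m,
    b; otherwise they are estimated from the curve (peak position from the
    maximum after subtracting a low-q power-law estimate).  Non-convergence
    raises with the lmfit diagnostics attached.
    """
    q, i = curve.q, curve.i
    guesses = {
        "a": max(i[0] * q[0] ** 2.5, 1e-12), "n": 2.5,
        "c": max(np.max(i) - np.median(i), np.max(i) * 0.1),
        "q0": float(q[np.argmax(i * q)]),
        "xi": 5.0 / (q[-1] - q[0]), "m": 2.0, "b": 0.0,
    }
    if initial:
        guesses.update(initial)
    model = lmfit.Model(broad_peak_model)
    params = model.make_params(**guesses)
    params["n"].set(min=0.1, max=6.0)
    params["m"].set(min=0.1, max=10.0)
    params["q0"].set(min=q[0], max=q[-1])
    params["xi"].set(min=1e-3)
    params["a"].set(min=0.0)
    params["c"].set(min=0.0)
    result = model.fit(i, params, q=q, weights=curve.weights)
    if not result.success:
        raise RuntimeError(f"broad-peak fit failed: {result.message}")
    if result.params["c"].value <= 0 or result.params["xi"].value <= 1e-3:
        logger.warning("broad-peak fit degenerate: Lorentzian component vanishes")

    def sd(name):
        err = result.params[name].stderr
        return float(err) if err is not None else float("nan")

    v = {name: float(result.params[name].value) for name in "a n c q0 xi m b".split()}
    return BroadPeakParams(
        **v, **{f"{name}_sd": sd(name) for name in "a n c q0 xi m b".split()}
    )


def gaussian_peak_fit(
    curve: ScatteringCurve,
    n_peaks: int,
    centers_guess: list[float] | None = None,
    baseline: str = "linear",
) -> dict:
    """Fit a sum of Gaussians plus a baseline; returns sorted peak centers.

    ``centers_guess`` seeds the peak positions (evenly spaced over the q
    range when omitted).  ``baseline`` is ``"linear"`` or ``"none"``.
    Returns a dict with ``centers``, ``center_sds``, ``d_spacings``,
    ``amplitudes``, ``sigmas`` and the lmfit ``result``.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    q, i = curve.q, curve.i
    if centers_guess is None:
        # seed from the most prominent local maxima of the baseline-detrended
        # curve; fall back to even spacing when too few are found
        detrended = i - np.linspace(i[0], i[-1], len(i))
        idx, props = signal.find_peaks(detrended, prominence=0.0)
        if len(idx) >= n_peaks:
            top = idx[np.argsort(props["prominences"])[::-1][:n_peaks]]
            centers_guess = sorted(q[j] for j in top)
        else:
            centers_guess = list(np.linspace(q[0], q[-1], n_peaks + 2)[1:-1])
    if len(centers_guess) != n_peaks:
        raise ValueError("centers_guess length must equal n_peaks")

    model = None
    params = lmfit.Parameters()
    span = q[-1] - q[0]
    for k, c0 in enumerate(centers_guess):
        g = lmfit.models.GaussianModel(prefix=f"g{k}_")
        model = g if model is None else model + g
        params.update(g.make_params())
        params[f"g{k}_center"].set(value=c0, min=q[0], max=q[-1])
        params[f"g{k}_sigma"].set(value=span / (6 * n_peaks), min=span / 1000, max=span)
        params[f"g{k}_amplitude"].set(value=float(np.max(i)) * span / (6 * n_peaks), min=0)
    if baseline == "linear":
        lin = lmfit.models.LinearModel(prefix="bl_")
        model = model + lin
        params.update(lin.make_params(slope=0.0, intercept=float(np.min(i))))
    elif baseline != "none":
        raise ValueError(f"unknown baseline {baseline!r}")

    result = model.fit(i, params, x=q, weights=curve.weights)
    if not result.success:
        logger.warning("multi-Gaussian fit convergence issue: %s", result.message)
    peaks = []
    for k in range(n_peaks):
        p = result.params
        err = p[f"g{k}_center"].stderr
        peaks.append(
            (float(p[f"g{k}_center"].value),
             float(err) if err is not None else float("nan"),
             float(p[f"g{k}_amplitude"].value),
             float(p[f"g{k}_sigma"].value))
        )
    peaks.sort(key=lambda t: t[0])
    return {
        "centers": [p[0] for p in peaks],
        "center_sds": [p[1] for p in peaks],
        "amplitudes": [p[2] for p in peaks],
        "sigmas": [p[3] for p in peaks],
        "d_spacings": [d_spacing(p[0]) for p in peaks],
        "result": result,
    }


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized sphere form factor P(q) = [3 (sin x - x cos x)/x^3]^2."""
    x = np.asarray(q, dtype=float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    return np.where(x == 0, 1.0, amp) ** 2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form (unnormalized) P(r) of a homogeneous sphere.

    P(r) = r^2 (1 - 3u/2 + u^3/2) for u = r/(2R) <= 1, zero beyond the
    diameter.
    """
    u = np.asarray(r, dtype=float) / (2.0 * radius)
    gamma = 1.0 - 1.5 * u + 0.5 * u ** 3
    return np.where(u <= 1.0, np.asarray(r) ** 2 * gamma, 0.0)
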