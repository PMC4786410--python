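"""Two-state binding analysis of NMR chemical-shift-perturbation titrations.

A ligand L titrated into protein P in fast exchange shifts each observed
resonance by an amount proportional to the bound fraction:

    dw(Lt) = dw_max * fb(Pt, Lt, K_D)

with the exact ligand-depletion (quadratic) bound fraction

    fb = (Pt + Lt + K_D - sqrt((Pt + Lt + K_D)^2 - 4 Pt Lt)) / (2 Pt).

The module provides per-residue K_D fits, the two-stage saturation filter
used to select isotherms for global analysis, a shared-K_D global fit across
residues (one K_D, one dw_max per residue), and Monte-Carlo error estimation
in which the dominant experimental uncertainty - the absolute ligand
concentration - is modelled as a multiplicative scale error on the titration
axis.

Only the single-site two-state model is implemented; isotherms showing
multiple independent binding events are outside this model's validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

KD_LOWER = 1e-6  # µM; open lower bound for the optimizer
KD_UPPER = 1e4   # µM

SATURATION_DELTA_MIN = 0.15  # ppm; minimum final |dw| to keep an isotherm
N_TAIL_POINTS = 5            # points used in the end-slope saturation check


@dataclass
class TitrationSeries:
    """One residue's chemical-shift trajectory over a titration.

    Concentrations in µM; shifts in ppm.  ``delta_omega`` is aligned with
    ``ligand_totals`` and is zero at zero ligand by construction.
    """

    residue: str
    protein_total: float
    ligand_totals: np.ndarray
    delta_omega: np.ndarray

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.delta_omega = np.asarray(self.delta_omega, dtype=float)
        if self.ligand_totals.shape != self.delta_omega.shape:
            raise ValueError(f"{self.residue}: concentration/shift length mismatch")
        if self.protein_total <= 0:
            raise ValueError(f"{self.residue}: protein concentration must be positive")
        if np.any(np.diff(self.ligand_totals) < 0):
            raise ValueError(f"{self.residue}: ligand concentrations must be non-decreasing")

    def __len__(self) -> int:
        return len(self.ligand_totals)


@dataclass
class BindingFit:
    """Fitted two-state parameters with Monte-Carlo uncertainties.

    ``kd_sd`` / ``dw_max_sd`` are NaN when Monte-Carlo was not run.
    ``dw_max`` maps residue label -> saturation shift (ppm).
    """

    kd: float
    kd_sd: float
    dw_max: dict[str, float]
    dw_max_sd: dict[str, float]
    n_isotherms: int
    converged: bool = True
    residuals: np.ndarray | None = None


@dataclass
class SelectionReport:
    """Which isotherms passed which stage of the saturation filter and why."""

    accepted: list[TitrationSeries]
    stage1_rejected: list[str] = field(default_factory=list)
    stage2_rejected: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    slopes: dict[str, float] = field(default_factory=dict)
    mean_slope: float = float("nan")


def fraction_bound(pt, lt, kd):
    """Exact two-state bound fraction of the protein with ligand depletion.

    All concentrations in the same units (µM by convention).  Vectorized over
    ``lt``.
    """
    pt = np.asarray(pt, dtype=float)
    lt = np.asarray(lt, dtype=float)
    if np.any(pt <= 0) or np.any(lt < 0) or kd <= 0:
        raise ValueError("require Pt > 0, Lt >= 0, K_D > 0")
    s = pt + lt + kd
    disc = s * s - 4.0 * pt * lt
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * pt)
    return np.clip(fb, 0.0, 1.0)


def predict_csp(series: TitrationSeries, kd: float, dw_max: float) -> np.ndarray:
    """Predicted chemical-shift perturbations for a series under the model."""
    return dw_max * fraction_bound(series.protein_total, series.ligand_totals, kd)


def select_isotherms(
    series_set: list[TitrationSeries],
    delta_min: float = SATURATION_DELTA_MIN,
    n_tail: int = N_TAIL_POINTS,
) -> SelectionReport:
    """Two-stage filter selecting saturated isotherms for the global fit.

    Stage 1 keeps series whose final ``|dw|`` exceeds ``delta_min`` (default
    0.15 ppm).  Stage 2 normalizes the last ``n_tail`` points of each stage-1
    survivor by its final shift, fits a straight line against titration-point
    index, and keeps series whose slope is strictly less than the mean slope
    of the stage-1 survivors; a small end-slope indicates a resonance that
    has reached saturation.  Series with fewer than ``n_tail`` points are
    excluded with a logged reason.
    """
    report = SelectionReport(accepted=[])
    stage1: list[TitrationSeries] = []
    for s in series_set:
        if len(s) < n_tail:
            logger.warning("isotherm %s: only %d points (< %d), excluded", s.residue, len(s), n_tail)
            report.excluded.append(s.residue)
            continue
        if abs(s.delta_omega[-1]) <= delta_min:
            report.stage1_rejected.append(s.residue)
            continue
        stage1.append(s)
    for s in stage1:
        tail = s.delta_omega[-n_tail:] / s.delta_omega[-1]
        idx = np.arange(n_tail, dtype=float)
        slope = np.polyfit(idx, tail, 1)[0]
        report.slopes[s.residue] = float(slope)
    if not stage1:
        return report
    report.mean_slope = float(np.mean(list(report.slopes.values())))
    for s in stage1:
        if report.slopes[s.residue] < report.mean_slope:
            report.accepted.append(s)
        else:
            report.stage2_rejected.append(s.residue)
    return report


def _solve_dw_max(series: TitrationSeries, kd: float) -> float:
    """Closed-form least-squares dw_max for a fixed K_D (variable projection)."""
    fb = fraction_bound(series.protein_total, series.ligand_totals, kd)
    denom = float(fb @ fb)
    if denom == 0.0:
        return 0.0
    return float(fb @ series.delta_omega) / denom


def _global_residuals(kd: float, series_set: list[TitrationSeries]) -> np.ndarray:
    res = []
    for s in series_set:
        dw_max = _solve_dw_max(s, kd)
        res.append(s.delta_omega - dw_max * fraction_bound(s.protein_total, s.ligand_totals, kd))
    return np.concatenate(res)


def _fit_shared_kd(
    series_set: list[TitrationSeries], kd_starts: tuple[float, ...] = (1.0, 30.0, 1000.0)
) -> tuple[float, dict[str, float], np.ndarray, bool]:
    """Shared-K_D fit over a set of series via variable projection.

    Each series' dw_max is solved in closed form for every trial K_D, so the
    nonlinear search is one-dimensional.  Log-spaced starts guard against
    local minima.
    """
    best = None
    for kd0 in kd_starts:
        sol = least_squares(
            lambda x: _global_residuals(x[0], series_set),
            x0=[kd0],
            bounds=([KD_LOWER], [KD_UPPER]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    kd = float(best.x[0])
    dw_max = {s.residue: _solve_dw_max(s, kd) for s in series_set}
    return kd, dw_max, best.fun, bool(best.success)


def _mc_concentration_errors(
    series_set: list[TitrationSeries],
    kd_hat: float,
    ligand_conc_error: float,
    mc_reps: int,
    rng: np.random.Generator,
    per_point: bool = False,
) -> tuple[float, dict[str, list[float]]]:
    """Monte-Carlo refits under ligand-concentration scale errors.

    Each replicate multiplies the ligand axis by one factor drawn from
    Normal(1, ligand_conc_error) - the error shifts points along the abscissa
    - and refits.  ``per_point=True`` instead perturbs every concentration
    independently.  Returns the SD of K_D and the replicate dw_max draws.
    """
    kds = []
    dw_draws: dict[str, list[float]] = {s.residue: [] for s in series_set}
    for _ in range(mc_reps):
        perturbed = []
        for s in series_set:
            if per_point:
                scale = rng.normal(1.0, ligand_conc_error, size=len(s))
            else:
                scale = rng.normal(1.0, ligand_conc_error)
            lt = np.maximum(s.ligand_totals * scale, 0.0)
            lt = np.sort(lt)
            perturbed.append(
                TitrationSeries(s.residue, s.protein_total, lt, s.delta_omega)
            )
        kd_rep, dw_rep, _, _ = _fit_shared_kd(perturbed, kd_starts=(kd_hat,))
        kds.append(kd_rep)
        for r, v in dw_rep.items():
            dw_draws[r].append(v)
    return float(np.std(kds)), dw_draws


def fit_residue_kd(
    series: TitrationSeries,
    ligand_conc_error: float = 0.10,
    mc_reps: int = 500,
    seed: int | None = None,
) -> BindingFit:
    """Per-residue (K_D, dw_max) fit with Monte-Carlo errors.

    Requires at least four titration points.  A flat series (all shifts zero)
    is unidentifiable and raises ``ValueError``.
    """
    if len(series) < 4:
        raise ValueError(f"{series.residue}: need >= 4 points to fit K_D")
    if np.allclose(series.delta_omega, 0.0):
        raise ValueError(f"{series.residue}: flat isotherm, K_D unidentifiable")
    return fit_global_kd(
        [series], ligand_conc_error=ligand_conc_error, mc_reps=mc_reps, seed=seed
    )


def fit_global_kd(
    accepted: list[TitrationSeries],
    ligand_conc_error: float = 0.10,
    mc_reps: int = 500,
    seed: int | None = None,
    per_point_error: bool = False,
) -> BindingFit:
    """Global two-state fit: one shared K_D, one dw_max per isotherm.

    Monte-Carlo errors follow the concentration-scale scheme of
    :func:`_mc_concentration_errors` (default 10% scale error, 500
    replicates).  ``mc_reps=0`` returns the point estimate with NaN errors.
    """
    if not accepted:
        raise ValueError("no isotherms to fit")
    kd, dw_max, residuals, converged = _fit_shared_kd(accepted)
    if not converged:
        logger.warning("global K_D fit did not report convergence")
    kd_sd = float("nan")
    dw_sd = {r: float("nan") for r in dw_max}
    if mc_reps > 0:
        rng = np.random.default_rng(seed)
        kd_sd, dw_draws = _mc_concentration_errors(
            accepted, kd, ligand_conc_error, mc_reps, rng, per_point=per_point_error
        )
        dw_sd = {r: float(np.std(v)) for r, v in dw_draws.items()}
    return BindingFit(
        kd=kd,
        kd_sd=kd_sd,
        dw_max=dw_max,
        dw_max_sd=dw_sd,
        n_isotherms=len(accepted),
        converged=converged,
        residuals=residuals,
    )
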