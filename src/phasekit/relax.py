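"""Model-free analysis of backbone amide NMR relaxation.

The module covers the full path from raw peak-intensity decays to motional
parameters:

* exponential decay fitting (including the two-point scheme) with
  Monte-Carlo errors,
* the transverse dipole-dipole/CSA cross-correlated relaxation rate
  eta_xy = (R2_alpha - R2_beta)/2, which is free of chemical-exchange
  contributions,
* the Lipari-Szabo model-free (LS-MF) spectral density

      J(w) = 2/5 [ S^2 tau_c / (1 + (w tau_c)^2)
                   + (1 - S^2) tau_i / (1 + (w tau_i)^2) ],
      1/tau_i = 1/tau_c + 1/tau_f,

  and its local variant (local-MF: tau_f = 0, residue-specific tau_c,local),
* grid search plus continuous global minimization of a shared tumbling time
  tau_c with residue-specific (S^2, tau_f),
* per-residue model selection between LS-MF and local-MF by nested F-test
  and a realism constraint (S^2 < 1),
* the Stokes-Einstein hydrated-radius ratio used to infer binding
  stoichiometry from the change in tau_c with mass.

Prefactor conventions (standard in the TRACT / model-free literature, all
constants centralized in :class:`PhysicalConstants` and overridable):

    d      = (mu0 / 4 pi) hbar gamma_H |gamma_N| / r_NH^3      (dipolar)
    c      = omega_N |CSA| / sqrt(3)                            (CSA, for R1)
    R1     = d^2/4 [J(wH - wN) + 3 J(wN) + 6 J(wH + wN)] + c^2 J(wN)
    eta_xy = (d omega_N |CSA| / 6) P2(cos theta) [4 J(0) + 3 J(wN)]

with P2 the second Legendre polynomial and theta the angle between the CSA
tensor's unique axis and the N-H bond.  Magnitudes are used for gamma_N and
the CSA so that eta_xy is positive for a macromolecule (R2_alpha, the
fast-relaxing anti-TROSY component, larger than R2_beta).  Rotational
anisotropy is not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import brentq, least_squares

logger = logging.getLogger(__name__)

NS = 1e-9
PS = 1e-12

#: Avogadro's number (1/mol)
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class PhysicalConstants:
    """Spin-interaction constants for backbone ^15N relaxation.

    Defaults: 15N CSA of -162 ppm, an N-H bond length of 1.04 Angstrom and a
    17 degree angle between the CSA unique axis and the bond vector.
    """

    csa_ppm: float = -162.0
    r_nh_angstrom: float = 1.04
    theta_deg: float = 17.0
    gamma_h: float = 2.6752218744e8   # rad/s/T
    gamma_n: float = -2.7126e7        # rad/s/T (negative for 15N)
    hbar: float = 1.054571817e-34     # J s
    mu0: float = 4.0e-7 * np.pi       # T m / A

    @property
    def dipolar_constant(self) -> float:
        """d = (mu0/4pi) hbar gamma_H |gamma_N| / r_NH^3, in rad/s."""
        r3 = (self.r_nh_angstrom * 1e-10) ** 3
        return (self.mu0 / (4 * np.pi)) * self.hbar * self.gamma_h * abs(self.gamma_n) / r3

    @property
    def p2_cos_theta(self) -> float:
        c = np.cos(np.deg2rad(self.theta_deg))
        return 0.5 * (3 * c * c - 1)


DEFAULT_CONSTANTS = PhysicalConstants()

# Grid-search ranges: S^2 from 0.6 to 1.0 step 0.01, tau_f from 0 to 1 ns in
# 100 ps steps, tau_c from 40 to 80 ns in 1 ns steps.
GRID_S2 = np.round(np.arange(0.60, 1.0 + 1e-9, 0.01), 2)
GRID_TAU_F_PS = np.arange(0.0, 1000.0 + 1e-9, 100.0)
GRID_TAU_C_NS = np.arange(40.0, 80.0 + 1e-9, 1.0)

# Continuous-fit bounds
S2_BOUNDS = (1e-3, 1.0)
S2_BOUNDS_UNREALISTIC = (1e-3, 2.0)   # used to *detect* unrealistic fits
TAU_F_BOUNDS_PS = (0.0, 2000.0)
TAU_C_BOUNDS_NS = (20.0, 120.0)
TAU_C_LOCAL_BOUNDS_NS = (0.05, 120.0)


@dataclass
class DecayCurve:
    """A peak-intensity relaxation decay for one residue at one field."""

    residue: str
    field_mhz: float
    rate_type: str                      # R2_alpha | R2_beta | R1
    delays: np.ndarray                  # s
    intensities: np.ndarray
    noise_sd: np.ndarray | float = 1.0
    duplicates: bool = False

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.isscalar(self.noise_sd) or np.ndim(self.noise_sd) == 0:
            self.noise_sd = np.full_like(self.intensities, float(self.noise_sd))
        else:
            self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if len(self.delays) < 2:
            raise ValueError(f"{self.residue}: need >= 2 delay points")


@dataclass
class RateObservation:
    """A quantified relaxation observable used in model-free fitting."""

    residue: str
    field_mhz: float
    rate_type: str      # eta_xy | R1
    value: float
    sigma: float = 1.0


@dataclass
class RelaxationRecord:
    """Per-residue, per-field quantified rates (s^-1)."""

    residue: str
    field_mhz: float
    r2_alpha: float | None = None
    r2_alpha_sd: float = 0.0
    r2_beta: float | None = None
    r2_beta_sd: float = 0.0
    r1: float | None = None
    r1_sd: float = 0.0
    eta_xy: float | None = None
    eta_xy_sd: float = 0.0

    def with_eta(self) -> "RelaxationRecord":
        """Return a copy with eta_xy computed from R2_alpha/R2_beta."""
        if self.r2_alpha is None or self.r2_beta is None:
            raise ValueError(f"{self.residue}: both R2 components required for eta_xy")
        if self.r2_alpha <= self.r2_beta:
            logger.warning(
                "%s @ %.0f MHz: R2_alpha <= R2_beta, unexpected for a macromolecule",
                self.residue, self.field_mhz,
            )
        eta, sd = compute_eta_xy(self.r2_alpha, self.r2_alpha_sd, self.r2_beta, self.r2_beta_sd)
        return replace(self, eta_xy=eta, eta_xy_sd=sd)

    def observations(self) -> list[RateObservation]:
        obs = []
        if self.eta_xy is not None:
            obs.append(RateObservation(self.residue, self.field_mhz, "eta_xy",
                                       self.eta_xy, self.eta_xy_sd or 1.0))
        if self.r1 is not None:
            obs.append(RateObservation(self.residue, self.field_mhz, "R1",
                                       self.r1, self.r1_sd or 1.0))
        return obs


@dataclass
class MotionalParams:
    """Model-free motional parameters for one residue.

    Exactly one of ``tau_c_ns`` (shared tumbling) / ``tau_c_local_ns`` is set
    depending on the model.  ``model`` is ``"LS-MF"`` or ``"local-MF"``.
    """

    residue: str
    model: str
    s2: float
    tau_f_ps: float = 0.0
    tau_c_ns: float | None = None
    tau_c_local_ns: float | None = None
    chi2: float = float("nan")
    s2_sd: float = float("nan")
    tau_f_sd_ps: float = float("nan")
    tau_c_sd_ns: float = float("nan")
    notes: list[str] = field(default_factory=list)

    @property
    def effective_tau_c_ns(self) -> float:
        return self.tau_c_local_ns if self.tau_c_local_ns is not None else self.tau_c_ns


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def _fit_exp(delays: np.ndarray, intensities: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of I(t) = I0 exp(-R t); returns (R, I0)."""
    # log-linear initialization (valid because intensities are positive here)
    slope, intercept = np.polyfit(delays, np.log(intensities), 1)
    x0 = [max(-slope, 1e-3), np.exp(intercept)]
    sol = least_squares(
        lambda x: x[1] * np.exp(-x[0] * delays) - intensities,
        x0=x0, bounds=([0.0, 0.0], [np.inf, np.inf]),
    )
    return float(sol.x[0]), float(sol.x[1])


def fit_decay(
    curve: DecayCurve, mc_reps: int = 1000, seed: int | None = None
) -> dict:
    """Fit a single-exponential decay; Monte-Carlo errors by resampling.

    With exactly two delay points the closed form
    ``R = ln(I1/I2)/(t2 - t1)`` is used with analytically propagated error
    (the two-point sampling scheme).  With three or more points a
    least-squares fit is performed and errors come from ``mc_reps``
    resamples of the intensities from Normal(I, noise_sd).

    Returns a dict with keys ``rate``, ``rate_sd``, ``i0``, ``i0_sd``.
    Non-positive intensities are rejected pointwise with a warning.
    """
    keep = curve.intensities > 0
    if not np.all(keep):
        logger.warning("%s: dropping %d non-positive intensity point(s)",
                       curve.residue, int((~keep).sum()))
    t = curve.delays[keep]
    y = curve.intensities[keep]
    s = curve.noise_sd[keep]
    if len(t) < 2:
        raise ValueError(f"{curve.residue}: fewer than 2 usable points")

    if len(t) == 2:
        dt = t[1] - t[0]
        rate = float(np.log(y[0] / y[1]) / dt)
        i0 = float(y[0] * np.exp(rate * t[0]))
        rate_sd = float(np.sqrt((s[0] / y[0]) ** 2 + (s[1] / y[1]) ** 2) / abs(dt))
        i0_sd = float(s[0])  # dominated by the first point's noise
        return {"rate": rate, "rate_sd": rate_sd, "i0": i0, "i0_sd": i0_sd}

    rate, i0 = _fit_exp(t, y)
    rate_sd = i0_sd = float("nan")
    if mc_reps > 0:
        rng = np.random.default_rng(seed)
        draws_r, draws_i = [], []
        for _ in range(mc_reps):
            y_rep = rng.normal(y, s)
            ok = y_rep > 0
            if ok.sum() < 2:
                continue
            r_rep, i_rep = _fit_exp(t[ok], y_rep[ok])
            draws_r.append(r_rep)
            draws_i.append(i_rep)
        rate_sd = float(np.std(draws_r))
        i0_sd = float(np.std(draws_i))
    return {"rate": rate, "rate_sd": rate_sd, "i0": i0, "i0_sd": i0_sd}


def compute_eta_xy(
    r2_alpha: float, sd_alpha: float, r2_beta: float, sd_beta: float
) -> tuple[float, float]:
    """eta_xy as half the difference of the two R2 doublet components.

    The error follows by propagation: sqrt(sd_a^2 + sd_b^2)/2.
    """
    eta = 0.5 * (r2_alpha - r2_beta)
    sd = 0.5 * np.hypot(sd_alpha, sd_beta)
    return float(eta), float(sd)


# ---------------------------------------------------------------------------
# spectral density and rate prediction
# ---------------------------------------------------------------------------

def spectral_density(omega, s2, tau_c, tau_f=0.0):
    """Lipari-Szabo model-free spectral density, SI units.

    ``omega`` in rad/s (scalar or array), ``tau_c``/``tau_f`` in seconds.
    ``tau_f = 0`` reduces to the single-Lorentzian (local-MF / rigid) form
    J = 2/5 S^2 tau_c / (1 + (w tau_c)^2).
    """
    omega = np.asarray(omega, dtype=float)
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    j = s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    if tau_f > 0.0 and s2 < 1.0:
        tau_i = 1.0 / (1.0 / tau_c + 1.0 / tau_f)
        j = j + (1.0 - s2) * tau_i / (1.0 + (omega * tau_i) ** 2)
    return 0.4 * j


def larmor_frequencies(field_mhz: float, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """(omega_H, omega_N) in rad/s for a ^1H Larmor frequency in MHz."""
    omega_h = 2 * np.pi * field_mhz * 1e6
    omega_n = omega_h * abs(constants.gamma_n) / constants.gamma_h
    return omega_h, omega_n


def predict_rates(
    field_mhz: float,
    s2: float,
    tau_c_s: float,
    tau_f_s: float = 0.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Predicted (eta_xy, R1) in s^-1 at a given field for LS-MF parameters.

    ``tau_c_s``/``tau_f_s`` in seconds.  A warning is emitted for fields
    outside the 500-1200 MHz range typical of modern spectrometers; the
    expressions remain valid.
    """
    if not 500.0 <= field_mhz <= 1200.0:
        logger.warning("field %.0f MHz outside the typical 500-1200 MHz range", field_mhz)
    omega_h, omega_n = larmor_frequencies(field_mhz, constants)
    d = constants.dipolar_constant
    csa = abs(constants.csa_ppm) * 1e-6
    c = omega_n * csa / np.sqrt(3.0)

    def j(w):
        return spectral_density(w, s2, tau_c_s, tau_f_s)

    r1 = (d * d / 4.0) * (j(omega_h - omega_n) + 3 * j(omega_n) + 6 * j(omega_h + omega_n)) \
        + c * c * j(omega_n)
    eta = (d * omega_n * csa / 6.0) * constants.p2_cos_theta * (4 * j(0.0) + 3 * j(omega_n))
    return float(eta), float(r1)


def predict_observation(
    obs: RateObservation,
    s2: float,
    tau_c_s: float,
    tau_f_s: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    eta, r1 = predict_rates(obs.field_mhz, s2, tau_c_s, tau_f_s, constants)
    if obs.rate_type == "eta_xy":
        return eta
    if obs.rate_type == "R1":
        return r1
    raise ValueError(f"unsupported rate type {obs.rate_type!r}")


# ---------------------------------------------------------------------------
# grid search and global minimization
# ---------------------------------------------------------------------------

def _chi2_grid(
    observations: list[RateObservation],
    s2_grid: np.ndarray,
    tau_f_ps_grid: np.ndarray,
    tau_c_ns_grid: np.ndarray,
    constants: PhysicalConstants,
) -> np.ndarray:
    """chi^2 over the full (S^2, tau_f, tau_c) grid, vectorized per observation."""
    s2 = s2_grid[:, None, None]
    tf = tau_f_ps_grid[None, :, None] * PS
    tc = tau_c_ns_grid[None, None, :] * NS
    with np.errstate(divide="ignore"):
        inv_tf = np.divide(1.0, tf, out=np.zeros(np.broadcast_shapes(tf.shape, tc.shape)), where=tf > 0)
        tau_i = np.where(tf > 0, 1.0 / (1.0 / tc + inv_tf), 0.0)

    def j(w):
        val = s2 * tc / (1.0 + (w * tc) ** 2)
        internal = (1.0 - s2) * tau_i / (1.0 + (w * tau_i) ** 2)
        return 0.4 * (val + np.where(tf > 0, internal, 0.0))

    chi2 = np.zeros((len(s2_grid), len(tau_f_ps_grid), len(tau_c_ns_grid)))
    d = constants.dipolar_constant
    csa = abs(constants.csa_ppm) * 1e-6
    for obs in observations:
        omega_h, omega_n = larmor_frequencies(obs.field_mhz, constants)
        if obs.rate_type == "eta_xy":
            calc = (d * omega_n * csa / 6.0) * constants.p2_cos_theta * (4 * j(0.0) + 3 * j(omega_n))
        elif obs.rate_type == "R1":
            c = omega_n * csa / np.sqrt(3.0)
            calc = (d * d / 4.0) * (j(omega_h - omega_n) + 3 * j(omega_n) + 6 * j(omega_h + omega_n)) \
                + c * c * j(omega_n)
        else:
            raise ValueError(f"unsupported rate type {obs.rate_type!r}")
        sigma = obs.sigma if obs.sigma > 0 else 1.0
        chi2 += ((obs.value - calc) / sigma) ** 2
    return chi2


def grid_search(
    observations: list[RateObservation],
    s2_grid: np.ndarray = GRID_S2,
    tau_f_ps_grid: np.ndarray = GRID_TAU_F_PS,
    tau_c_ns_grid: np.ndarray = GRID_TAU_C_NS,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> MotionalParams:
    """Exhaustive chi^2 minimization over the model-free parameter grid.

    The default grid spans S^2 in [0.6, 1.0] (step 0.01), tau_f in [0, 1 ns]
    (step 100 ps) and tau_c in [40, 80 ns] (step 1 ns).  Intended for
    residues of the folded core whose tumbling reports on the whole
    particle.  With fewer observations than the three parameters the result
    is flagged underdetermined.
    """
    if len(observations) < 2:
        raise ValueError("need at least two independent rate observations")
    residue = observations[0].residue
    chi2 = _chi2_grid(observations, s2_grid, tau_f_ps_grid, tau_c_ns_grid, constants)
    i, k, l = np.unravel_index(np.argmin(chi2), chi2.shape)
    params = MotionalParams(
        residue=residue,
        model="LS-MF",
        s2=float(s2_grid[i]),
        tau_f_ps=float(tau_f_ps_grid[k]),
        tau_c_ns=float(tau_c_ns_grid[l]),
        chi2=float(chi2[i, k, l]),
    )
    if len(observations) < 3:
        params.notes.append("underdetermined: fewer observations than parameters")
    return params


def group_by_tauc(
    grid_results: list[MotionalParams], tol_ns: float = 3.0
) -> list[list[MotionalParams]]:
    """Group residues with similar grid tau_c and tau_f of 0 or 100 ps.

    Groups are built greedily on sorted tau_c with a +/- ``tol_ns`` window;
    residues whose grid tau_f exceeds 100 ps are excluded from grouping.
    """
    eligible = [p for p in grid_results if p.tau_f_ps <= 100.0]
    eligible.sort(key=lambda p: p.tau_c_ns)
    groups: list[list[MotionalParams]] = []
    for p in eligible:
        if groups and abs(p.tau_c_ns - np.mean([q.tau_c_ns for q in groups[-1]])) <= tol_ns:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups


def rigid_rotor_tauc_lower_bound(
    observations: list[RateObservation],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Lower bound on tau_c (ns) from eta_xy under a rigid-rotor J(w).

    For S^2 = 1 and tau_f = 0 the predicted eta_xy is monotone increasing in
    tau_c; since internal motion (S^2 < 1) only reduces eta_xy, the
    rigid-rotor tau_c reproducing the observed eta_xy bounds the true tau_c
    from below.  The bound is the largest such value over the eta_xy
    observations.
    """
    bounds = []
    for obs in observations:
        if obs.rate_type != "eta_xy" or obs.value <= 0:
            continue

        def f(tc_ns, _obs=obs):
            eta, _ = predict_rates(_obs.field_mhz, 1.0, tc_ns * NS, 0.0, constants)
            return eta - _obs.value

        lo, hi = 0.05, 500.0
        if f(lo) > 0 or f(hi) < 0:
            continue
        bounds.append(brentq(f, lo, hi))
    return max(bounds) if bounds else TAU_C_BOUNDS_NS[0]


#: S^2 window for the joint folded-core refinement.  Core residues are
#: selected for rigidity, so S^2 stays within the grid range; letting it fall
#: lower opens a near-degenerate (S^2 down, tau_c up) valley of the target
#: function along which eta_xy is almost unchanged.
CORE_S2_BOUNDS = (0.60, 1.0)


def fit_global_tauc(
    group_observations: dict[str, list[RateObservation]],
    init: dict[str, MotionalParams] | None = None,
    mc_reps: int = 1000,
    seed: int | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    tau_f_ps_grid: np.ndarray = GRID_TAU_F_PS,
    max_iter: int = 6,
) -> tuple[float, float, dict[str, MotionalParams]]:
    """Jointly refine one tau_c plus residue-specific (S^2, tau_f) for a
    folded-core group.

    ``group_observations`` maps residue label -> observations across fields.
    Starting from the grid solutions in ``init`` (computed on the fly when
    omitted), the refinement alternates two steps to a fixed point:

    1. continuous joint minimization of the shared tau_c and per-residue
       S^2 (bounded to the core window [0.6, 1.0]) with each residue's
       tau_f held at its current grid assignment;
    2. re-assignment of every tau_f on its grid with tau_c fixed at the new
       joint value.

    tau_f is deliberately not a free continuous parameter here: with eta_xy
    measured at a few fields and R1 at one, a free tau_f opens a
    quasi-degenerate valley along which tau_c is unbounded above; the
    fast-motion grid (the same one the residue grouping conditions on)
    regularizes the problem.  The lower bound on tau_c comes from a
    rigid-rotor treatment of the eta_xy data.  Monte-Carlo errors resample
    every rate from Normal(value, sigma) and refit (one joint minimization
    per replicate, tau_f assignments held at the solution).

    Returns ``(tau_c_ns, tau_c_sd_ns, per-residue MotionalParams)``.
    """
    if not group_observations:
        raise ValueError("empty residue group")
    residues = list(group_observations)
    if init is None:
        init = {r: grid_search(group_observations[r], constants=constants) for r in residues}
    all_obs = [o for r in residues for o in group_observations[r]]
    tc_lower = max(rigid_rotor_tauc_lower_bound(all_obs, constants) - 1.0,
                   GRID_TAU_C_NS[0])
    tc_upper = GRID_TAU_C_NS[-1]
    n_res = len(residues)
    lb = np.r_[tc_lower, [CORE_S2_BOUNDS[0]] * n_res]
    ub = np.r_[tc_upper, [CORE_S2_BOUNDS[1]] * n_res]

    def residuals(x, tfs, obs_map):
        tc_s = x[0] * NS
        out = []
        for idx, r in enumerate(residues):
            s2 = x[1 + idx]
            for obs in obs_map[r]:
                calc = predict_observation(obs, s2, tc_s, tfs[idx] * PS, constants)
                out.append((obs.value - calc) / (obs.sigma if obs.sigma > 0 else 1.0))
        return np.asarray(out)

    tfs = [init[r].tau_f_ps for r in residues]
    x = np.clip(
        np.r_[np.mean([init[r].tau_c_ns for r in residues]),
              [init[r].s2 for r in residues]],
        lb, ub,
    )
    sol = None
    for _ in range(max_iter):
        sol = least_squares(residuals, x, args=(tfs, group_observations), bounds=(lb, ub))
        x = sol.x
        new_tfs = [
            grid_search(
                group_observations[r],
                tau_c_ns_grid=np.asarray([x[0]]),
                tau_f_ps_grid=tau_f_ps_grid,
                constants=constants,
            ).tau_f_ps
            for r in residues
        ]
        if new_tfs == tfs:
            break
        tfs = new_tfs
    tau_c_ns = float(sol.x[0])

    tau_c_sd = float("nan")
    if mc_reps > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(mc_reps):
            perturbed = {
                r: [replace(o, value=rng.normal(o.value, o.sigma)) for o in group_observations[r]]
                for r in residues
            }
            rep = least_squares(residuals, sol.x, args=(tfs, perturbed), bounds=(lb, ub))
            draws.append(rep.x[0])
        tau_c_sd = float(np.std(draws))

    chi2 = float(np.sum(sol.fun ** 2))
    results = {}
    for idx, r in enumerate(residues):
        results[r] = MotionalParams(
            residue=r, model="LS-MF",
            s2=float(sol.x[1 + idx]), tau_f_ps=float(tfs[idx]),
            tau_c_ns=tau_c_ns, tau_c_sd_ns=tau_c_sd, chi2=chi2,
        )
    return tau_c_ns, tau_c_sd, results


# ---------------------------------------------------------------------------
# per-residue model selection
# ---------------------------------------------------------------------------

def _fit_continuous(
    observations: list[RateObservation],
    free: str,
    fixed_tauc_ns: float | None,
    constants: PhysicalConstants,
    s2_upper: float = S2_BOUNDS_UNREALISTIC[1],
) -> tuple[np.ndarray, float]:
    """Bounded least-squares for one residue.

    ``free`` selects the parameter set: ``"s2_tf"`` (LS-MF with fixed global
    tau_c), ``"s2"`` (LS-MF, tau_f = 0), ``"tc_s2"`` (local-MF).  S^2 is
    deliberately allowed above 1 so that unrealistic solutions can be
    detected rather than silently pinned at the bound.
    """
    def residuals(x):
        if free == "s2_tf":
            s2, tf_s, tc_s = x[0], x[1] * PS, fixed_tauc_ns * NS
        elif free == "s2":
            s2, tf_s, tc_s = x[0], 0.0, fixed_tauc_ns * NS
        else:  # tc_s2
            s2, tf_s, tc_s = x[1], 0.0, x[0] * NS
        return np.asarray([
            (o.value - predict_observation(o, s2, tc_s, tf_s, constants))
            / (o.sigma if o.sigma > 0 else 1.0)
            for o in observations
        ])

    if free == "s2_tf":
        x0, lb, ub = [0.8, 100.0], [S2_BOUNDS[0], TAU_F_BOUNDS_PS[0]], [s2_upper, TAU_F_BOUNDS_PS[1]]
    elif free == "s2":
        x0, lb, ub = [0.8], [S2_BOUNDS[0]], [s2_upper]
    else:
        x0, lb, ub = [5.0, 0.5], [TAU_C_LOCAL_BOUNDS_NS[0], S2_BOUNDS[0]], \
            [TAU_C_LOCAL_BOUNDS_NS[1], s2_upper]
    sol = least_squares(residuals, x0, bounds=(lb, ub))
    return sol.x, float(np.sum(sol.fun ** 2))


def f_test(chi2_simple: float, p_simple: int, chi2_complex: float, p_complex: int,
           n_obs: int, alpha: float = 0.05) -> bool:
    """Nested F-test: True when the complex model is a significant improvement."""
    dof = n_obs - p_complex
    if dof <= 0 or chi2_complex <= 0:
        return False
    f_stat = ((chi2_simple - chi2_complex) / (p_complex - p_simple)) / (chi2_complex / dof)
    return f_stat > stats.f.ppf(1 - alpha, p_complex - p_simple, dof)


def fit_local_motion(
    observations: list[RateObservation],
    global_tauc_ns: float | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    alpha: float = 0.05,
) -> MotionalParams:
    """Per-residue model-free fit with model selection.

    Candidates: (a) LS-MF with the supplied global tau_c held fixed, fitting
    (S^2, tau_f) and using a nested F-test (95% by default) to decide whether
    tau_f is warranted over tau_f = 0; (b) local-MF, fitting a
    residue-specific tau_c,local and S^2 with tau_f = 0.  Cross-family
    selection falls back to the lower chi^2 because the two families are not
    nested.  Any candidate converging to S^2 >= 1 is rejected as physically
    unrealistic; when all candidates are rejected the residue is flagged
    unanalyzable.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observations for model selection")
    residue = observations[0].residue
    n = len(observations)
    candidates: list[MotionalParams] = []

    if global_tauc_ns is not None:
        x_simple, chi2_simple = _fit_continuous(observations, "s2", global_tauc_ns, constants)
        x_full, chi2_full = _fit_continuous(observations, "s2_tf", global_tauc_ns, constants)
        if f_test(chi2_simple, 1, chi2_full, 2, n, alpha):
            cand = MotionalParams(residue, "LS-MF", s2=float(x_full[0]),
                                  tau_f_ps=float(x_full[1]), tau_c_ns=global_tauc_ns,
                                  chi2=chi2_full)
        else:
            cand = MotionalParams(residue, "LS-MF", s2=float(x_simple[0]),
                                  tau_f_ps=0.0, tau_c_ns=global_tauc_ns, chi2=chi2_simple)
        if cand.s2 >= 1.0:
            cand.notes.append(f"rejected: unrealistic S^2 = {cand.s2:.2f}")
        candidates.append(cand)

    x_loc, chi2_loc = _fit_continuous(observations, "tc_s2", None, constants)
    loc = MotionalParams(residue, "local-MF", s2=float(x_loc[1]),
                         tau_c_local_ns=float(x_loc[0]), chi2=chi2_loc)
    if loc.s2 >= 1.0:
        loc.notes.append(f"rejected: unrealistic S^2 = {loc.s2:.2f}")
    candidates.append(loc)

    viable = [c for c in candidates if not any(n.startswith("rejected") for n in c.notes)]
    if not viable:
        out = MotionalParams(residue, "unanalyzable", s2=float("nan"))
        out.notes = [n for c in candidates for n in c.notes]
        return out
    best = min(viable, key=lambda c: c.chi2)
    if len(viable) > 1:
        best.notes.append("cross-family selection by chi^2 (families not nested)")
    return best


def back_calculate(
    observations: list[RateObservation],
    params_by_residue: dict[str, MotionalParams],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Pearson correlation between observed and back-calculated rates.

    Computed per rate-type over all residues and fields.  Rate types with
    fewer than three points get NaN.
    """
    obs_by_type: dict[str, tuple[list[float], list[float]]] = {}
    for obs in observations:
        p = params_by_residue.get(obs.residue)
        if p is None or p.model == "unanalyzable":
            continue
        calc = predict_observation(
            obs, p.s2, p.effective_tau_c_ns * NS, p.tau_f_ps * PS, constants
        )
        xs, ys = obs_by_type.setdefault(obs.rate_type, ([], []))
        xs.append(obs.value)
        ys.append(calc)
    out = {}
    for rate_type, (xs, ys) in obs_by_type.items():
        if len(xs) < 3:
            out[rate_type] = float("nan")
        else:
            out[rate_type] = float(stats.pearsonr(xs, ys).statistic)
    return out


# ---------------------------------------------------------------------------
# Stokes-Einstein stoichiometry
# ---------------------------------------------------------------------------

def hydrated_radius(mass_kda: float, vbar_ml_g: float = 0.73, r_water_angstrom: float = 2.0) -> float:
    """Stokes-Einstein hydrated radius in Angstrom.

    r_H = (3 V M / (4 pi N_A))^(1/3) + r_w with the molecular volume taken
    from the partial specific volume V (ml/g) and molar mass M.
    """
    if mass_kda <= 0 or vbar_ml_g <= 0 or r_water_angstrom < 0:
        raise ValueError("mass and specific volume must be positive; r_w >= 0")
    vol_cm3 = vbar_ml_g * mass_kda * 1000.0 / N_AVOGADRO   # cm^3 per molecule
    r_cm = (3.0 * vol_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return r_cm * 1e8 + r_water_angstrom


def stokes_einstein_ratio(
    mass1_kda: float,
    mass2_kda: float,
    vbar_ml_g: float = 0.73,
    r_water_angstrom: float = 2.0,
) -> float:
    """Predicted ratio tau_c(M2)/tau_c(M1) from hydrated-radius scaling.

    tau_c scales with the cube of the hydrated radius, so the ratio is
    (r_H(M2)/r_H(M1))^3.  With r_w = 0 this reduces exactly to M2/M1.
    """
    r1 = hydrated_radius(mass1_kda, vbar_ml_g, r_water_angstrom)
    r2 = hydrated_radius(mass2_kda, vbar_ml_g, r_water_angstrom)
    return (r2 / r1) ** 3
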