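"""Seeded synthetic-data generators for every analysis stage.

Each generator produces data through the same forward model its analysis
stage inverts — planted R-motifs for the sequence scanner, the exact
two-state quadratic for titrations, the model-free rate expressions plus
exponential decays for relaxation, and sphere/broad-peak/Gaussian forward
models for scattering — together with the ground truth, so recovery tests
never depend on external downloads.

A single top-level seed fans out deterministically to per-stage sub-seeds
via :func:`stage_seed` (SeedSequence spawning keyed by stage name), so
identical specs yield identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import binding, relax, sans
from .rmotif import ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STAGE_IDS = {"sequences": 0, "titration": 1, "relaxation": 2, "sans": 3}


def stage_seed(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one top-level seed."""
    ss = np.random.SeedSequence([seed, STAGE_IDS[stage]])
    return np.random.default_rng(ss)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset: stage, seed, ground truth block."""

    seed: int
    stage: str
    ground_truth: dict = dc_field(default_factory=dict)
    noise: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_motif(rng: np.random.Generator, n_args: int = None) -> str:
    """A single R-motif: arginines with gaps of 0-2 non-R residues."""
    if n_args is None:
        n_args = int(rng.integers(2, 5))
    non_r = AMINO_ACIDS.replace("R", "")
    parts = ["R"]
    for _ in range(n_args - 1):
        gap = int(rng.integers(0, 3))
        parts.append("".join(rng.choice(list(non_r), size=gap)) + "R")
    return "".join(parts)


def gen_sequences(
    n: int,
    mean_length: int = 300,
    plant_rate: float = 0.5,
    background_r_freq: float = 0.0,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[dict]]:
    """Random protein set with multivalent R-motif pairs planted at a known
    rate.

    A planted protein receives two motifs separated by at most 20 residues
    (a multivalent pair).  The background alphabet excludes arginine unless
    ``background_r_freq`` > 0, in which case isolated arginines appear at
    that frequency (never adjacent enough to the plants to merge, because
    plants are wrapped in a 3-residue R-free buffer).

    Returns the records and a truth table of dicts with keys ``id``,
    ``planted`` and ``spans``.
    """
    if not 0.0 <= plant_rate <= 1.0 or not 0.0 <= background_r_freq <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = stage_seed(seed, "sequences")
    non_r = AMINO_ACIDS.replace("R", "")
    records, truth = [], []
    for idx in range(n):
        length = max(40, int(rng.normal(mean_length, mean_length / 4)))
        if background_r_freq > 0:
            probs = np.full(20, (1 - background_r_freq) / 19)
            probs[AMINO_ACIDS.index("R")] = background_r_freq
            seq = list(rng.choice(list(AMINO_ACIDS), size=length, p=probs))
        else:
            seq = list(rng.choice(list(non_r), size=length))
        planted = bool(rng.random() < plant_rate)
        spans = []
        if planted:
            m1, m2 = _random_motif(rng), _random_motif(rng)
            # gap of 3-20 residues: close enough for multivalency, wide
            # enough that the two motifs never merge into one
            inter = int(rng.integers(3, 21))
            insert = m1 + "".join(rng.choice(list(non_r), size=inter)) + m2
            buffered = "AAA" + insert + "AAA"
            if len(buffered) > length:
                seq = list(rng.choice(list(non_r), size=len(buffered) + 10))
                length = len(seq)
            pos = int(rng.integers(0, length - len(buffered) + 1))
            seq[pos:pos + len(buffered)] = list(buffered)
            start1 = pos + 3 + 1  # 1-based first arginine
            spans = [
                (start1, start1 + len(m1) - 1),
                (start1 + len(m1) + inter, start1 + len(insert) - 1),
            ]
        rec = ProteinRecord(id=f"syn{idx:05d}", sequence="".join(seq))
        records.append(rec)
        truth.append({"id": rec.id, "planted": planted, "spans": spans})
    return records, truth


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

#: Nine-step ligand schedule up to a 3:1 ligand:protein ratio, emulating a
#: stepwise NMR titration design (concentrations in µM for Pt = 284 µM).
def default_lt_schedule(pt: float = 284.0, max_ratio: float = 3.0, n_additions: int = 9) -> np.ndarray:
    return np.linspace(0.0, max_ratio * pt, n_additions + 1)


def gen_titration(
    kd: float,
    dw_max: dict[str, float],
    pt: float = 284.0,
    lt: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> list[binding.TitrationSeries]:
    """Titration series from the exact two-state model plus Normal noise.

    ``dw_max`` maps residue label -> saturation shift (ppm).  The default
    ``noise_sd`` of 0.01 ppm reflects typical 15N chemical-shift measurement
    precision on well-resolved resonances.  The zero-ligand point is
    noise-free by construction (shifts are referenced to it).
    """
    rng = stage_seed(seed, "titration")
    if lt is None:
        lt = default_lt_schedule(pt)
    lt = np.asarray(lt, dtype=float)
    series = []
    for residue, dwm in dw_max.items():
        fb = binding.fraction_bound(pt, lt, kd)
        dw = dwm * fb + rng.normal(0.0, noise_sd, size=len(lt))
        dw[lt == 0.0] = 0.0
        series.append(binding.TitrationSeries(residue, pt, lt, dw))
    return series


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

DEFAULT_FIELDS_MHZ = (600.0, 800.0, 1000.0)


def gen_rate_observations(
    params: dict[str, relax.MotionalParams],
    fields_mhz: tuple[float, ...] = DEFAULT_FIELDS_MHZ,
    r1_fields_mhz: tuple[float, ...] = (800.0,),
    noise_frac: float = 0.0,
    seed: int = 0,
    constants: relax.PhysicalConstants = relax.DEFAULT_CONSTANTS,
) -> dict[str, list[relax.RateObservation]]:
    """Quantified-rate observations from model-free ground truth.

    eta_xy is generated at every field, R1 only at ``r1_fields_mhz``
    (longitudinal rates at a single field carry most of the fast-motion
    information at realistic precision).  ``noise_frac`` is the relative
    Gaussian noise; sigma is set to the noise level (or 2% of the rate when
    noiseless, as a weighting floor).
    """
    rng = stage_seed(seed, "relaxation")
    out: dict[str, list[relax.RateObservation]] = {}
    for residue, p in params.items():
        tau_c_s = p.effective_tau_c_ns * relax.NS
        tau_f_s = p.tau_f_ps * relax.PS
        obs = []
        for f in fields_mhz:
            eta, r1 = relax.predict_rates(f, p.s2, tau_c_s, tau_f_s, constants)
            sd = max(noise_frac * abs(eta), 0.02 * abs(eta))
            val = eta + (rng.normal(0.0, noise_frac * abs(eta)) if noise_frac > 0 else 0.0)
            obs.append(relax.RateObservation(residue, f, "eta_xy", float(val), float(sd)))
            if f in r1_fields_mhz:
                sd1 = max(noise_frac * abs(r1), 0.02 * abs(r1))
                v1 = r1 + (rng.normal(0.0, noise_frac * abs(r1)) if noise_frac > 0 else 0.0)
                obs.append(relax.RateObservation(residue, f, "R1", float(v1), float(sd1)))
        out[residue] = obs
    return out


def gen_decay_curves(
    rates: dict[str, float],
    rate_type: str = "R2_alpha",
    field_mhz: float = 800.0,
    delays: np.ndarray | None = None,
    i0: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[relax.DecayCurve]:
    """Exponential peak-intensity decays I(t) = I0 exp(-R t) plus noise."""
    rng = stage_seed(seed, "relaxation")
    curves = []
    for residue, rate in rates.items():
        t = np.asarray(delays, dtype=float) if delays is not None \
            else np.linspace(0.0, 3.0 / rate, 8)
        y = i0 * np.exp(-rate * t)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(t))
        curves.append(relax.DecayCurve(residue, field_mhz, rate_type, t,
                                       y, noise_sd if noise_sd > 0 else 1e-6))
    return curves


def core_cohort(
    n_residues: int,
    tau_c_ns: float,
    s2_range: tuple[float, float] = (0.75, 0.95),
    tau_f_choices: tuple[float, ...] = (0.0, 100.0),
    seed: int = 0,
) -> dict[str, relax.MotionalParams]:
    """Ground-truth folded-core cohort sharing one tumbling time.

    S^2 and tau_f are drawn on the grid (S^2 rounded to 0.01, tau_f from the
    supplied grid-step choices) so grid-search recovery is exact in the
    noiseless case.
    """
    rng = stage_seed(seed, "relaxation")
    params = {}
    for k in range(n_residues):
        s2 = float(np.round(rng.uniform(*s2_range), 2))
        tf = float(rng.choice(tau_f_choices))
        params[f"res{k:03d}"] = relax.MotionalParams(
            residue=f"res{k:03d}", model="LS-MF", s2=s2, tau_f_ps=tf, tau_c_ns=tau_c_ns
        )
    return params


# ---------------------------------------------------------------------------
# scattering
# ---------------------------------------------------------------------------

def _counting_sigma(i: np.ndarray, frac: float = 0.02) -> np.ndarray:
    """Counting-statistics-like error: sigma ~ frac * sqrt(I * I_max) + floor."""
    imax = float(np.max(np.abs(i)))
    return frac * np.sqrt(np.abs(i) * imax) + 1e-4 * imax


def gen_sans(
    kind: str,
    params: dict,
    q: np.ndarray | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> sans.ScatteringCurve:
    """Synthetic scattering curve on absolute scale with a sigma column.

    ``kind`` selects the forward model:

    * ``"sphere"`` — homogeneous sphere of ``radius`` (A), scaled to
      ``i0`` (1/cm);
    * ``"broad_peak"`` — the empirical broad-peak model with keys
      a, n, c, q0, xi, m, b;
    * ``"gaussians"`` — Gaussian peaks (``centers``, ``amplitudes``,
      ``widths``) on an optional linear baseline (``slope``, ``intercept``).
    """
    rng = stage_seed(seed, "sans")
    if q is None:
        q = np.linspace(0.004, 0.35, 300)
    q = np.asarray(q, dtype=float)
    if kind == "sphere":
        i = params.get("i0", 1.0) * sans.sphere_form_factor(q, params["radius"])
    elif kind == "broad_peak":
        i = sans.broad_peak_model(q, params["a"], params["n"], params["c"],
                                  params["q0"], params["xi"], params["m"], params["b"])
    elif kind == "gaussians":
        i = np.full_like(q, params.get("intercept", 0.0)) + params.get("slope", 0.0) * q
        for c0, amp, w in zip(params["centers"], params["amplitudes"], params["widths"]):
            i = i + amp * np.exp(-0.5 * ((q - c0) / w) ** 2)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    sigma = _counting_sigma(i, max(noise_frac, 0.005))
    if noise_frac > 0:
        i = i + rng.normal(0.0, noise_frac * np.sqrt(np.abs(i) * np.max(np.abs(i))))
    return sans.ScatteringCurve(q=q, i=i, sigma=sigma)
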