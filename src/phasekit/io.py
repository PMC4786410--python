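"""File I/O with strict schema and unit validation.

Table columns carry their units in the header (``delay_s``, ``Lt_uM``,
``field_MHz`` ...).  Readers reject files whose columns are missing or carry
the wrong unit suffix, naming the offending column, so a rate table in the
wrong units can never flow silently into an analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import binding, relax, sans
from .rmotif import NoLSInterval, ProteinRecord

logger = logging.getLogger(__name__)

TITRATION_COLUMNS = ["residue", "Pt_uM", "Lt_uM", "dw_ppm"]
DECAY_COLUMNS = ["residue", "field_MHz", "rate_type", "delay_s", "intensity", "noise_sd"]
RATE_COLUMNS = ["residue", "field_MHz", "R2a_s1", "R2a_sd_s1", "R2b_s1", "R2b_sd_s1",
                "R1_s1", "R1_sd_s1"]
NOLS_COLUMNS = ["id", "start", "end"]


class SchemaError(ValueError):
    """A table failed schema/unit validation."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing or wrongly-united column(s) {missing}; "
            f"expected columns {required} (units are part of the column name)"
        )


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly wrapped, CRLF-tolerant) multi-record FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).strip()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_nols_tsv(path) -> list[NoLSInterval]:
    """NoLS intervals: TSV with columns id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, NOLS_COLUMNS, path)
    return [NoLSInterval(str(r.id), int(r.start), int(r.end)) for r in df.itertuples()]


def read_titration_tsv(path) -> list[binding.TitrationSeries]:
    """Long-format titration table: residue, Pt_uM, Lt_uM, dw_ppm."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TITRATION_COLUMNS, path)
    out = []
    for residue, grp in df.groupby("residue", sort=False):
        grp = grp.sort_values("Lt_uM")
        pt = grp["Pt_uM"].iloc[0]
        if grp["Pt_uM"].nunique() > 1:
            raise SchemaError(f"{path}: residue {residue} has non-constant Pt_uM")
        out.append(binding.TitrationSeries(
            str(residue), float(pt),
            grp["Lt_uM"].to_numpy(float), grp["dw_ppm"].to_numpy(float),
        ))
    return out


def write_titration_tsv(path, series_set: list[binding.TitrationSeries]) -> None:
    rows = []
    for s in series_set:
        for lt, dw in zip(s.ligand_totals, s.delta_omega):
            rows.append({"residue": s.residue, "Pt_uM": s.protein_total,
                         "Lt_uM": lt, "dw_ppm": dw})
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_decay_tsv(path) -> list[relax.DecayCurve]:
    """Decay table: residue, field_MHz, rate_type, delay_s, intensity, noise_sd."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, DECAY_COLUMNS, path)
    curves = []
    for (residue, field, rate_type), grp in df.groupby(
        ["residue", "field_MHz", "rate_type"], sort=False
    ):
        grp = grp.sort_values("delay_s")
        curves.append(relax.DecayCurve(
            str(residue), float(field), str(rate_type),
            grp["delay_s"].to_numpy(float),
            grp["intensity"].to_numpy(float),
            grp["noise_sd"].to_numpy(float),
        ))
    return curves


def read_rate_tsv(path) -> list[relax.RelaxationRecord]:
    """Pre-quantified rate table (all rates in s^-1)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, RATE_COLUMNS, path)
    return [
        relax.RelaxationRecord(
            residue=str(r.residue), field_mhz=float(r.field_MHz),
            r2_alpha=float(r.R2a_s1), r2_alpha_sd=float(r.R2a_sd_s1),
            r2_beta=float(r.R2b_s1), r2_beta_sd=float(r.R2b_sd_s1),
            r1=float(r.R1_s1), r1_sd=float(r.R1_sd_s1),
        )
        for r in df.itertuples()
    ]


def write_rate_tsv(path, records: list[relax.RelaxationRecord]) -> None:
    rows = [
        {"residue": r.residue, "field_MHz": r.field_mhz,
         "R2a_s1": r.r2_alpha, "R2a_sd_s1": r.r2_alpha_sd,
         "R2b_s1": r.r2_beta, "R2b_sd_s1": r.r2_beta_sd,
         "R1_s1": r.r1, "R1_sd_s1": r.r1_sd}
        for r in records
    ]
    pd.DataFrame(rows, columns=RATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dat(path) -> sans.ScatteringCurve:
    """3-column scattering text file (q, I, sigma); '#' comments; whitespace
    or comma delimited.  The sigma column is optional."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        try:
            rows.append([float(x) for x in parts[:3]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if not rows:
        raise ValueError(f"{path}: no data lines")
    arr = np.asarray([r + [np.nan] * (3 - len(r)) for r in rows])
    sigma = arr[:, 2] if not np.all(np.isnan(arr[:, 2])) else None
    return sans.ScatteringCurve(q=arr[:, 0], i=arr[:, 1], sigma=sigma)


def write_dat(path, curve: sans.ScatteringCurve) -> None:
    with open(path, "w") as fh:
        fh.write("# q_invA I_invcm sigma_invcm\n")
        sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
        for q, i, s in zip(curve.q, curve.i, sigma):
            fh.write(f"{q:.8g} {i:.8g} {s:.8g}\n")


def write_json(path, payload: dict) -> None:
    """JSON report writer tolerant of numpy scalars and arrays."""
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
        fh.write("\n")
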