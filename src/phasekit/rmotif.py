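"""Arginine-rich short linear motif (R-motif) detection and set statistics.

An R-motif is a run of arginines in which consecutive arginines are separated
by at most two intervening residues (``RX<=2R`` extended greedily).  A protein
is *multivalent* when two such motifs occur close together in sequence: the
gap between the last arginine of one motif and the first arginine of the next
is at most 20 residues.  Multivalent R-motifs mediate binding to the acidic
tracts of nucleophosmin (NPM1) and drive liquid-liquid phase separation; they
also coincide extensively with predicted nucleolar localization signals
(NoLS), which is why this module can intersect motif spans with externally
supplied NoLS intervals.

Coordinates are 1-based inclusive throughout, matching the residue numbering
conventions of structural biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The 20 standard residues plus X for unknown.  Ambiguity codes B/Z/X never
#: count as arginine.
VALID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Maximum number of residues between consecutive arginines inside one motif.
DEFAULT_MAX_INNER_GAP = 2

#: Maximum number of residues between consecutive motifs for multivalency.
DEFAULT_MAX_MOTIF_GAP = 20


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier.

    The sequence must be non-empty, upper-case, and restricted to the 20
    standard one-letter codes plus ``X``.  Lower-case input is accepted and
    normalized with a warning.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        seq = self.sequence
        if seq != seq.upper():
            logger.warning("protein %s: lower-case sequence normalized to upper-case", self.id)
            object.__setattr__(self, "sequence", seq.upper())
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue code(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A maximal R-motif span, 1-based inclusive, with its arginine count."""

    start: int
    end: int
    arg_count: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}-{self.end}]")
        if self.arg_count < 2:
            raise ValueError("an R-motif requires at least two arginines")

    def overlaps(self, start: int, end: int) -> bool:
        """True when [start, end] shares at least one residue with this hit."""
        return self.start <= end and start <= self.end


@dataclass
class ValencyReport:
    """Per-protein motif inventory and multivalency classification."""

    id: str
    hits: list[MotifHit]
    multivalent: bool
    gaps: list[int] = field(default_factory=list)

    @property
    def valency(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class NoLSInterval:
    """Externally predicted nucleolar localization signal span (1-based)."""

    id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"NoLS interval start {self.start} > end {self.end}")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 proportion comparison between two protein sets."""

    k1: int
    n1: int
    k2: int
    n2: int
    p_value: float

    @property
    def p1(self) -> float:
        return self.k1 / self.n1

    @property
    def p2(self) -> float:
        return self.k2 / self.n2


def find_motifs(
    record: ProteinRecord, max_inner_gap: int = DEFAULT_MAX_INNER_GAP
) -> list[MotifHit]:
    """Find all maximal R-motifs in a protein sequence.

    Arginines are chained greedily: an arginine joins the current motif when
    it lies within ``max_inner_gap`` residues of the motif's last arginine.
    Chains with a single arginine are not motifs.  The returned hits are
    maximal, non-overlapping and sorted by start position.
    """
    seq = record.sequence
    r_positions = [i + 1 for i, aa in enumerate(seq) if aa == "R"]
    hits: list[MotifHit] = []
    if not r_positions:
        return hits
    chain = [r_positions[0]]
    for pos in r_positions[1:]:
        if pos - chain[-1] - 1 <= max_inner_gap:
            chain.append(pos)
        else:
            if len(chain) >= 2:
                hits.append(MotifHit(chain[0], chain[-1], len(chain)))
            chain = [pos]
    if len(chain) >= 2:
        hits.append(MotifHit(chain[0], chain[-1], len(chain)))
    return hits


def classify_valency(
    hits: list[MotifHit],
    max_gap: int | float = DEFAULT_MAX_MOTIF_GAP,
    any_pair: bool = False,
) -> ValencyReport:
    """Classify a protein's valency from its motif hits.

    A protein is multivalent when some pair of *consecutive* motifs is
    separated by at most ``max_gap`` residues (residues strictly between the
    last arginine of one motif and the first arginine of the next).  Set
    ``any_pair=True`` to consider every motif pair rather than consecutive
    ones only; with the gap measured between consecutive sorted motifs the
    two are equivalent, the flag exists for auditability.
    """
    hits = sorted(hits, key=lambda h: h.start)
    gaps = [b.start - a.end - 1 for a, b in zip(hits, hits[1:])]
    if any_pair:
        pair_gaps = [
            hits[j].start - hits[i].end - 1
            for i in range(len(hits))
            for j in range(i + 1, len(hits))
        ]
        multivalent = any(g <= max_gap for g in pair_gaps)
    else:
        multivalent = any(g <= max_gap for g in gaps)
    return ValencyReport(id="", hits=hits, multivalent=multivalent, gaps=gaps)


def scan_record(
    record: ProteinRecord,
    max_inner_gap: int = DEFAULT_MAX_INNER_GAP,
    max_motif_gap: int | float = DEFAULT_MAX_MOTIF_GAP,
) -> ValencyReport:
    """Scan one protein: motif detection followed by valency classification."""
    hits = find_motifs(record, max_inner_gap=max_inner_gap)
    report = classify_valency(hits, max_gap=max_motif_gap)
    report.id = record.id
    return report


def scan_set(
    records: list[ProteinRecord],
    max_inner_gap: int = DEFAULT_MAX_INNER_GAP,
    max_motif_gap: int | float = DEFAULT_MAX_MOTIF_GAP,
) -> pd.DataFrame:
    """Scan a protein set; one row per protein.

    Columns: ``id``, ``length``, ``n_motifs``, ``multivalent``, ``motifs``
    (spans formatted ``start-end;...``).  Duplicate ids are logged and the
    last record wins.
    """
    seen: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.id in seen:
            logger.warning("duplicate protein id %s: keeping the last record", rec.id)
        seen[rec.id] = rec
    rows = []
    for rec in seen.values():
        report = scan_record(rec, max_inner_gap, max_motif_gap)
        rows.append(
            {
                "id": rec.id,
                "length": len(rec),
                "n_motifs": report.valency,
                "multivalent": report.multivalent,
                "motifs": ";".join(f"{h.start}-{h.end}" for h in report.hits),
            }
        )
    return pd.DataFrame(rows, columns=["id", "length", "n_motifs", "multivalent", "motifs"])


def summarize_scan(table: pd.DataFrame) -> dict:
    """Set-level proportions from a scan table."""
    n = len(table)
    if n == 0:
        return {"n_proteins": 0, "frac_with_motif": float("nan"), "frac_multivalent": float("nan")}
    return {
        "n_proteins": n,
        "frac_with_motif": float((table["n_motifs"] >= 1).mean()),
        "frac_multivalent": float(table["multivalent"].mean()),
    }


def enrichment_test(
    k1: int, n1: int, k2: int, n2: int, method: str = "fisher"
) -> EnrichmentResult:
    """Two-sided test for a difference in proportions k1/n1 vs k2/n2.

    ``method='fisher'`` (default) is the exact test on the 2x2 table;
    ``method='chi2'`` is the chi-square test with continuity correction.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("set size must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if method == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif method == "chi2":
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(k1, n1, k2, n2, p_value=float(p))


def nols_overlap(
    reports: list[ValencyReport],
    intervals: list[NoLSInterval],
    sequence_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Intersect motif spans with predicted NoLS intervals.

    Returns one row per protein in ``reports`` with whether the protein has
    any predicted NoLS, and whether any of its motif spans shares at least one
    residue with any of its NoLS intervals.  Intervals extending past the
    known sequence length are clipped with a warning.
    """
    by_id: dict[str, list[NoLSInterval]] = {}
    for iv in intervals:
        if sequence_lengths and iv.id in sequence_lengths:
            length = sequence_lengths[iv.id]
            if iv.end > length:
                logger.warning(
                    "NoLS interval %s [%d-%d] exceeds sequence length %d: clipped",
                    iv.id, iv.start, iv.end, length,
                )
                if iv.start > length:
                    continue
                iv = NoLSInterval(iv.id, iv.start, length)
        by_id.setdefault(iv.id, []).append(iv)
    rows = []
    for report in reports:
        ivs = by_id.get(report.id, [])
        overlap = any(
            hit.overlaps(iv.start, iv.end) for hit in report.hits for iv in ivs
        )
        rows.append(
            {
                "id": report.id,
                "n_motifs": report.valency,
                "multivalent": report.multivalent,
                "has_nols": bool(ivs),
                "motif_nols_overlap": overlap,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "n_motifs", "multivalent", "has_nols", "motif_nols_overlap"]
    )


def summarize_nols(table: pd.DataFrame) -> dict:
    """Set-level NoLS statistics: how many scanned proteins carry a predicted
    NoLS, and what fraction of those are multivalent."""
    with_nols = table[table["has_nols"]]
    n_nols = len(with_nols)
    return {
        "n_proteins": int(len(table)),
        "n_with_nols": int(n_nols),
        "n_with_nols_multivalent": int(with_nols["multivalent"].sum()) if n_nols else 0,
        "frac_nols_multivalent": float(with_nols["multivalent"].mean()) if n_nols else float("nan"),
        "frac_overlap": float(with_nols["motif_nols_overlap"].mean()) if n_nols else float("nan"),
    }
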