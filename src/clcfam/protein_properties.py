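"""Physicochemical profiling of protein sequences.

Length, molecular weight (average residue masses), isoelectric point
(Henderson-Hasselbalch net charge with the Bjellqvist pKa set, solved by
bisection), GRAVY (mean Kyte-Doolittle hydropathy) and a simple
hydropathy-window transmembrane-segment predictor.

The TM predictor is a documented sliding-window heuristic (window 19,
threshold 1.6), not an HMM; its counts are descriptive output only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .family_identification import AMINO_ACIDS, CLCCandidate

__all__ = [
    "PropertyTables",
    "PropertyProfile",
    "DEFAULT_TABLES",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "gravy",
    "predict_tmh",
    "property_table",
    "write_property_table",
]

# Average (isotope-weighted) residue masses in Da, and the mass of water.
_AVERAGE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.0153

# Bjellqvist pKa set.  Terminal pKa values depend on the terminal residue.
_PKA_NTERM = {
    "A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70,
}
_PKA_NTERM_DEFAULT = 7.50
_PKA_CTERM = {"D": 4.55, "E": 4.75}
_PKA_CTERM_DEFAULT = 3.55
_PKA_POSITIVE = {"K": 10.00, "R": 12.00, "H": 5.98}
_PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}

# Kyte-Doolittle hydropathy scale.
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class PropertyTables:
    """The residue-level constants every property computation draws from."""

    mass_table: dict[str, float] = field(default_factory=lambda: dict(_AVERAGE_MASS))
    water_mass: float = _WATER
    pka_nterm: dict[str, float] = field(default_factory=lambda: dict(_PKA_NTERM))
    pka_nterm_default: float = _PKA_NTERM_DEFAULT
    pka_cterm: dict[str, float] = field(default_factory=lambda: dict(_PKA_CTERM))
    pka_cterm_default: float = _PKA_CTERM_DEFAULT
    pka_positive: dict[str, float] = field(default_factory=lambda: dict(_PKA_POSITIVE))
    pka_negative: dict[str, float] = field(default_factory=lambda: dict(_PKA_NEGATIVE))
    kd_scale: dict[str, float] = field(default_factory=lambda: dict(_KD))

    def __post_init__(self) -> None:
        for name, table in (("mass_table", self.mass_table), ("kd_scale", self.kd_scale)):
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"{name} missing residues {sorted(missing)}")


DEFAULT_TABLES = PropertyTables()


@dataclass
class PropertyProfile:
    """Per-protein physicochemical summary (spans 1-based inclusive)."""

    protein_id: str
    length: int
    mw: float
    pi: float
    gravy: float
    tmh_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mw <= 0:
            raise ValueError("length and mw must be positive")
        if not 0 < self.pi < 14:
            raise ValueError("pi out of range")
        prev_end = 0
        for s, e in self.tmh_segments:
            if s <= prev_end or e < s or e > self.length:
                raise ValueError("tmh segments must be ordered, disjoint, in bounds")
            prev_end = e

    @property
    def tmh_count(self) -> int:
        return len(self.tmh_segments)


def molecular_weight(sequence: str, tables: PropertyTables = DEFAULT_TABLES) -> float:
    """Molecular weight in Da: sum of residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        total = sum(tables.mass_table[ch] for ch in sequence)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} has no defined mass") from exc
    return total + tables.water_mass


def net_charge(
    sequence: str, ph: float, tables: PropertyTables = DEFAULT_TABLES
) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Positive contributions: N-terminus, K, R, H.  Negative: C-terminus,
    D, E, C, Y.  X residues carry no charge.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pos_pkas = [tables.pka_nterm.get(sequence[0], tables.pka_nterm_default)]
    neg_pkas = [tables.pka_cterm.get(sequence[-1], tables.pka_cterm_default)]
    for ch in sequence:
        if ch in tables.pka_positive:
            pos_pkas.append(tables.pka_positive[ch])
        elif ch in tables.pka_negative:
            neg_pkas.append(tables.pka_negative[ch])
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos_pkas)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg_pkas)
    return charge


def isoelectric_point(
    sequence: str, tables: PropertyTables = DEFAULT_TABLES, tol: float = 1e-4
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The net charge is strictly decreasing in pH, so the root is always
    bracketed.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, tables) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str, tables: PropertyTables = DEFAULT_TABLES) -> float:
    """Grand average of hydropathy; X residues are excluded from the mean."""
    if not sequence:
        raise ValueError("empty sequence")
    vals = [tables.kd_scale[ch] for ch in sequence if ch != "X"]
    if not vals:
        raise ValueError("sequence contains no canonical residues")
    return sum(vals) / len(vals)


def predict_tmh(
    sequence: str,
    tables: PropertyTables = DEFAULT_TABLES,
    window: int = 19,
    threshold: float = 1.6,
) -> list[tuple[int, int]]:
    """Hydropathy-window transmembrane segments, 1-based inclusive spans.

    A window centre qualifies when the mean Kyte-Doolittle value over the
    window is >= ``threshold`` (X scores 0).  Maximal runs of qualifying
    centres are expanded to full window extent and overlapping expansions
    are merged.  Sequences shorter than the window yield no segments.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = len(sequence)
    if n < window:
        return []
    vals = [tables.kd_scale.get(ch, 0.0) for ch in sequence]
    half = window // 2
    # rolling window means
    csum = [0.0]
    for v in vals:
        csum.append(csum[-1] + v)
    segments: list[tuple[int, int]] = []
    run_start: int | None = None
    for centre in range(half, n - half):
        mean = (csum[centre + half + 1] - csum[centre - half]) / window
        if mean >= threshold:
            if run_start is None:
                run_start = centre
        elif run_start is not None:
            segments.append((run_start - half + 1, centre - 1 + half + 1))
            run_start = None
    if run_start is not None:
        segments.append((run_start - half + 1, n - half - 1 + half + 1))
    merged: list[tuple[int, int]] = []
    for s, e in segments:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def property_table(
    candidates: Sequence[CLCCandidate], tables: PropertyTables = DEFAULT_TABLES
) -> list[PropertyProfile]:
    """One property profile per candidate, input order preserved."""
    profiles = []
    for cand in candidates:
        seq = cand.protein.sequence
        profiles.append(
            PropertyProfile(
                protein_id=cand.protein.id,
                length=len(seq),
                mw=molecular_weight(seq, tables),
                pi=isoelectric_point(seq, tables),
                gravy=gravy(seq, tables),
                tmh_segments=predict_tmh(seq, tables),
            )
        )
    return profiles


def write_property_table(
    profiles: Sequence[PropertyProfile],
    path: str | Path,
    sep: str = "\t",
    mw_decimals: int = 1,
    pi_decimals: int = 2,
    gravy_decimals: int = 3,
) -> None:
    """Write the summary table; Mw reported in kDa."""
    with open(path, "w") as fh:
        fh.write(sep.join(["id", "length", "mw_kda", "pi", "gravy", "tmh_count"]) + "\n")
        for p in profiles:
            fh.write(
                sep.join(
                    [
                        p.protein_id,
                        str(p.length),
                        f"{p.mw / 1000:.{mw_decimals}f}",
                        f"{p.pi:.{pi_decimals}f}",
                        f"{p.gravy:.{gravy_decimals}f}",
                        str(p.tmh_count),
                    ]
                )
                + "\n"
            )
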