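"""Conserved-region location and anion selectivity / transport classification.

Three conserved regions are searched per sequence:

* region I   ``GxGIPE``   — the wildcard is the selectivity residue
  (P -> NO3- preference, S -> Cl- preference);
* region II  ``GKxGPxxH`` — an E at the first wildcard is the gating
  glutamate;
* region III ``PxxGxLF``  — an E four residues past the match end is the
  proton glutamate.

A protein with both glutamates is called an antiporter; with at least
one determinately absent, a channel; otherwise it stays unclassified.
Selectivity and transport class are independent axes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from .family_identification import AMINO_ACIDS, DomainHit, ProteinRecord

__all__ = [
    "RegionPattern",
    "ConservedRegionMatch",
    "CLCClassification",
    "Presence",
    "Selectivity",
    "TransportClass",
    "DEFAULT_REGIONS",
    "find_region",
    "call_selectivity",
    "detect_gating_glutamate",
    "detect_proton_glutamate",
    "classify_transport",
    "classify_protein",
    "classify_many",
    "classify_from_alignment",
    "write_classification_table",
]


class Presence(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNDETERMINED = "undetermined"


class Selectivity(str, Enum):
    NO3 = "NO3-"
    CL = "Cl-"
    UNKNOWN = "unknown"


class TransportClass(str, Enum):
    ANTIPORTER = "antiporter"
    CHANNEL = "channel"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class RegionPattern:
    """A conserved-region pattern; ``x`` is a wildcard over the 20
    canonical residues (never X)."""

    region_id: str
    pattern: str
    key_offset: int | None = None  # 1-based position of the diagnostic residue
    downstream_offset: int | None = None  # residues past match end (region III)

    def __post_init__(self) -> None:
        if len(self.pattern) < 6:
            raise ValueError("pattern must be at least 6 residues")
        if self.key_offset is not None and not 1 <= self.key_offset <= len(self.pattern):
            raise ValueError("key_offset outside pattern")

    def regex(self) -> re.Pattern[str]:
        wildcard = f"[{AMINO_ACIDS}]"
        return re.compile(
            "".join(wildcard if ch == "x" else re.escape(ch) for ch in self.pattern)
        )


DEFAULT_REGIONS: dict[str, RegionPattern] = {
    "I": RegionPattern("I", "GxGIPE", key_offset=2),
    "II": RegionPattern("II", "GKxGPxxH", key_offset=3),
    "III": RegionPattern("III", "PxxGxLF", downstream_offset=4),
}


@dataclass(frozen=True)
class ConservedRegionMatch:
    """A located conserved region (1-based inclusive span)."""

    protein_id: str
    region_id: str
    start: int
    end: int
    matched_text: str
    key_residue: str | None = None


def find_region(
    protein: ProteinRecord,
    pattern: RegionPattern,
    domain_span: DomainHit | None = None,
) -> ConservedRegionMatch | None:
    """Leftmost occurrence of the pattern, optionally restricted to a
    domain span.  Returns ``None`` when the pattern does not occur."""
    seq = protein.sequence
    lo, hi = 0, len(seq)
    if domain_span is not None:
        lo, hi = domain_span.start - 1, domain_span.end
    m = pattern.regex().search(seq, lo, hi)
    if m is None:
        return None
    key = None
    if pattern.key_offset is not None:
        key = m.group(0)[pattern.key_offset - 1]
    return ConservedRegionMatch(
        protein_id=protein.id,
        region_id=pattern.region_id,
        start=m.start() + 1,
        end=m.end(),
        matched_text=m.group(0),
        key_residue=key,
    )


def call_selectivity(match_i: ConservedRegionMatch | None) -> Selectivity:
    """P at the region-I wildcard -> NO3-; S -> Cl-; otherwise unknown."""
    if match_i is None or match_i.key_residue is None:
        return Selectivity.UNKNOWN
    if match_i.key_residue == "P":
        return Selectivity.NO3
    if match_i.key_residue == "S":
        return Selectivity.CL
    return Selectivity.UNKNOWN


def detect_gating_glutamate(match_ii: ConservedRegionMatch | None) -> Presence:
    """Gating glutamate: E at the region-II key position."""
    if match_ii is None or match_ii.key_residue is None:
        return Presence.UNDETERMINED
    return Presence.PRESENT if match_ii.key_residue == "E" else Presence.ABSENT


def detect_proton_glutamate(
    protein: ProteinRecord,
    match_iii: ConservedRegionMatch | None,
    offset: int = 4,
) -> Presence:
    """Proton glutamate: E at ``offset`` residues past the region-III end."""
    if match_iii is None:
        return Presence.UNDETERMINED
    pos = match_iii.end + offset  # 1-based
    if pos > len(protein.sequence):
        return Presence.UNDETERMINED
    return (
        Presence.PRESENT
        if protein.sequence[pos - 1] == "E"
        else Presence.ABSENT
    )


@dataclass
class CLCClassification:
    """Per-protein classification record."""

    protein_id: str
    matches: dict[str, ConservedRegionMatch | None]
    selectivity_residue: str | None
    selectivity: Selectivity
    gating_glutamate: Presence
    proton_glutamate: Presence
    transport_class: TransportClass


def classify_transport(gating: Presence, proton: Presence) -> TransportClass:
    """Combine the two glutamate calls into a transport class.

    Antiporter iff both present; channel if at least one is
    determinately absent; unclassified otherwise (some signal
    undetermined and none absent).
    """
    if gating is Presence.PRESENT and proton is Presence.PRESENT:
        return TransportClass.ANTIPORTER
    if Presence.ABSENT in (gating, proton):
        return TransportClass.CHANNEL
    return TransportClass.UNCLASSIFIED


def classify_protein(
    protein: ProteinRecord,
    regions: Mapping[str, RegionPattern] = DEFAULT_REGIONS,
    domain_span: DomainHit | None = None,
    proton_offset: int | None = None,
) -> CLCClassification:
    """Locate the three regions in one sequence and classify it."""
    matches = {
        rid: find_region(protein, pat, domain_span) for rid, pat in regions.items()
    }
    m1, m2, m3 = matches.get("I"), matches.get("II"), matches.get("III")
    if proton_offset is None:
        pat3 = regions.get("III")
        proton_offset = (
            pat3.downstream_offset if pat3 and pat3.downstream_offset else 4
        )
    selectivity = call_selectivity(m1)
    gating = detect_gating_glutamate(m2)
    proton = detect_proton_glutamate(protein, m3, offset=proton_offset)
    return CLCClassification(
        protein_id=protein.id,
        matches=matches,
        selectivity_residue=m1.key_residue if m1 else None,
        selectivity=selectivity,
        gating_glutamate=gating,
        proton_glutamate=proton,
        transport_class=classify_transport(gating, proton),
    )


def classify_many(
    proteins: Sequence[ProteinRecord],
    regions: Mapping[str, RegionPattern] = DEFAULT_REGIONS,
    domain_spans: Mapping[str, DomainHit] | None = None,
    proton_offset: int | None = None,
) -> list[CLCClassification]:
    spans = domain_spans or {}
    return [
        classify_protein(p, regions, spans.get(p.id), proton_offset) for p in proteins
    ]


def classify_from_alignment(
    rows: Sequence[tuple[str, str]],
    reference_id: str,
    regions: Mapping[str, RegionPattern] = DEFAULT_REGIONS,
    proton_offset: int = 4,
) -> list[CLCClassification]:
    """Column-anchored classification mode.

    The regions are located in the ungapped reference row; every other
    row is read at the alignment columns of those matches (and of the
    proton-glutamate site).  Rows whose residues at the anchored columns
    do not form a region match fall back to undetermined calls.
    """
    by_id = dict(rows)
    if reference_id not in by_id:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref_gapped = by_id[reference_id]
    ref_seq = ref_gapped.replace("-", "")
    # residue index (0-based) -> alignment column
    col_of: list[int] = [i for i, ch in enumerate(ref_gapped) if ch != "-"]
    ref_protein = ProteinRecord(id=reference_id, sequence=ref_seq)
    out: list[CLCClassification] = []
    anchor: dict[str, tuple[list[int], RegionPattern]] = {}
    proton_col: int | None = None
    for rid, pat in regions.items():
        m = find_region(ref_protein, pat)
        if m is None:
            continue
        cols = [col_of[i] for i in range(m.start - 1, m.end)]
        anchor[rid] = (cols, pat)
        if rid == "III":
            pos = m.end + proton_offset  # 1-based residue in reference
            if pos <= len(ref_seq):
                proton_col = col_of[pos - 1]
    for row_id, gapped in rows:
        matches: dict[str, ConservedRegionMatch | None] = {}
        for rid, pat in regions.items():
            matches[rid] = None
            if rid not in anchor:
                continue
            cols, pat = anchor[rid]
            text = "".join(gapped[c] for c in cols)
            if pat.regex().fullmatch(text):
                key = text[pat.key_offset - 1] if pat.key_offset else None
                matches[rid] = ConservedRegionMatch(
                    protein_id=row_id,
                    region_id=rid,
                    start=cols[0] + 1,  # alignment-column coordinates
                    end=cols[-1] + 1,
                    matched_text=text,
                    key_residue=key,
                )
        m1, m2, m3 = matches.get("I"), matches.get("II"), matches.get("III")
        gating = detect_gating_glutamate(m2)
        if m3 is None or proton_col is None or gapped[proton_col] == "-":
            proton = Presence.UNDETERMINED
        else:
            proton = (
                Presence.PRESENT if gapped[proton_col] == "E" else Presence.ABSENT
            )
        out.append(
            CLCClassification(
                protein_id=row_id,
                matches=matches,
                selectivity_residue=m1.key_residue if m1 else None,
                selectivity=call_selectivity(m1),
                gating_glutamate=gating,
                proton_glutamate=proton,
                transport_class=classify_transport(gating, proton),
            )
        )
    return out


def write_classification_table(
    classifications: Sequence[CLCClassification], path: str | Path, sep: str = "\t"
) -> None:
    cols = [
        "id", "region_I", "region_II", "region_III", "selectivity_residue",
        "selectivity", "gating_glutamate", "proton_glutamate", "transport_class",
    ]

    def span(m: ConservedRegionMatch | None) -> str:
        return f"{m.start}..{m.end}" if m else "."

    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for c in classifications:
            fh.write(
                sep.join(
                    [
                        c.protein_id,
                        span(c.matches.get("I")),
                        span(c.matches.get("II")),
                        span(c.matches.get("III")),
                        c.selectivity_residue or ".",
                        c.selectivity.value,
                        c.gating_glutamate.value,
                        c.proton_glutamate.value,
                        c.transport_class.value,
                    ]
                )
                + "\n"
            )
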