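"""Identification of CLC candidate proteins by domain scanning.

Locates Voltage_CLC and CBS domains in protein sequences, either by
ingesting HMMER3 per-domain tabular output ("domtblout") or with a
built-in log-odds profile scanner, and filters candidates at an E-value
cutoff (default 1e-10).  All residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "DomainProfile",
    "DomainHit",
    "CLCCandidate",
    "read_fasta",
    "write_fasta",
    "parse_domtblout",
    "profile_from_consensus",
    "calibrate_profile",
    "scan_profile",
    "collapse_isoforms",
    "filter_candidates",
    "write_candidate_table",
    "DEFAULT_E_CUTOFF",
]

#: The 20 canonical amino acids, fixed column order for profile matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_VALID_CHARS = set(AMINO_ACIDS) | {"X"}

DEFAULT_E_CUTOFF = 1e-10


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier.

    ``sequence`` is uppercase, whitespace-free and restricted to the 20
    canonical residues plus the ambiguity letter ``X``.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """A located domain instance, coordinates 1-based inclusive."""

    protein_id: str
    domain: str
    start: int
    end: int
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"hit {self.domain} on {self.protein_id}: "
                f"invalid span {self.start}..{self.end}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainProfile:
    """Positional log-odds profile for window scanning.

    ``log_odds`` has shape (length, 20) in bits relative to the
    background; the ambiguity letter X always scores 0.  E-values come
    from a Gumbel fit (``evalue_loc``/``evalue_scale``) to best-window
    scores of shuffled null sequences (see :func:`calibrate_profile`),
    multiplied by the number of windows scanned.
    """

    name: str
    log_odds: np.ndarray
    bit_threshold: float
    evalue_loc: float = 0.0
    evalue_scale: float = 1.0

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != len(AMINO_ACIDS):
            raise ValueError("log_odds must have shape (length, 20)")
        if not math.isfinite(self.bit_threshold):
            raise ValueError("bit_threshold must be finite")
        if self.evalue_scale <= 0:
            raise ValueError("evalue_scale must be positive")

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[0])

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def evalue(self, score: float, n_windows: int) -> float:
        p = float(stats.gumbel_r.sf(score, loc=self.evalue_loc, scale=self.evalue_scale))
        return p * max(1, n_windows)


@dataclass
class CLCCandidate:
    """A protein together with its domain evidence and the filter verdict."""

    protein: ProteinRecord
    voltage_clc_hits: list[DomainHit] = field(default_factory=list)
    cbs_hits: list[DomainHit] = field(default_factory=list)
    passed_filter: bool = False

    @property
    def best_evalue(self) -> float:
        if not self.voltage_clc_hits:
            return math.inf
        return min(h.evalue for h in self.voltage_clc_hits)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

_SPECIES_RE = re.compile(r"species=(\S+)")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The first whitespace-delimited token of each header is the record id;
    a ``species=NAME`` token in the description, if present, fills the
    species field.  Wrapped sequence lines are joined and case-folded to
    uppercase; a single trailing ``*`` (stop) is dropped.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        entries = list(SimpleFastaParser(fh))
    if not entries:
        raise FastaParseError(f"{path}: no FASTA records found")
    for header, seq in entries:
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise FastaParseError(f"{path}: record with empty header")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        m = _SPECIES_RE.search(header)
        species = m.group(1) if m else ""
        seq = seq.replace(" ", "").replace("\t", "").upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise FastaParseError(f"{path}: internal stop '*' in record {rid!r}")
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise FastaParseError(
                f"{path}: record {rid!r} has invalid residue(s) {sorted(bad)}"
            )
        if not seq:
            raise FastaParseError(f"{path}: record {rid!r} has empty sequence")
        records.append(ProteinRecord(id=rid, sequence=seq, species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.species else f"{rec.id} species={rec.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# HMMER3 per-domain table ingestion
# ---------------------------------------------------------------------------

def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain tabular file into domain hits.

    Uses the envelope coordinates (columns 20-21), the per-domain
    independent E-value (column 13) and the per-domain bit score
    (column 14), all 1-based column numbers of the standard layout.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    domain=fields[3],
                    start=int(fields[19]),
                    end=int(fields[20]),
                    bit_score=float(fields[13]),
                    evalue=float(fields[12]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Built-in profile scanning
# ---------------------------------------------------------------------------

def profile_from_consensus(
    name: str,
    consensus: str,
    match_prob: float = 0.9,
    bit_threshold: float | None = None,
) -> DomainProfile:
    """Build a log-odds profile from a consensus string.

    Uppercase letters contribute ``log2(match_prob / 0.05)`` bits at the
    consensus residue and split the remaining probability over the other
    19 residues; a lowercase ``x`` marks a wildcard column scoring 0 for
    every residue.  The default threshold is 60% of the maximum
    attainable score.
    """
    if not 0 < match_prob < 1:
        raise ValueError("match_prob must be in (0, 1)")
    bg = 1.0 / len(AMINO_ACIDS)
    off_prob = (1.0 - match_prob) / (len(AMINO_ACIDS) - 1)
    rows = []
    for ch in consensus:
        if ch == "x":
            rows.append(np.zeros(len(AMINO_ACIDS)))
            continue
        ch = ch.upper()
        if ch not in _AA_INDEX:
            raise ValueError(f"invalid consensus character {ch!r}")
        row = np.full(len(AMINO_ACIDS), math.log2(off_prob / bg))
        row[_AA_INDEX[ch]] = math.log2(match_prob / bg)
        rows.append(row)
    log_odds = np.vstack(rows)
    prof = DomainProfile(name=name, log_odds=log_odds, bit_threshold=0.0)
    prof.bit_threshold = (
        0.6 * prof.max_score() if bit_threshold is None else bit_threshold
    )
    return prof


def _encode(sequence: str) -> np.ndarray:
    # X (and only X) maps to index 20, a zero-score pseudo-column.
    return np.fromiter(
        (_AA_INDEX.get(ch, 20) for ch in sequence), dtype=np.int64, count=len(sequence)
    )


def _window_scores(sequence: str, profile: DomainProfile) -> np.ndarray:
    """Score every window offset; empty array if the sequence is too short."""
    L = profile.length
    n = len(sequence) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = _encode(sequence)
    # pad log-odds with an X column of zeros
    lo = np.hstack([profile.log_odds, np.zeros((L, 1))])
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, idx[j : j + n]]
    return scores


def calibrate_profile(
    profile: DomainProfile,
    seed: int = 0,
    n_shuffles: int = 100,
    null_length: int = 500,
) -> DomainProfile:
    """Fit the profile's Gumbel E-value null on random sequences.

    Best-window scores of ``n_shuffles`` uniform-background sequences of
    ``null_length`` residues are fitted with a right-skewed Gumbel; the
    location/scale are stored on the profile (in place) and returned.
    """
    rng = np.random.default_rng(seed)
    best = np.empty(n_shuffles)
    aa = np.array(list(AMINO_ACIDS))
    for i in range(n_shuffles):
        seq = "".join(rng.choice(aa, size=null_length))
        best[i] = _window_scores(seq, profile).max()
    loc, scale = stats.gumbel_r.fit(best)
    profile.evalue_loc = float(loc)
    profile.evalue_scale = float(scale)
    return profile


def scan_profile(protein: ProteinRecord, profile: DomainProfile) -> list[DomainHit]:
    """Scan a protein with a profile; greedy non-overlapping hits.

    Windows scoring at least ``bit_threshold`` are accepted greedily by
    descending score (ties to the leftmost offset); accepted hits never
    overlap.  Returns hits sorted by start coordinate.  A protein
    shorter than the profile yields an empty list.
    """
    scores = _window_scores(protein.sequence, profile)
    n = scores.size
    if n == 0:
        return []
    order = np.lexsort((np.arange(n), -scores))
    taken = np.zeros(len(protein.sequence), dtype=bool)
    L = profile.length
    hits: list[DomainHit] = []
    for off in order:
        s = float(scores[off])
        if s < profile.bit_threshold:
            break
        if taken[off : off + L].any():
            continue
        taken[off : off + L] = True
        hits.append(
            DomainHit(
                protein_id=protein.id,
                domain=profile.name,
                start=int(off) + 1,
                end=int(off) + L,
                bit_score=s,
                evalue=profile.evalue(s, n),
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def collapse_isoforms(
    records: Sequence[ProteinRecord], locus_of: Mapping[str, str]
) -> list[ProteinRecord]:
    """Keep one record per locus: the longest, ties to the smaller id."""
    missing = [r.id for r in records if r.id not in locus_of]
    if missing:
        raise KeyError(f"record id(s) missing from locus map: {missing}")
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        locus = locus_of[rec.id]
        if locus not in best:
            best[locus] = rec
            order.append(locus)
        else:
            cur = best[locus]
            if (-len(rec), rec.id) < (-len(cur), cur.id):
                best[locus] = rec
    return [best[locus] for locus in order]


def filter_candidates(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    voltage_clc_name: str = "Voltage_CLC",
    cbs_name: str = "CBS",
) -> list[CLCCandidate]:
    """Attach domain hits and apply the E-value screen.

    A candidate passes iff it has at least one Voltage_CLC hit with
    E-value <= ``e_cutoff``.  CBS hits are recorded but not required.
    Output is sorted by protein id.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    by_protein: dict[str, dict[str, list[DomainHit]]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, {}).setdefault(h.domain, []).append(h)
    out: list[CLCCandidate] = []
    for prot in proteins:
        doms = by_protein.get(prot.id, {})
        vc = sorted(doms.get(voltage_clc_name, []), key=lambda h: h.start)
        cbs = sorted(doms.get(cbs_name, []), key=lambda h: h.start)
        passed = any(h.evalue <= e_cutoff for h in vc)
        out.append(
            CLCCandidate(
                protein=prot,
                voltage_clc_hits=vc,
                cbs_hits=cbs,
                passed_filter=passed,
            )
        )
    out.sort(key=lambda c: c.protein.id)
    return out


def write_candidate_table(
    candidates: Sequence[CLCCandidate], path: str | Path, sep: str = "\t"
) -> None:
    """Write the candidate summary table (coordinates 1-based inclusive)."""
    cols = ["id", "species", "length", "n_voltage_clc", "n_cbs", "best_evalue", "passed"]
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for c in candidates:
            best = "" if math.isinf(c.best_evalue) else f"{c.best_evalue:.3g}"
            fh.write(
                sep.join(
                    [
                        c.protein.id,
                        c.protein.species,
                        str(len(c.protein)),
                        str(len(c.voltage_clc_hits)),
                        str(len(c.cbs_hits)),
                        best,
                        str(c.passed_filter).lower(),
                    ]
                )
                + "\n"
            )
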