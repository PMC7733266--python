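"""Synthetic fixture generators with ground-truth manifests.

Three generators cover the downstream stages: proteomes with planted
domain/region signals among decoys, duplication-loss gene histories
evolved inside a species tree, and Ct / measurement tables with known
effects.  All generators are pure functions of (spec, seed) and every
generated entity has a manifest entry sufficient to score the
downstream result without re-deriving truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .expression_anion_stats import CtTable, MeasurementTable
from .family_identification import DomainProfile, ProteinRecord, profile_from_consensus
from .phylo_reconciliation import parse_newick

__all__ = [
    "VOLTAGE_CLC_CONSENSUS",
    "CBS_CONSENSUS",
    "TrueGeneLabel",
    "ProteomeSpec",
    "DupLossSpec",
    "ExpressionSpec",
    "MeasurementSpec",
    "Manifest",
    "default_profiles",
    "simulate_proteome",
    "simulate_duploss_gene_tree",
    "simulate_ct_table",
    "simulate_measurement_table",
    "default_species_tree",
    "DEFAULT_SPECIES_NEWICK",
    "TAXON_GROUPS",
    "write_manifest",
    "read_manifest",
]

# Filler alphabet excludes G and P so that no conserved-region pattern
# (each requires a literal G or P) can arise by chance in backgrounds.
_FILLER = "ADEFHIKLMNQRSTVWYC"

# Fixed consensus strings used both for planting signals and for building
# the scanning profiles; 'x' marks the variable diagnostic positions
# (selectivity residue, gating glutamate, proton glutamate site).
_SEG_A = "MSLNDTVRFEAKHQLWYVTN"
_SEG_B = "FLKERHANTVDMSYQWILVTAEDS"
_SEG_C = "KVNDRETHALMSWYFIQVTLSEDA"
_SEG_D = "RLHTEVNAKDSMWYFQ"

VOLTAGE_CLC_CONSENSUS = (
    _SEG_A + "GxGIPE" + _SEG_B + "GKxGPLVH" + _SEG_C + "PIVGSLF" + "ARL" + "x" + _SEG_D
)
CBS_CONSENSUS = "LRSEVVTMDANHKLYEVMTRSEHNVSALAVVDDNHRLLTM"

_TM_SEGMENT = "ILV" * 7  # 21 strongly hydrophobic residues

# offsets of the wildcard slots within VOLTAGE_CLC_CONSENSUS (0-based)
_SEL_SLOT = len(_SEG_A) + 1
_GATE_SLOT = len(_SEG_A) + 6 + len(_SEG_B) + 2
_PROTON_SLOT = len(_SEG_A) + 6 + len(_SEG_B) + 8 + len(_SEG_C) + 7 + 3


def default_profiles(seed: int = 0) -> dict[str, DomainProfile]:
    """Scanning profiles for the two planted domains (uncalibrated;
    call :func:`clcfam.family_identification.calibrate_profile` to fit
    the E-value null)."""
    return {
        "Voltage_CLC": profile_from_consensus("Voltage_CLC", VOLTAGE_CLC_CONSENSUS),
        "CBS": profile_from_consensus("CBS", CBS_CONSENSUS),
    }


@dataclass
class Manifest:
    """Flat ground-truth store: entity id -> field -> value."""

    entries: dict[str, dict[str, object]] = field(default_factory=dict)

    def __getitem__(self, key: str) -> dict[str, object]:
        return self.entries[key]


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entity, fields in manifest.entries.items():
            for key, value in fields.items():
                fh.write(f"{entity}.{key}={value}\n")


def read_manifest(path: str | Path) -> Manifest:
    manifest = Manifest()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        head, _, value = line.partition("=")
        entity, _, key = head.partition(".")
        manifest.entries.setdefault(entity, {})[key] = value
    return manifest


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueGeneLabel:
    """Ground-truth design of one planted CLC gene."""

    selectivity_residue: str = "S"
    gating: bool = True
    proton: bool = True
    n_tm: int = 3


@dataclass
class ProteomeSpec:
    n_true: int
    n_decoy: int
    labels: Sequence[TrueGeneLabel] | None = None
    seed: int = 0
    flank: tuple[int, int] = (30, 60)  # uniform range for filler stretches

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_decoy < 0:
            raise ValueError("counts must be >= 0")
        if self.labels is not None and len(self.labels) != self.n_true:
            raise ValueError(
                f"got {len(self.labels)} labels for {self.n_true} true genes"
            )


def _bg(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(_FILLER), size=n))


def _domain_sequence(label: TrueGeneLabel) -> str:
    chars = list(VOLTAGE_CLC_CONSENSUS)
    chars[_SEL_SLOT] = label.selectivity_residue
    chars[_GATE_SLOT] = "E" if label.gating else "T"
    chars[_PROTON_SLOT] = "E" if label.proton else "Q"
    return "".join(chars)


def simulate_proteome(spec: ProteomeSpec) -> tuple[list[ProteinRecord], Manifest]:
    """Generate a proteome of planted CLC genes plus decoys.

    True genes carry the Voltage_CLC consensus (with their labelled key
    residues), two CBS copies and ``n_tm`` hydrophobic stretches.
    Decoys carry at most partial signals: CBS copies only, a single
    conserved region, or pure background.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.labels) if spec.labels is not None else [
        TrueGeneLabel() for _ in range(spec.n_true)
    ]
    lo, hi = spec.flank
    records: list[ProteinRecord] = []
    manifest = Manifest()
    for i, label in enumerate(labels):
        tm_block = "".join(_TM_SEGMENT + _bg(rng, 8, 14) for _ in range(label.n_tm))
        prefix = _bg(rng, lo, hi) + tm_block
        domain = _domain_sequence(label)
        seq = (
            prefix
            + domain
            + _bg(rng, 15, 25)
            + CBS_CONSENSUS
            + _bg(rng, 10, 20)
            + CBS_CONSENSUS
            + _bg(rng, lo, hi)
        )
        rid = f"true{i:03d}"
        records.append(ProteinRecord(id=rid, sequence=seq, species="synth"))
        if label.gating and label.proton:
            expected_class = "antiporter"
        else:
            expected_class = "channel"
        sel = {"P": "NO3-", "S": "Cl-"}.get(label.selectivity_residue, "unknown")
        manifest.entries[rid] = {
            "kind": "true",
            "selectivity_residue": label.selectivity_residue,
            "selectivity": sel,
            "gating": "present" if label.gating else "absent",
            "proton": "present" if label.proton else "absent",
            "transport_class": expected_class,
            "domain_start": len(prefix) + 1,
            "domain_end": len(prefix) + len(domain),
            "n_tm": label.n_tm,
        }
    decoy_kinds = ["cbs_only", "single_region", "background"]
    for i in range(spec.n_decoy):
        kind = decoy_kinds[i % len(decoy_kinds)]
        if kind == "cbs_only":
            seq = (
                _bg(rng, 80, 120)
                + CBS_CONSENSUS
                + _bg(rng, 10, 20)
                + CBS_CONSENSUS
                + _bg(rng, 60, 90)
            )
        elif kind == "single_region":
            key = str(rng.choice(["P", "S", "A"]))
            seq = _bg(rng, 100, 140) + "G" + key + "GIPE" + _bg(rng, 120, 160)
        else:
            seq = _bg(rng, 300, 450)
        rid = f"decoy{i:03d}"
        records.append(ProteinRecord(id=rid, sequence=seq, species="synth"))
        manifest.entries[rid] = {"kind": "decoy", "decoy_type": kind}
    return records, manifest


# ---------------------------------------------------------------------------
# Duplication-loss gene-tree simulation
# ---------------------------------------------------------------------------

DEFAULT_SPECIES_NEWICK = (
    "((((((Ath:1,Csi:1):1,(Egr:1,Esa:1):1):1,((Gma:1,Peu:1):1,(Pgr:1,Vvi:1):1):1):1,"
    "(Osa:1,Zma:1):2):1,(Gbi:1,Pta:1):2):1,((Mpo:1,Smo:1):1,Sfa:1):2);"
)

TAXON_GROUPS: dict[str, set[str]] = {
    "core_eudicots": {"Ath", "Csi", "Egr", "Esa", "Gma", "Peu", "Pgr", "Vvi"},
    "monocots": {"Osa", "Zma"},
    "gymnosperms": {"Gbi", "Pta"},
    "bryophytes": {"Mpo", "Smo", "Sfa"},
}


def default_species_tree() -> dendropy.Tree:
    """A 15-taxon species tree (8 core eudicots, 2 monocots, 2
    gymnosperms, 3 bryophytes) with unit-scale branch lengths."""
    return parse_newick(DEFAULT_SPECIES_NEWICK)


@dataclass
class DupLossSpec:
    species_tree: dendropy.Tree
    dup_rate: float = 0.1
    loss_rate: float = 0.0
    seed: int = 0
    force_root_duplication: bool = False

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")


class _HNode:
    """History-tree node: kind in {'dup', 'spec', 'leaf', 'loss'}."""

    __slots__ = ("kind", "species", "children", "name")

    def __init__(self, kind: str, species: dendropy.Node | None, children=None, name=""):
        self.kind = kind
        self.species = species
        self.children = children or []
        self.name = name


def _branch_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


def simulate_duploss_gene_tree(
    spec: DupLossSpec,
) -> tuple[dendropy.Tree, dict[str, str], Manifest]:
    """Evolve a gene lineage along the species tree under a birth-death
    process (per-lineage exponential waiting times on branches).

    The manifest records every raw duplication/loss with its species
    branch, plus the *observable* event counts (events surviving in the
    pruned, extant-only gene tree) and an ``lca_canonical`` flag telling
    whether minimum-event reconciliation of that pruned tree recovers
    exactly those observable counts (loss patterns can mask or relocate
    events, in which case parsimony legitimately reports fewer).
    """
    stree = spec.species_tree
    for node in stree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("species tree must have branch lengths on all edges")
    rng = np.random.default_rng(spec.seed)
    raw_events: list[tuple[str, str]] = []

    def evolve(species_node: dendropy.Node, t_remaining: float) -> _HNode:
        rate = spec.dup_rate + spec.loss_rate
        while True:
            if rate > 0:
                dt = rng.exponential(1.0 / rate)
            else:
                dt = math.inf
            if dt < t_remaining:
                t_remaining -= dt
                if rng.random() < spec.dup_rate / rate:
                    raw_events.append(("duplication", _branch_label(species_node)))
                    return _HNode(
                        "dup",
                        species_node,
                        [
                            evolve(species_node, t_remaining),
                            evolve(species_node, t_remaining),
                        ],
                    )
                raw_events.append(("loss", _branch_label(species_node)))
                return _HNode("loss", species_node)
            break
        if species_node.is_leaf():
            return _HNode("leaf", species_node)
        return _HNode(
            "spec",
            species_node,
            [evolve(ch, ch.edge.length) for ch in species_node.child_nodes()],
        )

    root = stree.seed_node
    if spec.force_root_duplication:
        raw_events.append(("duplication", _branch_label(root)))
        history = _HNode("dup", root, [evolve(root, 0.0), evolve(root, 0.0)])
    else:
        history = evolve(root, 0.0)

    # Prune extinct subtrees and count observable events.  A loss is
    # observable only beneath a retained branching node: suppressed
    # single-child chains carry their loss count upward and the chain
    # hanging above the final root is discarded (reconciliation of a
    # rooted tree cannot see events above its root).
    obs = {"dup": 0, "loss": 0}

    def prune(node: _HNode) -> tuple[_HNode | None, int]:
        """Return (kept node, chain losses pending above it)."""
        if node.kind == "loss":
            return None, 0
        if node.kind == "leaf":
            return node, 0
        kept = [(ch, chain) for ch, chain in (prune(c) for c in node.children)
                if ch is not None]
        if not kept:
            return None, 0
        if len(kept) == 1:
            child, chain = kept[0]
            if node.kind == "spec":
                chain += 1  # sibling species branch lost
            return child, chain
        # both children survive: their pending chains become visible
        for _, chain in kept:
            obs["loss"] += chain
        if node.kind == "dup":
            obs["dup"] += 1
        return _HNode(node.kind, node.species, [ch for ch, _ in kept]), 0

    pruned, _root_chain = prune(history)  # root chain is unobservable
    if pruned is None:
        raise RuntimeError("all gene lineages were lost; re-run with another seed")

    # Is the pruned history parsimony-canonical?  LCA reconciliation maps
    # every gene node to the species LCA of its surviving leaves; when a
    # loss pattern moves that LCA below the species branch where an event
    # really happened (or turns a duplication into an apparent
    # speciation), minimum-event reconciliation cannot recover the true
    # counts.  We record whether every kept node's leaf-species LCA
    # coincides with its true species branch and every kept duplication
    # still looks like one.
    s_parent = {n: n.parent_node for n in stree.preorder_node_iter()}
    s_depth = {}
    for n in stree.preorder_node_iter():
        s_depth[n] = 0 if s_parent[n] is None else s_depth[s_parent[n]] + 1

    def s_lca(a, b):
        while s_depth[a] > s_depth[b]:
            a = s_parent[a]
        while s_depth[b] > s_depth[a]:
            b = s_parent[b]
        while a is not b:
            a, b = s_parent[a], s_parent[b]
        return a

    canonical = True

    def check(node: _HNode) -> dendropy.Node:
        nonlocal canonical
        if node.kind == "leaf":
            return node.species
        child_lcas = [check(ch) for ch in node.children]
        lca = child_lcas[0]
        for c in child_lcas[1:]:
            lca = s_lca(lca, c)
        if lca is not node.species:
            canonical = False
        if node.kind == "dup" and all(c is not lca for c in child_lcas):
            canonical = False
        return lca

    check(pruned)

    counter: dict[str, int] = {}
    leaf_map: dict[str, str] = {}

    def name_leaves(node: _HNode) -> None:
        if node.kind == "leaf":
            sp = node.species.taxon.label
            counter[sp] = counter.get(sp, 0) + 1
            node.name = f"{sp}_g{counter[sp]}"
            leaf_map[node.name] = sp
            return
        for ch in node.children:
            name_leaves(ch)

    def to_newick(node: _HNode) -> str:
        if node.kind == "leaf":
            return f"{node.name}:1"
        return "(" + ",".join(to_newick(ch) for ch in node.children) + "):1"

    name_leaves(pruned)
    if pruned.kind == "leaf":
        newick = f"({pruned.name}:1);"
    else:
        newick = to_newick(pruned) + ";"
    gene_tree = parse_newick(newick)

    manifest = Manifest()
    manifest.entries["history"] = {
        "n_raw_duplications": sum(1 for k, _ in raw_events if k == "duplication"),
        "n_raw_losses": sum(1 for k, _ in raw_events if k == "loss"),
        "observable_duplications": obs["dup"],
        "observable_losses": obs["loss"],
        "lca_canonical": canonical,
        "forced_root_duplication": spec.force_root_duplication,
    }
    for i, (kind, branch) in enumerate(raw_events):
        manifest.entries[f"event{i:03d}"] = {"kind": kind, "species_branch": branch}
    return gene_tree, leaf_map, manifest


# ---------------------------------------------------------------------------
# Ct and measurement tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    genes: Sequence[str]
    tissues: Sequence[str]
    treatments: Sequence[float]
    log2_fold: Mapping[tuple[str, str, float], float]
    reference_gene: str = "PgActin"
    calibrator: float = 0.0
    base_ct: float = 25.0
    reference_ct: float = 20.0
    sigma_ct: float = 0.2
    n_bioreps: int = 3
    n_techreps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ct < 0:
            raise ValueError("sigma_ct must be >= 0")
        if self.n_bioreps < 1 or self.n_techreps < 1:
            raise ValueError("replicate counts must be positive")
        if self.calibrator not in self.treatments:
            raise ValueError("calibrator level must be among the treatments")
        if self.reference_gene in self.genes:
            raise ValueError("reference gene must not appear among the target genes")


def simulate_ct_table(spec: ExpressionSpec) -> tuple[CtTable, Manifest]:
    """Ct = base - planted log2 fold (target genes) plus Gaussian noise;
    the reference gene is constant in expectation."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for tissue in spec.tissues:
        for treatment in spec.treatments:
            for gene in list(spec.genes) + [spec.reference_gene]:
                if gene == spec.reference_gene:
                    mean_ct = spec.reference_ct
                else:
                    lf = spec.log2_fold.get((gene, tissue, treatment), 0.0)
                    mean_ct = spec.base_ct - lf
                for b in range(1, spec.n_bioreps + 1):
                    for t in range(1, spec.n_techreps + 1):
                        noise = rng.normal(0.0, spec.sigma_ct) if spec.sigma_ct else 0.0
                        rows.append(
                            {
                                "gene": gene,
                                "tissue": tissue,
                                "treatment_mM": treatment,
                                "biorep": b,
                                "techrep": t,
                                "ct": mean_ct + noise,
                            }
                        )
    table = CtTable(
        data=pd.DataFrame(rows),
        reference_gene=spec.reference_gene,
        calibrator=spec.calibrator,
    )
    manifest = Manifest()
    for gene in spec.genes:
        for tissue in spec.tissues:
            for treatment in spec.treatments:
                lf = spec.log2_fold.get((gene, tissue, treatment), 0.0)
                cal = spec.log2_fold.get((gene, tissue, spec.calibrator), 0.0)
                manifest.entries[f"{gene}|{tissue}|{treatment:g}"] = {
                    "log2_fold": lf - cal,
                    "true_fold": 2.0 ** (lf - cal),
                }
    return table, manifest


_SHAPES = ("flat", "increasing", "decreasing", "hump")


@dataclass
class MeasurementSpec:
    profiles: Mapping[tuple[str, str], str]  # (variable, tissue) -> shape
    treatments: Sequence[float] = (0.0, 100.0, 200.0, 300.0)
    base: float = 10.0
    sigma: float = 0.5
    n_reps: int = 3
    peak_index: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        bad = [s for s in self.profiles.values() if s not in _SHAPES]
        if bad:
            raise ValueError(f"unknown profile shape(s) {bad}; choose from {_SHAPES}")


def _shape_multiplier(shape: str, i: int, peak: int) -> float:
    if shape == "flat":
        return 1.0
    if shape == "increasing":
        return 1.0 + 1.5 * i
    if shape == "decreasing":
        return 1.0 / (1.0 + 0.8 * i)
    # hump: peaks at the configured treatment index
    return 1.0 + 2.0 * math.exp(-((i - peak) ** 2) / 0.8)


def simulate_measurement_table(
    spec: MeasurementSpec,
) -> tuple[MeasurementTable, Manifest]:
    """Per-(variable, tissue) treatment profiles with Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    manifest = Manifest()
    for (variable, tissue), shape in spec.profiles.items():
        for i, treatment in enumerate(spec.treatments):
            mean = spec.base * _shape_multiplier(shape, i, spec.peak_index)
            manifest.entries[f"{variable}|{tissue}|{treatment:g}"] = {
                "true_mean": mean,
                "shape": shape,
            }
            for rep in range(1, spec.n_reps + 1):
                noise = rng.normal(0.0, spec.sigma) if spec.sigma else 0.0
                rows.append(
                    {
                        "tissue": tissue,
                        "treatment_mM": treatment,
                        "rep": rep,
                        "variable": variable,
                        "value": mean + noise,
                    }
                )
    return MeasurementTable(data=pd.DataFrame(rows)), manifest
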