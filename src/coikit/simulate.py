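"""Synthetic COI-like datasets with known ground truth.

The generator emulates a multi-family reptile-like assemblage as seen through
a single mitochondrial barcode: deep divergences between families, moderate
divergence between congeneric species, shallow intraspecific variation, and
protein-coding sequences free of in-frame stop codons.

Trees are ultrametric in expected-substitutions-per-site units. Per family,
species are arranged in genera: within-genus species joins sit at stratified
heights of 0.60-1.00 x ``species_depth`` (stratification keeps internal
edges long enough to be recoverable), genus joins at 1.10-1.30 x
``species_depth``, and all families attach to a star backbone root at
``family_depth``. Conspecific samples coalesce at ``intraspecific_depth/2``,
so expected conspecific divergence equals ``intraspecific_depth``.

Sequences evolve site-independently under the Kimura two-parameter process
(transition/transversion rate ratio ``kappa``; branch lengths are expected
substitutions per site). Any codon that would become an in-frame stop under
the vertebrate mitochondrial code is reverted to its pre-mutation state, so
generated data always pass the stop-codon QC screen.

Planted candidate lineages emulate unidentified specimens: an extra record is
evolved from a nominal species' sequence along a branch of
``multiplier x expected sister-pair distance`` of its family, with the
multiplier recorded in the ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .qc import stop_codons
from .seqio import Alignment, SequenceRecord, Status

__all__ = [
    "SimConfig",
    "SimNode",
    "GroundTruth",
    "PlantedLineage",
    "simulate_taxonomy_trees",
    "evolve_sequences",
    "plant_candidates",
    "simulate_dataset",
]

_CODE = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 8
    genera_per_family: int = 4
    species_per_genus: int = 3
    samples_per_species: int = 1
    seq_length: int = 664
    kappa: float = 4.0  # mitochondrial ts/tv rate ratio, typically 3-6
    family_depth: float = 0.25  # subs/site, root height of the whole tree
    species_depth: float = 0.10  # scale of within-family species joins
    intraspecific_depth: float = 0.01  # expected conspecific divergence
    planted_candidates: tuple[tuple[str, float], ...] = ()
    code_table: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (self.family_depth > 1.3 * self.species_depth):
            raise ValueError("family_depth must exceed 1.3 x species_depth")
        if not (self.species_depth > self.intraspecific_depth >= 0):
            raise ValueError("require species_depth > intraspecific_depth >= 0")
        if min(self.n_families, self.genera_per_family, self.species_per_genus,
               self.samples_per_species) < 1:
            raise ValueError("counts must be >= 1")

    def family_names(self) -> list[str]:
        return [f"Family{i + 1:02d}" for i in range(self.n_families)]


@dataclass
class SimNode:
    """Ultrametric tree node; tips at height 0, heights in subs/site."""

    height: float
    children: list["SimNode"] = field(default_factory=list)
    name: str | None = None  # set on tips

    def tips(self) -> list["SimNode"]:
        if not self.children:
            return [self]
        return [t for c in self.children for t in c.tips()]


@dataclass(frozen=True)
class PlantedLineage:
    record_id: str
    family: str
    genus: str
    source_species: str
    source_record: str
    multiplier: float
    target_distance: float  # expected distance to nearest nominal record


@dataclass
class GroundTruth:
    family_trees: dict[str, SimNode]  # species-level trees (tips = species)
    root: SimNode  # full sample-level tree
    taxonomy: dict[str, tuple[str, str, str]]
    expected_sister_distance: dict[str, float]
    planted: list[PlantedLineage] = field(default_factory=list)

    def expected_distances(self) -> tuple[list[str], np.ndarray]:
        """Expected pairwise distances (2 x MRCA height) between all tips."""
        tips = self.root.tips()
        labels = [t.name for t in tips]
        index = {t.name: i for i, t in enumerate(tips)}
        n = len(labels)
        d = np.zeros((n, n))

        def visit(node: SimNode):
            if not node.children:
                return [node.name]
            below = [visit(c) for c in node.children]
            for ga, gb in itertools.combinations(below, 2):
                for a in ga:
                    for b in gb:
                        d[index[a], index[b]] = d[index[b], index[a]] = 2 * node.height
            return [x for g in below for x in g]

        visit(self.root)
        return labels, d


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _random_join_tree(tips: list[SimNode], heights: list[float], rng) -> SimNode:
    """Join random pairs of clusters at the given ascending heights."""
    clusters = list(tips)
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        node = SimNode(height=h, children=[clusters[i], clusters[j]])
        clusters[i] = node
        del clusters[j]
    if len(clusters) > 1:  # guard; heights list should fully resolve
        return SimNode(height=max(h.height for h in clusters) * 1.01, children=clusters)
    return clusters[0]


def _stratified_heights(k: int, lo: float, hi: float, rng) -> list[float]:
    """k ascending heights over [lo, hi], one per equal sub-band.

    Joins hug the lower end of their sub-band and the deepest join hugs the
    top of the range. This keeps the edge above the shallowest join (the
    cherry edge, which sister-pair detection must recover by bootstrap) long
    by construction; unconstrained uniform draws frequently place two joins
    almost on top of each other, producing unrecoverable internal edges.
    """
    edges = np.linspace(lo, hi, k + 1)
    w = (hi - lo) / k
    heights = [
        float(rng.uniform(edges[i] + 0.10 * w, edges[i] + 0.35 * w))
        for i in range(k - 1)
    ]
    heights.append(float(rng.uniform(hi - 0.35 * w, hi - 0.10 * w)))
    return heights


def simulate_taxonomy_trees(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Build the species-level trees and the sample-level tree with taxonomy."""
    s = config.species_depth
    family_trees: dict[str, SimNode] = {}
    taxonomy: dict[str, tuple[str, str, str]] = {}
    sister: dict[str, float] = {}
    family_roots: list[SimNode] = []

    for fi, family in enumerate(config.family_names()):
        genus_roots = []
        for gi in range(config.genera_per_family):
            genus = f"Genus{fi + 1:02d}{chr(ord('a') + gi)}"
            tips = [
                SimNode(height=0.0, name=f"{genus} s{si + 1}")
                for si in range(config.species_per_genus)
            ]
            n_joins = len(tips) - 1
            if n_joins:
                heights = _stratified_heights(n_joins, 0.60 * s, 1.00 * s, rng)
                genus_roots.append(_random_join_tree(tips, heights, rng))
            else:
                genus_roots.append(tips[0])
        n_joins = len(genus_roots) - 1
        if n_joins:
            heights = _stratified_heights(n_joins, 1.10 * s, 1.30 * s, rng)
            fam_root = _random_join_tree(genus_roots, heights, rng)
        else:
            fam_root = genus_roots[0]
        family_trees[family] = fam_root
        family_roots.append(fam_root)

        cherries = [
            2 * node.height
            for node in _iter_nodes(fam_root)
            if node.children and all(not c.children for c in node.children)
        ]
        sister[family] = float(np.mean(cherries)) if cherries else 2 * 0.8 * s

    # expand species tips into sample tips and record taxonomy
    sample_roots = []
    for family, fam_root in zip(config.family_names(), family_roots):
        sample_roots.append(
            _expand_samples(fam_root, family, config, taxonomy)
        )
    root = SimNode(height=config.family_depth, children=sample_roots)
    return GroundTruth(
        family_trees=family_trees,
        root=root,
        taxonomy=taxonomy,
        expected_sister_distance=sister,
    )


def _iter_nodes(node: SimNode):
    yield node
    for c in node.children:
        yield from _iter_nodes(c)


def _expand_samples(node: SimNode, family: str, config: SimConfig, taxonomy) -> SimNode:
    if node.children:
        return SimNode(
            height=node.height,
            children=[_expand_samples(c, family, config, taxonomy) for c in node.children],
        )
    species = node.name
    genus = species.split(" ")[0]
    rec_base = species.replace(" ", "_")
    k = config.samples_per_species
    if k == 1:
        tip = SimNode(height=0.0, name=f"{rec_base}_r1")
        taxonomy[tip.name] = (species, genus, family)
        return tip
    tips = []
    for r in range(k):
        tip = SimNode(height=0.0, name=f"{rec_base}_r{r + 1}")
        taxonomy[tip.name] = (species, genus, family)
        tips.append(tip)
    return SimNode(height=config.intraspecific_depth / 2.0, children=tips)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _k2p_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """Cumulative K2p substitution probabilities for branch length d."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    for sbase in range(4):
        P[sbase, sbase] = p_same
        P[sbase, sbase ^ 2] = p_ts  # A<->G, C<->T
    return np.cumsum(P, axis=1)


def _stop_values(code_table: int) -> np.ndarray:
    values = []
    code = {c: i for i, c in enumerate(_CODE)}
    for codon in stop_codons(code_table):
        values.append(16 * code[codon[0]] + 4 * code[codon[1]] + code[codon[2]])
    return np.array(sorted(values))


def _evolve_branch(parent_seq: np.ndarray, d: float, kappa: float,
                   stop_vals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One K2p step of length d with stop-codon reversion (frame 0)."""
    if d <= 0:
        return parent_seq.copy()
    cum = _k2p_transition_matrix(d, kappa)
    u = rng.random(parent_seq.size)
    child = (u[:, None] > cum[parent_seq]).sum(axis=1).astype(np.int8)
    n_codons = parent_seq.size // 3
    if n_codons:
        cod = child[: 3 * n_codons].reshape(-1, 3).astype(np.int32)
        vals = 16 * cod[:, 0] + 4 * cod[:, 1] + cod[:, 2]
        bad = np.isin(vals, stop_vals)
        if bad.any():
            view = child[: 3 * n_codons].reshape(-1, 3)
            view[bad] = parent_seq[: 3 * n_codons].reshape(-1, 3)[bad]
    return child


def _random_root_sequence(length: int, stop_vals: np.ndarray, rng) -> np.ndarray:
    n_codons = -(-length // 3)
    codons = []
    ok = np.setdiff1d(np.arange(64), stop_vals)
    draws = rng.choice(ok, size=n_codons)
    for v in draws:
        codons.extend(((v >> 4) & 3, (v >> 2) & 3, v & 3))
    return np.array(codons[:length], dtype=np.int8)


def _decode(seq: np.ndarray) -> str:
    return "".join(_CODE[b] for b in seq)


def evolve_sequences(
    ground_truth: GroundTruth, config: SimConfig, rng: np.random.Generator
) -> Alignment:
    """Evolve sequences down the sample-level tree and build the alignment."""
    stop_vals = _stop_values(config.code_table)
    root_seq = _random_root_sequence(config.seq_length, stop_vals, rng)
    records: list[SequenceRecord] = []

    def descend(node: SimNode, seq: np.ndarray, parent_height: float):
        branch = parent_height - node.height
        child_seq = _evolve_branch(seq, branch, config.kappa, stop_vals, rng)
        if not node.children:
            species, genus, family = ground_truth.taxonomy[node.name]
            records.append(
                SequenceRecord(
                    id=node.name,
                    seq=_decode(child_seq),
                    species=species,
                    genus=genus,
                    family=family,
                    status=Status.NOMINAL,
                )
            )
            return
        for c in node.children:
            descend(c, child_seq, node.height)

    root = ground_truth.root
    for c in root.children:
        descend(c, root_seq, root.height)
    if not root.children:  # degenerate single-tip tree
        descend(root, root_seq, root.height)
    return Alignment(records, frame_offset=0, code_table=config.code_table)


# ---------------------------------------------------------------------------
# Planted candidates
# ---------------------------------------------------------------------------

def plant_candidates(
    alignment: Alignment,
    ground_truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[Alignment, GroundTruth]:
    """Append unidentified records at known distances from nominal species.

    Each ``(family, multiplier)`` entry adds one record evolved from a random
    nominal species of that family along a branch of
    ``multiplier x expected_sister_distance[family]``; its nearest nominal
    neighbour is therefore the source species, at that expected distance.
    """
    stop_vals = _stop_values(config.code_table)
    by_id = {r.id: r for r in alignment.records}
    new_records = list(alignment.records)
    used_sources: set[str] = set()
    counter: dict[str, int] = {}
    for family, multiplier in config.planted_candidates:
        if multiplier <= 0:
            raise ValueError("planting multiplier must be positive")
        pool = sorted(
            {r.species for r in alignment.records
             if r.family == family and r.status is Status.NOMINAL} - used_sources
        )
        if not pool:
            raise ValueError(f"no unused nominal source species in family {family!r}")
        source_species = pool[int(rng.integers(len(pool)))]
        used_sources.add(source_species)
        source_rec = next(r for r in alignment.records if r.species == source_species)
        t = multiplier * ground_truth.expected_sister_distance[family]
        seq = np.array([_CODE.index(c) for c in source_rec.seq], dtype=np.int8)
        planted_seq = _evolve_branch(seq, t, config.kappa, stop_vals, rng)
        counter[family] = counter.get(family, 0) + 1
        rec_id = f"{family}_plant{counter[family]}"
        genus = source_rec.genus
        rec = SequenceRecord(
            id=rec_id,
            seq=_decode(planted_seq),
            species=f"{genus} sp. P{counter[family]}",
            genus=genus,
            family=family,
            status=Status.UNIDENTIFIED,
        )
        new_records.append(rec)
        ground_truth.taxonomy[rec_id] = (rec.species, genus, family)
        ground_truth.planted.append(
            PlantedLineage(
                record_id=rec_id,
                family=family,
                genus=genus,
                source_species=source_species,
                source_record=source_rec.id,
                multiplier=multiplier,
                target_distance=t,
            )
        )
    aln = Alignment(new_records, frame_offset=0, code_table=config.code_table)
    return aln, ground_truth


def simulate_dataset(config: SimConfig) -> tuple[Alignment, GroundTruth]:
    """Full generator: trees -> sequences -> planted candidates (one seed)."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_taxonomy_trees(config, rng)
    alignment = evolve_sequences(truth, config, rng)
    if config.planted_candidates:
        alignment, truth = plant_candidates(alignment, truth, config, rng)
    return alignment, truth
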