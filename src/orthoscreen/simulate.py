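"""Synthetic ortholog panels, pathway tables and variant tables.

The generator emulates the study design the screens assume: a panel of ~46
species with a small trait-positive (foreground) group — 7 of 46 by default,
with a 2-of-18 variant — evolving protein sequences along a rooted tree under
a uniform amino-acid exchange process, with convergent foreground-specific
sites planted at chosen columns.  Everything is reproducible from a single
integer seed.

The substitution process is deliberately the simplest one with a known
stationary distribution: per branch of length t (expected substitutions per
site), each site receives a Poisson(t) number of exchange events, each
replacing the residue with one of the other 19 amino acids uniformly.  The
stationary distribution is uniform over the 20 amino acids.  Planting
replaces the evolved column after simulation, so the intended genotype
pattern holds regardless of branch lengths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np

from .io import (
    AMINO_ACIDS,
    FOREGROUND,
    BACKGROUND,
    OrthologAlignment,
    PathwayTable,
    SpeciesPanel,
    ValidationError,
    VariantRecord,
    translate_codon,
)

PLANT_MODES = ("foreground_specific_convergent", "foreground_partial", "background_polymorphic")


@dataclass(frozen=True)
class PlantedSite:
    """A column to overwrite after simulation.

    ``mode`` is one of:

    * ``foreground_specific_convergent`` — all foreground tips share one
      residue, all background tips share a different one;
    * ``foreground_partial`` — only ``m`` of the foreground tips carry the
      derived residue, the rest match the background;
    * ``background_polymorphic`` — foreground convergent but the background
      split between two residues (so the column is not background-conserved).
    """

    gene: int
    column: int
    mode: str
    m: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in PLANT_MODES:
            raise ValidationError(f"unknown planting mode {self.mode!r}")
        if self.mode == "foreground_partial" and (self.m is None or self.m < 1):
            raise ValidationError("foreground_partial requires m >= 1")


@dataclass
class SimulationConfig:
    """Reproducible description of one synthetic alignment panel."""

    panel: SpeciesPanel
    n_genes: int = 50
    gene_length: int = 300
    planted_sites: tuple[PlantedSite, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel.tree is None:
            raise ValidationError("simulation requires a panel tree with branch lengths")
        for site in self.planted_sites:
            if not 0 <= site.gene < self.n_genes:
                raise ValidationError(f"planted gene index {site.gene} outside [0, {self.n_genes})")
            if not 0 <= site.column < self.gene_length:
                raise ValidationError(
                    f"planted column {site.column} outside gene length {self.gene_length}"
                )


def make_panel(
    n_species: int = 46,
    n_foreground: int = 7,
    *,
    seed: int = 0,
    branch_length: float = 0.05,
) -> SpeciesPanel:
    """Build a panel with a random rooted tree and a scattered foreground group.

    Tree topology is a uniform random coalescent-style joining of tips, with
    every edge given the same expected substitutions/site (``branch_length``).
    Foreground tips are drawn at random so the trait-positive group is
    phylogenetically scattered, as in the real panels.
    """
    if n_species < 3 or not 1 <= n_foreground <= n_species - 2:
        raise ValidationError("need >= 3 species and 1 <= n_foreground <= n_species - 2")
    rng = random.Random(seed)
    species = [f"sp{i:02d}" for i in range(1, n_species + 1)]
    taxa = dendropy.TaxonNamespace(species)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in species:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        node.edge.length = branch_length
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        parent = dendropy.Node()
        parent.edge.length = branch_length
        parent.add_child(nodes.pop(i))
        parent.add_child(nodes.pop(j))
        nodes.append(parent)
    tree.seed_node.add_child(nodes[0])
    tree.seed_node.child_nodes()[0].edge.length = 0.0
    tree.is_rooted = True
    fg = set(rng.sample(species, n_foreground))
    phenotype = {s: (FOREGROUND if s in fg else BACKGROUND) for s in species}
    return SpeciesPanel(species_ids=species, phenotype=phenotype, tree=tree)


def _evolve_along_edge(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform-exchange evolution of an integer residue array over time t."""
    child = seq.copy()
    if t <= 0:
        return child
    counts = rng.poisson(t, size=seq.size)
    for pos in np.nonzero(counts)[0]:
        residue = child[pos]
        for _ in range(counts[pos]):
            # uniform among the 19 other residues
            step = rng.integers(1, 20)
            residue = (residue + step) % 20
        child[pos] = residue
    return child


def _plant(column: dict[str, int], panel: SpeciesPanel, site: PlantedSite,
           rng: np.random.Generator) -> dict[str, int]:
    r_b = int(rng.integers(20))
    r_f = (r_b + int(rng.integers(1, 20))) % 20
    out = dict(column)
    if site.mode == "foreground_specific_convergent":
        for s in panel.background:
            out[s] = r_b
        for s in panel.foreground:
            out[s] = r_f
    elif site.mode == "foreground_partial":
        fg = panel.foreground
        m = min(site.m or 1, len(fg))
        carriers = set(fg[:m])
        for s in panel.background:
            out[s] = r_b
        for s in fg:
            out[s] = r_f if s in carriers else r_b
    else:  # background_polymorphic
        r_b2 = next(r for r in range(20) if r not in (r_b, r_f))
        bg = panel.background
        for i, s in enumerate(bg):
            out[s] = r_b if i < max(1, len(bg) // 2) else r_b2
        for s in panel.foreground:
            out[s] = r_f
    return out


def simulate_alignment_set(config: SimulationConfig) -> list[OrthologAlignment]:
    """Evolve ``n_genes`` alignments along the panel tree and plant sites.

    Each gene starts from a uniformly random root sequence.  Planted columns
    overwrite the evolved residues (see :class:`PlantedSite`).  Output is
    bit-identical for a fixed config.
    """
    panel = config.panel
    rng = np.random.default_rng(config.seed)
    planted_by_gene: dict[int, list[PlantedSite]] = {}
    for site in config.planted_sites:
        planted_by_gene.setdefault(site.gene, []).append(site)
    alignments: list[OrthologAlignment] = []
    for g in range(config.n_genes):
        root = rng.integers(0, 20, size=config.gene_length)
        tip_seqs: dict[str, np.ndarray] = {}
        stack = [(config.panel.tree.seed_node, root)]
        while stack:
            node, seq = stack.pop()
            children = node.child_nodes()
            if not children:
                tip_seqs[node.taxon.label] = seq
                continue
            for child in reversed(children):
                t = child.edge.length or 0.0
                stack.append((child, _evolve_along_edge(seq, t, rng)))
        for site in sorted(planted_by_gene.get(g, []), key=lambda s: s.column):
            column = {s: int(tip_seqs[s][site.column]) for s in panel.species_ids}
            for s, residue in _plant(column, panel, site, rng).items():
                tip_seqs[s][site.column] = residue
        rows = {
            s: "".join(AMINO_ACIDS[i] for i in tip_seqs[s]) for s in panel.species_ids
        }
        alignments.append(OrthologAlignment(gene_id=f"gene{g + 1:04d}", rows=rows))
    return alignments


def simulate_pathway_table(
    universe_size: int,
    n_pathways: int,
    size_range: tuple[int, int],
    overlap_fraction: float,
    seed: int = 0,
    *,
    universe: Sequence[str] | None = None,
) -> PathwayTable:
    """Sample pathways with controlled pairwise overlap.

    Each pathway of size s draws round(``overlap_fraction`` * s) genes from a
    small shared core pool (identical across pathways, so equal-sized pathways
    overlap by exactly that count) and the remainder from private, pairwise
    disjoint genes.  ``overlap_fraction=0`` yields pairwise disjoint pathways.

    With ``universe`` given, its names are used (shuffled under the seed) and
    ``universe_size`` must equal its length; otherwise synthetic gene names
    ``g00001...`` are generated.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValidationError(f"bad size range {size_range}")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValidationError(f"overlap_fraction must be in [0,1], got {overlap_fraction}")
    if universe_size < hi:
        raise ValidationError("universe smaller than max pathway size")
    rng = np.random.default_rng(seed)
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_pathways)]
    cores = [round(overlap_fraction * s) for s in sizes]
    pool_size = max(cores, default=0)
    n_private = sum(s - c for s, c in zip(sizes, cores))
    if pool_size + n_private > universe_size:
        raise ValidationError(
            f"infeasible overlap request: need {pool_size + n_private} genes, "
            f"universe has {universe_size}"
        )
    if universe is not None:
        if len(universe) != universe_size:
            raise ValidationError(f"universe_size {universe_size} != len(universe) {len(universe)}")
        universe = list(universe)
        rng.shuffle(universe)
    else:
        universe = [f"g{i:05d}" for i in range(1, universe_size + 1)]
    pool = universe[:pool_size]
    private_iter = iter(universe[pool_size:])
    pathways: dict[str, frozenset[str]] = {}
    for i, (s, c) in enumerate(zip(sizes, cores), 1):
        core = list(rng.choice(pool, size=c, replace=False)) if c else []
        private = [next(private_iter) for _ in range(s - c)]
        pathways[f"P{i:03d}"] = frozenset(core + private)
    return PathwayTable(pathways=pathways, universe=frozenset(universe))


def simulate_variant_table(
    reference: str,
    n_variants: int,
    quality_dist: Callable[[np.random.Generator], float] | Sequence[float] | None = None,
    depth_dist: Callable[[np.random.Generator], int] | Sequence[int] | None = None,
    seed: int = 0,
    *,
    sequence_id: str = "ref",
    het_fraction: float = 0.2,
) -> list[VariantRecord]:
    """Sample SNV records at distinct positions of a reference sequence.

    ``quality_dist`` / ``depth_dist`` may be a callable taking the RNG, a
    sequence cycled in order (useful for planting exact boundary values), or
    None for the defaults (quality ~ Uniform(10, 50); depth ~ Poisson(45),
    matching ~45x genome coverage).
    """
    if n_variants > len(reference):
        raise ValidationError(f"n_variants {n_variants} exceeds reference length {len(reference)}")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    positions = sorted(rng.choice(len(reference), size=n_variants, replace=False)) if n_variants else []

    def draw(dist, default, i):
        if dist is None:
            return default()
        if callable(dist):
            return dist(rng)
        return dist[i % len(dist)]

    records = []
    for i, pos in enumerate(positions):
        ref = reference[pos].upper()
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4] if ref in bases else "A"
        records.append(
            VariantRecord(
                sequence_id=sequence_id,
                position=int(pos),
                ref=ref,
                alt=alt,
                genotype="het" if rng.random() < het_fraction else "hom",
                quality=float(draw(quality_dist, lambda: rng.uniform(10, 50), i)),
                depth=int(draw(depth_dist, lambda: rng.poisson(45), i)),
            )
        )
    return records


def simulate_codon_alignment(
    species: Sequence[str],
    n_codons: int,
    seed: int = 0,
    *,
    gene_id: str = "gene0001",
    p_shared_prefix: float = 0.5,
) -> OrthologAlignment:
    """Random codon alignment for exercising the 4D-site extractor.

    With probability ``p_shared_prefix`` a codon column shares its first two
    bases across all species (third positions independent and random, so some
    of these columns fall in 4-fold families, e.g. Gly GGN or the Leu CTN
    block, and some do not, e.g. Met/Trp families); otherwise every species
    gets an independent random codon.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    codon_rows: dict[str, list[str]] = {s: [] for s in species}
    for _ in range(n_codons):
        if rng.random() < p_shared_prefix:
            prefix = bases[rng.integers(4)] + bases[rng.integers(4)]
            for s in species:
                codon_rows[s].append(prefix + bases[rng.integers(4)])
        else:
            for s in species:
                codon_rows[s].append("".join(bases[rng.integers(4)] for _ in range(3)))
    codon_strs = {s: "".join(c) for s, c in codon_rows.items()}
    protein = {
        s: "".join(translate_codon(codon_strs[s][3 * i : 3 * i + 3]) for i in range(n_codons))
        for s in species
    }
    return OrthologAlignment(gene_id=gene_id, rows=protein, codon_rows=codon_strs)
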