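"""Readers, writers and validated domain containers for every external format
the pipeline touches.

All coordinates are 0-based, half-open internally; 1-based coordinates appear
only at the reporting boundary (output TSVs, VCF input conversion).

Alphabet conventions: ``'X'`` is an unknown residue, ``'-'`` is an alignment
gap.  They are distinct states, but both make a species non-informative at a
column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS) | {"-", "X"}
NUCLEOTIDES = "ACGT"
CODON_ALPHABET = frozenset(NUCLEOTIDES) | {"-", "N"}

FOREGROUND = "foreground"
BACKGROUND = "background"


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class SpeciesPanel:
    """A species set with a binary phenotype partition and optional rooted tree.

    Parameters
    ----------
    species_ids
        Ordered, unique species names.
    phenotype
        Mapping of every species to ``"foreground"`` (trait-positive) or
        ``"background"`` (comparison panel).
    tree
        Optional rooted phylogeny (:class:`dendropy.Tree`) whose tip labels are
        a subset of ``species_ids``.  Branch lengths, in expected
        substitutions/site, are required only by the simulator; the screens
        themselves are set-based.
    """

    species_ids: list[str]
    phenotype: dict[str, str]
    tree: dendropy.Tree | None = None

    def __post_init__(self) -> None:
        if len(set(self.species_ids)) != len(self.species_ids):
            dupes = {s for s in self.species_ids if self.species_ids.count(s) > 1}
            raise ValidationError(f"duplicate species ids: {sorted(dupes)}")
        if set(self.phenotype) != set(self.species_ids):
            raise ValidationError("phenotype labels must cover exactly the panel species")
        bad = {s: l for s, l in self.phenotype.items() if l not in (FOREGROUND, BACKGROUND)}
        if bad:
            raise ValidationError(f"unknown phenotype label(s): {bad}")
        if len(self.foreground) < 1:
            raise ValidationError("panel needs at least one foreground species")
        if len(self.background) < 2:
            raise ValidationError("panel needs at least two background species")
        if self.tree is not None:
            tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
            if len(tips) != sum(1 for _ in self.tree.leaf_node_iter()):
                raise ValidationError("tree tip labels are not unique")
            extra = tips - set(self.species_ids)
            if extra:
                raise ValidationError(f"tree tips not in panel: {sorted(extra)}")

    @property
    def foreground(self) -> list[str]:
        return [s for s in self.species_ids if self.phenotype[s] == FOREGROUND]

    @property
    def background(self) -> list[str]:
        return [s for s in self.species_ids if self.phenotype[s] == BACKGROUND]

    def __len__(self) -> int:
        return len(self.species_ids)


@dataclass
class OrthologAlignment:
    """Per-gene aligned sequences across a species panel.

    ``rows`` maps species to aligned residue strings over the 20 amino acids
    plus ``'-'`` (gap) and ``'X'`` (unknown).  ``codon_rows``, when present,
    maps the same species to aligned nucleotide strings of exactly three times
    the protein length over ``{A,C,G,T,N,-}``.
    """

    gene_id: str
    rows: dict[str, str]
    codon_rows: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError(f"{self.gene_id}: alignment has no rows")
        lengths = {len(seq) for seq in self.rows.values()}
        if len(lengths) != 1:
            offenders = sorted(self.rows, key=lambda s: len(self.rows[s]))
            raise ValidationError(
                f"{self.gene_id}: ragged alignment (species {offenders[0]!r} has length "
                f"{len(self.rows[offenders[0]])}, {offenders[-1]!r} has {len(self.rows[offenders[-1]])})"
            )
        for sp, seq in self.rows.items():
            bad = set(seq.upper()) - PROTEIN_ALPHABET
            if bad:
                raise ValidationError(f"{self.gene_id}/{sp}: invalid residue(s) {sorted(bad)}")
        if self.codon_rows is not None:
            plen = self.length
            if set(self.codon_rows) != set(self.rows):
                raise ValidationError(f"{self.gene_id}: codon rows do not match protein rows")
            for sp, seq in self.codon_rows.items():
                if len(seq) != 3 * plen:
                    raise ValidationError(
                        f"{self.gene_id}/{sp}: codon row length {len(seq)} != 3*{plen}"
                    )
                bad = set(seq.upper()) - CODON_ALPHABET
                if bad:
                    raise ValidationError(f"{self.gene_id}/{sp}: invalid base(s) {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> dict[str, str]:
        """Residue of every species at 0-based column ``i``."""
        if not 0 <= i < self.length:
            raise IndexError(f"column {i} out of range for length {self.length}")
        return {sp: seq[i] for sp, seq in self.rows.items()}


@dataclass
class PathwayTable:
    """Pathway (gene-set) memberships over a gene universe.

    Every pathway gene must belong to ``universe`` (the annotated genes of the
    focal species); pathway sizes from this table are the N(a)/N(b)
    denominators of the pathway score.
    """

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.pathways = {p: frozenset(g) for p, g in self.pathways.items()}
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} is empty")
            stray = genes - self.universe
            if stray:
                raise ValidationError(f"pathway {pid!r} has genes outside universe: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class VariantRecord:
    """One called variant site on a reference sequence.

    ``position`` is 0-based on the reference; ``quality`` is a Phred score;
    ``depth`` is the total mapped-read count at the site.  ``genotype`` is
    ``"hom"`` or ``"het"``.
    """

    sequence_id: str
    position: int
    ref: str
    alt: str
    genotype: str
    quality: float
    depth: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"negative position {self.position}")
        if self.genotype not in ("hom", "het"):
            raise ValidationError(f"genotype must be 'hom' or 'het', got {self.genotype!r}")
        if self.quality < 0:
            raise ValidationError(f"negative quality {self.quality}")
        if self.depth < 0:
            raise ValidationError(f"negative depth {self.depth}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_phenotype_table(path: str | Path) -> SpeciesPanel:
    """Read a two-column TSV (species, label) into a :class:`SpeciesPanel`.

    Labels must be ``foreground`` or ``background``; file order is preserved.
    A header line ``species<TAB>label`` is accepted and skipped.
    """
    species: list[str] = []
    phenotype: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
        name, label = (p.strip() for p in parts)
        if (name, label) == ("species", "label"):
            continue
        if name in phenotype:
            raise ValidationError(f"{path}:{lineno}: duplicate species {name!r}")
        if label not in (FOREGROUND, BACKGROUND):
            raise ValidationError(f"{path}:{lineno}: unknown label {label!r}")
        species.append(name)
        phenotype[name] = label
    return SpeciesPanel(species_ids=species, phenotype=phenotype)


def read_tree_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree (branch lengths optional, polytomies allowed)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree


def read_alignment_fasta(
    path: str | Path,
    panel: SpeciesPanel,
    *,
    gene_id: str | None = None,
    allow_missing: bool = False,
) -> OrthologAlignment:
    """Read a protein alignment FASTA whose headers are panel species names.

    Headers not in the panel are an error.  Panel species absent from the file
    are an error unless ``allow_missing`` is set, in which case they become
    all-``'X'`` rows (non-informative everywhere).
    """
    gene = gene_id or Path(path).stem
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name not in panel.phenotype:
            raise ValidationError(f"{path}: header {name!r} is not a panel species")
        if name in rows:
            raise ValidationError(f"{path}: duplicate header {name!r}")
        rows[name] = str(rec.seq).upper()
    if not rows:
        raise ValidationError(f"{path}: no FASTA records")
    missing = [s for s in panel.species_ids if s not in rows]
    if missing:
        if not allow_missing:
            raise ValidationError(
                f"{path}: panel species missing from alignment: {missing} "
                "(pass allow_missing=True to pad with 'X')"
            )
        length = len(next(iter(rows.values())))
        for s in missing:
            rows[s] = "X" * length
    # preserve panel order for determinism
    rows = {s: rows[s] for s in panel.species_ids if s in rows}
    return OrthologAlignment(gene_id=gene, rows=rows)


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """One codon to one residue; gaps to '-', ambiguity and stops to 'X'."""
    codon = codon.upper()
    if codon == "---":
        return "-"
    if set(codon) - set(NUCLEOTIDES):
        return "X"
    if codon in _STANDARD_TABLE.stop_codons:
        return "X"
    return _STANDARD_TABLE.forward_table[codon]


def read_codon_alignment_fasta(
    path: str | Path,
    *,
    gene_id: str | None = None,
) -> OrthologAlignment:
    """Read an aligned in-frame nucleotide FASTA as a codon alignment.

    Protein rows are derived by translation (codon ``---`` to gap, partial
    gaps/N/stops to ``'X'``); sequence length must be divisible by 3.
    """
    gene = gene_id or Path(path).stem
    codon_rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in codon_rows:
            raise ValidationError(f"{path}: duplicate header {rec.id!r}")
        seq = str(rec.seq).upper()
        if len(seq) % 3:
            raise ValidationError(f"{path}/{rec.id}: length {len(seq)} not divisible by 3")
        codon_rows[rec.id] = seq
    if not codon_rows:
        raise ValidationError(f"{path}: no FASTA records")
    rows = {
        sp: "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))
        for sp, seq in codon_rows.items()
    }
    return OrthologAlignment(gene_id=gene, rows=rows, codon_rows=codon_rows)


def write_alignment_fasta(alignment: OrthologAlignment, path: str | Path) -> None:
    """Write the protein rows of an alignment as FASTA (one record per species)."""
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in alignment.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_pathways_gmt(path: str | Path, universe: Iterable[str]) -> PathwayTable:
    """Read a GMT file (pathway_id, description, genes...) against a universe.

    Genes outside the universe are dropped with a warning; pathways empty after
    filtering are dropped.
    """
    universe = frozenset(universe)
    pathways: dict[str, frozenset[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: GMT line needs at least id and description")
        pid = parts[0].strip()
        if not pid:
            raise ValidationError(f"{path}:{lineno}: empty pathway id")
        if pid in pathways:
            raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
        genes = {g.strip() for g in parts[2:] if g.strip()}
        dropped = genes - universe
        if dropped:
            log.warning("%s:%d: pathway %s: dropping %d gene(s) outside universe: %s",
                        path, lineno, pid, len(dropped), sorted(dropped))
        kept = genes & universe
        if not kept:
            log.warning("%s:%d: pathway %s empty after universe filter; dropped", path, lineno, pid)
            continue
        pathways[pid] = frozenset(kept)
    return PathwayTable(pathways=pathways, universe=universe)


def write_pathways_gmt(table: PathwayTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(table.pathways):
            genes = "\t".join(sorted(table.pathways[pid]))
            fh.write(f"{pid}\tna\t{genes}\n")


_VARIANT_COLUMNS = ["sequence_id", "pos", "ref", "alt", "genotype", "qual", "depth"]


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read the minimal variant TSV (sequence_id, pos, ref, alt, genotype, qual, depth).

    ``pos`` is 0-based.  A header row matching the column names is skipped.
    """
    records: list[VariantRecord] = []
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if parts == _VARIANT_COLUMNS:
            continue
        if len(parts) != 7:
            raise ValidationError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        seq_id, pos, ref, alt, gt, qual, depth = parts
        try:
            records.append(
                VariantRecord(
                    sequence_id=seq_id,
                    position=int(pos),
                    ref=ref.upper(),
                    alt=alt.upper(),
                    genotype=gt,
                    quality=float(qual),
                    depth=int(depth),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sequence_id}\t{r.position}\t{r.ref}\t{r.alt}\t{r.genotype}\t{r.quality:g}\t{r.depth}\n"
            )


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a minimal VCF 4.x variant input.

    Only CHROM (sequence id), POS (1-based, converted to 0-based), REF, ALT
    (first allele), QUAL, ``DP`` from INFO and the first sample's GT (het if
    the two alleles differ) are used; all other VCF features are ignored.
    """
    records: list[VariantRecord] = []
    for lineno, line in _data_lines(path):
        # _data_lines drops '#' lines, which covers the VCF header
        parts = line.split("\t")
        if len(parts) < 8:
            raise ValidationError(f"{path}:{lineno}: VCF line has {len(parts)} fields (<8)")
        chrom, pos, _id, ref, alt, qual, _filt, info = parts[:8]
        alt0 = alt.split(",")[0]
        depth = 0
        for kv in info.split(";"):
            if kv.startswith("DP="):
                depth = int(kv[3:])
        genotype = "hom"
        if len(parts) >= 10:
            gt = parts[9].split(":")[0].replace("|", "/")
            alleles = gt.split("/")
            if len(set(alleles)) > 1:
                genotype = "het"
        try:
            records.append(
                VariantRecord(
                    sequence_id=chrom,
                    position=int(pos) - 1,
                    ref=ref.upper(),
                    alt=alt0.upper(),
                    genotype=genotype,
                    quality=0.0 if qual == "." else float(qual),
                    depth=depth,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_depth_tsv(path: str | Path) -> dict[str, list[int]]:
    """Read per-position depth (columns sequence_id, pos, depth; pos 0-based,
    contiguous from 0 per sequence)."""
    depths: dict[str, dict[int, int]] = {}
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if parts == ["sequence_id", "pos", "depth"]:
            continue
        if len(parts) != 3:
            raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        seq_id, pos, depth = parts
        depths.setdefault(seq_id, {})[int(pos)] = int(depth)
    out: dict[str, list[int]] = {}
    for seq_id, by_pos in depths.items():
        n = max(by_pos) + 1
        if set(by_pos) != set(range(n)):
            raise ValidationError(f"{path}: depth positions for {seq_id!r} are not contiguous from 0")
        out[seq_id] = [by_pos[i] for i in range(n)]
    return out
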