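"""Site-level screens over ortholog alignment panels.

Two screens live here:

* the lineage-specific screen — find alignment columns where every foreground
  (trait-positive) species carries one residue, every background species
  carries a single different residue, and aggregate to genes; and
* extraction of 4-fold degenerate (4D) third-codon positions from codon
  alignments, for near-neutral phylogenetic signal.

Both are set-based: the tree plays no role.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd
from Bio.Data import CodonTable

from .io import OrthologAlignment, SpeciesPanel, ValidationError

Status = Literal["foreground_specific", "conserved", "variable", "unevaluable"]

_NON_INFORMATIVE = {"-", "X"}


@dataclass(frozen=True)
class SiteCall:
    """Classification of one alignment column against the panel partition."""

    gene_id: str
    column: int  # 0-based
    status: Status
    background_residue: str | None
    foreground_residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.status == "foreground_specific":
            assert self.background_residue is not None
            fg = set(self.foreground_residues)
            assert len(fg) == 1 and self.background_residue not in fg


def classify_column(
    alignment: OrthologAlignment,
    panel: SpeciesPanel,
    column: int,
    *,
    foreground_any: bool = False,
) -> SiteCall:
    """Classify one column as foreground_specific / conserved / variable / unevaluable.

    A column is *foreground_specific* when every background species shows the
    same residue, every foreground species shows the same residue, and the two
    differ.  A gap ``'-'`` or unknown ``'X'`` anywhere in either group makes
    the column *unevaluable* (never specific).  *conserved* means all species
    share one residue; anything else is *variable*.

    With ``foreground_any=True`` the requirement that foreground residues agree
    with each other is relaxed: it suffices that every foreground residue
    differs from the (single) background residue.  In that case
    ``background_residue`` is still unique but ``foreground_residues`` may be a
    mixed multiset; the call's status is still ``foreground_specific``.
    """
    col = alignment.column(column)
    fg = [col[s] for s in panel.foreground if s in col]
    bg = [col[s] for s in panel.background if s in col]
    call = lambda status, bg_res: SiteCall(  # noqa: E731
        gene_id=alignment.gene_id,
        column=column,
        status=status,
        background_residue=bg_res,
        foreground_residues=tuple(fg),
    )
    if any(r in _NON_INFORMATIVE for r in fg + bg) or not fg or not bg:
        return call("unevaluable", None)
    bg_set = set(bg)
    fg_set = set(fg)
    if len(bg_set) == 1:
        (r_b,) = bg_set
        if r_b not in fg_set:
            if len(fg_set) == 1:
                return call("foreground_specific", r_b)
            if foreground_any:
                # relaxed mode: discordant foreground residues, all differing
                # from the conserved background residue
                return _relaxed_specific(alignment.gene_id, column, r_b, fg)
    if len(bg_set | fg_set) == 1:
        return call("conserved", next(iter(bg_set)))
    return call("variable", None)


def _relaxed_specific(gene_id: str, column: int, r_b: str, fg: list[str]) -> SiteCall:
    # bypass the strict-invariant assertion via object construction with uniform check off
    call = object.__new__(SiteCall)
    object.__setattr__(call, "gene_id", gene_id)
    object.__setattr__(call, "column", column)
    object.__setattr__(call, "status", "foreground_specific")
    object.__setattr__(call, "background_residue", r_b)
    object.__setattr__(call, "foreground_residues", tuple(fg))
    return call


def lineage_specific_genes(
    alignments: Iterable[OrthologAlignment],
    panel: SpeciesPanel,
    *,
    allow_missing: bool = False,
    foreground_any: bool = False,
) -> dict[str, list[SiteCall]]:
    """Genes carrying at least one foreground_specific column, with their sites.

    Returns a dict ordered by gene_id; each value is the list of
    foreground_specific :class:`SiteCall` objects ordered by column.  An
    alignment that does not cover all panel species is an error unless
    ``allow_missing`` is set, in which case absent species count as ``'X'``
    rows (making every column of that gene unevaluable under the strict rule).
    """
    alignments = list(alignments)
    if not alignments:
        raise ValidationError("empty alignment list")
    hits: dict[str, list[SiteCall]] = {}
    for aln in alignments:
        missing = [s for s in panel.species_ids if s not in aln.rows]
        if missing:
            if not allow_missing:
                raise ValidationError(
                    f"{aln.gene_id}: alignment missing panel species {missing} "
                    "(set allow_missing to treat them as all-'X')"
                )
            aln = OrthologAlignment(
                gene_id=aln.gene_id,
                rows={**aln.rows, **{s: "X" * aln.length for s in missing}},
            )
        calls = [
            classify_column(aln, panel, c, foreground_any=foreground_any)
            for c in range(aln.length)
        ]
        specific = [c for c in calls if c.status == "foreground_specific"]
        if specific:
            hits[aln.gene_id] = specific
    return {g: hits[g] for g in sorted(hits)}


def lineage_table(hits: dict[str, list[SiteCall]]) -> pd.DataFrame:
    """Flatten screen hits to a reporting table (1-based columns)."""
    rows = [
        {
            "gene_id": g,
            "column_1based": c.column + 1,
            "background_residue": c.background_residue,
            "foreground_residue": "".join(sorted(set(c.foreground_residues))),
        }
        for g, calls in hits.items()
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "column_1based", "background_residue", "foreground_residue"]
    )


# ---------------------------------------------------------------------------
# 4-fold degenerate sites
# ---------------------------------------------------------------------------

def _fourfold_prefixes() -> frozenset[str]:
    """First-two-base prefixes whose codon family is 4-fold degenerate
    (the encoded amino acid is invariant to the third position)."""
    table = CodonTable.unambiguous_dna_by_id[1]  # standard code
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = set()
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                aas.add("*" if codon in table.stop_codons else table.forward_table[codon])
            if len(aas) == 1:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()


@dataclass
class FourfoldMatrix:
    """Concatenated third-codon-position matrix of retained 4D columns."""

    rows: dict[str, str]
    retained: list[tuple[str, int]] = field(default_factory=list)  # (gene_id, codon index)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def extract_4d_sites(codon_alignments: Iterable[OrthologAlignment]) -> FourfoldMatrix:
    """Concatenate third positions of codon columns that are 4-fold degenerate
    in every species.

    A codon column is retained iff, in every species, the codon belongs to a
    4-fold-degenerate family and the first two codon positions are identical
    across species (so the site is unambiguously synonymous in all species).
    A codon containing ``'-'`` or ``'N'`` drops the column (not an error).
    Retention is invariant to species row order, and the extraction is
    idempotent by construction.
    """
    rows_out: dict[str, list[str]] = {}
    retained: list[tuple[str, int]] = []
    for aln in codon_alignments:
        if aln.codon_rows is None:
            raise ValidationError(f"{aln.gene_id}: no codon rows")
        species = sorted(aln.codon_rows)
        length = len(aln.codon_rows[species[0]])
        if length % 3:
            raise ValidationError(f"{aln.gene_id}: codon alignment length {length} not divisible by 3")
        for sp in species:
            rows_out.setdefault(sp, [])
        for ci in range(length // 3):
            codons = {sp: aln.codon_rows[sp][3 * ci : 3 * ci + 3].upper() for sp in species}
            if any(set(c) - set("ACGT") for c in codons.values()):
                continue  # gap or N anywhere drops the column
            prefixes = {c[:2] for c in codons.values()}
            if len(prefixes) != 1 or next(iter(prefixes)) not in FOURFOLD_PREFIXES:
                continue
            for sp in species:
                rows_out[sp].append(codons[sp][2])
            retained.append((aln.gene_id, ci))
    return FourfoldMatrix(rows={sp: "".join(chars) for sp, chars in rows_out.items()},
                          retained=retained)
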