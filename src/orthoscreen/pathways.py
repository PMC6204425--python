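"""Pathway scoring of recently varied genes, with shared-gene propagation.

For pathway A with N(a) annotated genes of which n(a) are in the varied set,
the base score is n(a)/N(a).  Every other pathway B sharing O(ab) genes with A
contributes (e(b)/N(b)) * (O(ab)/N(a)), where e(b) counts the varied genes of
B excluding the members shared with A.  The total S(A) is the base plus all
contributions — a single propagation hop, no transitive closure.

The denominators N(a), N(b) are the focal-species pathway sizes from the
:class:`~orthoscreen.io.PathwayTable`, not global database sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .io import PathwayTable, ValidationError

EbMode = Literal["varied", "all-genes"]


@dataclass(frozen=True)
class PropagationTerm:
    """Contribution of one overlapping pathway B to S(A)."""

    pathway_id: str
    N_b: int
    O_ab: int
    e_b: int
    contribution: float


@dataclass(frozen=True)
class PathwayScore:
    """Full decomposition of one pathway's score, retained for audit."""

    pathway_id: str
    N_a: int
    n_a: int
    base: float
    terms: tuple[PropagationTerm, ...]
    S: float

    def __post_init__(self) -> None:
        assert self.S >= self.base >= 0.0
        assert all(t.contribution >= 0.0 for t in self.terms)


def score_pathway(
    A: str,
    varied: Iterable[str],
    table: PathwayTable,
    *,
    eb_mode: EbMode = "varied",
) -> PathwayScore:
    """Score pathway ``A`` given the varied gene set.

    ``eb_mode`` selects how e(b) is counted: ``"varied"`` (default) counts
    varied genes of B outside A; ``"all-genes"`` counts all genes of B outside
    A.  Only pathways B with a nonzero overlap O(ab) contribute, and terms are
    emitted in pathway_id order so the sum is order-independent.
    """
    if A not in table.pathways:
        raise ValidationError(f"pathway {A!r} not in table")
    varied = frozenset(varied)
    stray = varied - table.universe
    if stray:
        raise ValidationError(f"varied genes outside universe: {sorted(stray)}")
    genes_a = table.pathways[A]
    N_a = len(genes_a)
    n_a = len(varied & genes_a)
    base = n_a / N_a
    terms: list[PropagationTerm] = []
    for B in sorted(table.pathways):
        if B == A:
            continue
        genes_b = table.pathways[B]
        O_ab = len(genes_a & genes_b)
        if O_ab == 0:
            continue
        outside_a = genes_b - genes_a
        e_b = len((varied & outside_a) if eb_mode == "varied" else outside_a)
        contribution = (e_b / len(genes_b)) * (O_ab / N_a)
        terms.append(PropagationTerm(B, len(genes_b), O_ab, e_b, contribution))
    S = base + sum(t.contribution for t in terms)
    return PathwayScore(pathway_id=A, N_a=N_a, n_a=n_a, base=base, terms=tuple(terms), S=S)


def rank_pathways(
    varied: Iterable[str],
    table: PathwayTable,
    *,
    eb_mode: EbMode = "varied",
) -> list[PathwayScore]:
    """Score every pathway; descending by S, ties broken by pathway_id."""
    varied = frozenset(varied)
    scores = [score_pathway(p, varied, table, eb_mode=eb_mode) for p in table.pathways]
    return sorted(scores, key=lambda s: (-s.S, s.pathway_id))


def score_table(scores: Iterable[PathwayScore]) -> pd.DataFrame:
    """Reporting table: pathway_id, N_a, n_a, base, n_terms, S, rank."""
    rows = [
        {
            "pathway_id": s.pathway_id,
            "N_a": s.N_a,
            "n_a": s.n_a,
            "base": s.base,
            "n_terms": len(s.terms),
            "S": s.S,
            "rank": i + 1,
        }
        for i, s in enumerate(scores)
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "N_a", "n_a", "base", "n_terms", "S", "rank"])
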