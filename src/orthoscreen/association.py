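"""Phenotype-partitioned site-by-site exact association scan.

For every alignment column and every amino-acid allele carried by at least one
trait-positive (foreground) species, the scan asks: if the k carriers of the
allele had been drawn at random from the N informative species at the column,
how surprising is it that m or more of them are among the K foreground
species?  That upper hypergeometric tail probability is computed exactly in
integer arithmetic — no normal approximation — and columns passing the
significance threshold (raw P < 0.001 by default) are aggregated to candidate
genes.

The test deliberately ignores tree structure: species are exchangeable under
the null, exactly as in the forward-genomics-style screen it implements.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Literal

import pandas as pd

from .io import OrthologAlignment, SpeciesPanel, ValidationError

_NON_INFORMATIVE = {"-", "X"}

Correction = Literal["none", "bonferroni", "bh"]


@dataclass(frozen=True)
class AlleleAssociation:
    """One tested (column, allele) pair with its exact tail probability.

    N — informative species at the column (gap/'X' carriers excluded);
    K — foreground species among them; k — carriers of the allele;
    m — foreground carriers.  ``exclusive`` flags k == m (the allele is absent
    from every background species).
    """

    gene_id: str
    column: int  # 0-based
    allele: str
    N: int
    K: int
    k: int
    m: int
    p_value: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0
        assert self.m <= min(self.K, self.k) and self.k <= self.N

    @property
    def exclusive(self) -> bool:
        return self.k == self.m


def hypergeom_tail(N: int, K: int, k: int, m: int) -> float:
    """Exact upper tail P(X >= m) for X ~ Hypergeometric(N, K, k).

    X counts foreground species among k carriers drawn without replacement
    from a panel of N species containing K foreground.  Evaluated as an exact
    rational sum of binomial-coefficient terms, then converted to float.
    """
    if not (0 <= K <= N and 0 <= k <= N and 0 <= m <= min(K, k)):
        raise ValidationError(f"invalid hypergeometric parameters N={N} K={K} k={k} m={m}")
    if m <= max(0, k - (N - K)):
        return 1.0
    total = comb(N, k)
    tail = sum(comb(K, i) * comb(N - K, k - i) for i in range(m, min(K, k) + 1))
    return float(Fraction(tail, total))


def hypergeom_tail_exact(N: int, K: int, k: int, m: int) -> Fraction:
    """As :func:`hypergeom_tail` but returning the exact rational value."""
    if not (0 <= K <= N and 0 <= k <= N and 0 <= m <= min(K, k)):
        raise ValidationError(f"invalid hypergeometric parameters N={N} K={K} k={k} m={m}")
    tail = sum(comb(K, i) * comb(N - K, k - i) for i in range(m, min(K, k) + 1))
    return Fraction(tail, comb(N, k))


def _column_best(
    aln: OrthologAlignment, panel: SpeciesPanel, column: int
) -> AlleleAssociation | None:
    """Minimum-p allele association at one column, or None if nothing testable.

    Missing species and gap/'X' carriers shrink the column-local panel rather
    than disqualifying the column.  Ties among alleles with equal minimal p
    break by residue alphabetical order.
    """
    col = aln.column(column)
    informative = {
        sp: r for sp, r in col.items() if r not in _NON_INFORMATIVE
    }
    fg = [sp for sp in informative if panel.phenotype[sp] == "foreground"]
    N = len(informative)
    K = len(fg)
    if K == 0 or N == K:
        return None
    fg_alleles = sorted({informative[sp] for sp in fg})
    best: AlleleAssociation | None = None
    for allele in fg_alleles:
        k = sum(1 for r in informative.values() if r == allele)
        m = sum(1 for sp in fg if informative[sp] == allele)
        p = hypergeom_tail(N, K, k, m)
        if best is None or p < best.p_value:
            best = AlleleAssociation(
                gene_id=aln.gene_id, column=column, allele=allele,
                N=N, K=K, k=k, m=m, p_value=p,
            )
    return best


def site_association_scan(
    alignments: Iterable[OrthologAlignment],
    panel: SpeciesPanel,
    alpha: float = 0.001,
    *,
    correction: Correction = "none",
) -> list[AlleleAssociation]:
    """Scan all columns of all genes; return associations with p < alpha.

    Per column only the minimum-p allele (over alleles carried by >= 1
    foreground species) is reported.  No multiple-testing correction is
    applied by default; ``correction`` may request Bonferroni or
    Benjamini-Hochberg over all tested columns, in which case the adjusted
    p-value must clear alpha (reported p-values stay raw).
    Output is sorted by (gene_id, column, p_value).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    tested: list[AlleleAssociation] = []
    for aln in alignments:
        for c in range(aln.length):
            best = _column_best(aln, panel, c)
            if best is not None:
                tested.append(best)
    n_tests = len(tested)
    if correction == "none":
        kept = [a for a in tested if a.p_value < alpha]
    elif correction == "bonferroni":
        kept = [a for a in tested if a.p_value * n_tests < alpha]
    elif correction == "bh":
        order = sorted(range(n_tests), key=lambda i: tested[i].p_value)
        passing: set[int] = set()
        max_rank = 0
        for rank, idx in enumerate(order, 1):
            if tested[idx].p_value * n_tests / rank < alpha:
                max_rank = rank
        passing = set(order[:max_rank])
        kept = [a for i, a in enumerate(tested) if i in passing]
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return sorted(kept, key=lambda a: (a.gene_id, a.column, a.p_value))


def candidate_genes(associations: Iterable[AlleleAssociation]) -> pd.DataFrame:
    """Gene-level aggregation: one row per gene with >= 1 passing site.

    Columns gene_id, best_p, n_sites; ordered by best_p then gene_id.
    """
    by_gene: dict[str, list[float]] = {}
    for a in associations:
        by_gene.setdefault(a.gene_id, []).append(a.p_value)
    rows = [
        {"gene_id": g, "best_p": min(ps), "n_sites": len(ps)}
        for g, ps in by_gene.items()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "best_p", "n_sites"])
    if not df.empty:
        df = df.sort_values(["best_p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return df


def association_table(associations: Iterable[AlleleAssociation]) -> pd.DataFrame:
    """Reporting table (1-based columns) for the scan output."""
    rows = [
        {
            "gene_id": a.gene_id,
            "column_1based": a.column + 1,
            "allele": a.allele,
            "N": a.N,
            "K": a.K,
            "k": a.k,
            "m": a.m,
            "p_value": a.p_value,
            "exclusive": a.exclusive,
        }
        for a in associations
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "column_1based", "allele", "N", "K", "k", "m", "p_value", "exclusive"],
    )
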