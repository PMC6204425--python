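"""Site-level variant filtering and putative ortholog-sequence construction.

The consensus builder reconstructs a sister taxon's gene sequence from a
reference by applying homozygous substitutions and short indels that survive
the site-level filter policy (Phred quality >= 20, mapped depth within
[5, 120] by default), then masking every position whose depth falls outside
the accepted range to ``'N'``.  Heterozygous records are skipped (with a
logged count); read-level alignment plausibility rules are upstream of this
module and out of its scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import ValidationError, VariantRecord

log = logging.getLogger(__name__)

MAX_INDEL_BP = 5


@dataclass(frozen=True)
class FilterPolicy:
    """Site-level retention thresholds.

    Records are retained when quality >= ``min_quality`` and ``min_depth`` <=
    depth <= ``max_depth``; the boundaries are inclusive because the removal
    conditions are strict inequalities (quality < 20, depth < 5 or > 120).
    """

    min_quality: float = 20.0
    min_depth: int = 5
    max_depth: int = 120

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValidationError(f"min_depth {self.min_depth} > max_depth {self.max_depth}")
        if self.min_quality < 0:
            raise ValidationError(f"negative min_quality {self.min_quality}")

    def keeps(self, record: VariantRecord) -> bool:
        return (
            record.quality >= self.min_quality
            and self.min_depth <= record.depth <= self.max_depth
        )

    def depth_ok(self, depth: int) -> bool:
        return self.min_depth <= depth <= self.max_depth


@dataclass
class DepthTrack:
    """Per-position mapped depth along one reference sequence."""

    sequence_id: str
    depths: list[int]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise ValidationError(f"{self.sequence_id}: negative depth")

    def __len__(self) -> int:
        return len(self.depths)


def filter_variants(records: list[VariantRecord], policy: FilterPolicy) -> list[VariantRecord]:
    """Retain records passing the site-level policy; order preserved.

    Idempotent: filtering a filtered list is the identity.
    """
    return [r for r in records if policy.keeps(r)]


def build_putative_sequence(
    reference: str,
    records: list[VariantRecord],
    depth: DepthTrack,
    policy: FilterPolicy,
) -> str:
    """Apply homozygous variants to a reference and N-mask out-of-range depths.

    Substitutions and indels (VCF-style anchored ref/alt strings, net length
    change <= 5 bp) are applied right-to-left so earlier coordinates stay
    valid; heterozygous records are skipped with a logged count.  Afterwards
    every reference position whose depth is outside the accepted range is
    masked to ``'N'`` (an insertion anchored at a masked position is masked
    with it; a deleted position leaves nothing to mask).
    """
    reference = reference.upper()
    if len(depth) != len(reference):
        raise ValidationError(
            f"depth track length {len(depth)} != reference length {len(reference)}"
        )
    # one output fragment per reference position; indels splice fragments
    out: list[str] = list(reference)
    n_het = 0
    spans: list[tuple[int, int]] = []  # [start, end) of applied edits, for overlap checks
    for rec in sorted(records, key=lambda r: r.position, reverse=True):
        if rec.genotype == "het":
            n_het += 1
            continue
        start, end = rec.position, rec.position + len(rec.ref)
        if end > len(reference):
            raise ValidationError(
                f"{rec.sequence_id}: record at {rec.position} runs past reference end"
            )
        if reference[start:end] != rec.ref:
            raise ValidationError(
                f"{rec.sequence_id}: ref mismatch at position {rec.position} "
                f"(expected {rec.ref!r}, reference has {reference[start:end]!r})"
            )
        if abs(len(rec.alt) - len(rec.ref)) > MAX_INDEL_BP:
            raise ValidationError(
                f"{rec.sequence_id}: indel at {rec.position} exceeds {MAX_INDEL_BP} bp"
            )
        for s, e in spans:
            if start < e and s < end:
                raise ValidationError(
                    f"{rec.sequence_id}: overlapping edits at positions {start} and {s}"
                )
        spans.append((start, end))
        out[start] = rec.alt
        for i in range(start + 1, end):
            out[i] = ""
    if n_het:
        log.info("skipped %d heterozygous record(s)", n_het)
    for i, d in enumerate(depth.depths):
        if not policy.depth_ok(d):
            out[i] = "N" * len(out[i])
    return "".join(out)


def pairwise_divergence(snp_count: int, indel_bases: int, callable_sites: int) -> float:
    """Proportion of diverged bases: (snp_count + indel_bases) / callable_sites.

    The caller supplies the callable-site denominator explicitly; formatting
    to percent happens at the reporting boundary.
    """
    if callable_sites <= 0:
        raise ValidationError(f"callable_sites must be positive, got {callable_sites}")
    if snp_count < 0 or indel_bases < 0:
        raise ValidationError("counts must be non-negative")
    return (snp_count + indel_bases) / callable_sites
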