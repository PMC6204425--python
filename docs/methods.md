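# Methods

## The screens and their assumptions

### Lineage-specific background-conserved sites

The column rule is a strict set comparison, with no phylogenetic weighting:
a column is *foreground-specific* iff (a) every background species carries
one residue r_b, (b) every foreground species carries one residue r_f, and
(c) r_f ≠ r_b. A gap (`-`) or unknown residue (`X`) anywhere in the column,
in either group, makes it *unevaluable*, never specific; the two symbols are
kept distinct (alignment gap vs. unknown residue) but both are
non-informative. This strictness stands in for evidence-based filtering of
candidate sites (transcript support, domain annotation), which is outside
this package's scope: a site that cannot be evaluated in every panel member
is not claimed.

When the foreground has more than one species, the default requires the
foreground residues to agree with each other (strict convergence):
discordant foreground residues cannot represent a shared lineage variant.
`foreground_any=True` (CLI `--foreground-any`) relaxes this to "every
foreground residue differs from the conserved background residue", for users
screening heterogeneous foreground groups.

Orthologs are often missing in real panels. The screen's default treats an
alignment that does not cover the panel as an error; `allow_missing` pads
absent species with `X` rows, which under the strict rule makes every column
of that gene unevaluable. This deliberately records, rather than resolves,
the ambiguity of how missing species should count against a
background-conservation claim.

Because the comparison is at the protein level, every reported difference is
nonsynonymous by construction; codon-level synonymy checking is not
attempted.

### Exact hypergeometric association scan

Under the null, the k carriers of an allele are an exchangeable draw from the
N informative species at the column; the reported quantity is the exact upper
tail P(X ≥ m) for X ~ Hypergeometric(N, K, k). The tail is evaluated as a sum
of integer binomial-coefficient products over an exact rational, then
converted to float — no approximation of any kind, so complementarity
P(X ≥ m) + P(X ≤ m−1) = 1 holds exactly. Parameter domain: 0 ≤ m ≤ min(K, k),
k ≤ N, K ≤ N; violations raise.

Scan policy choices, each exposed to the caller:

* every allele carried by ≥ 1 foreground species is tested; per column only
  the minimum-p allele is reported, ties broken by residue alphabetical order;
* the default threshold is raw P < 0.001 with no multiple-testing correction;
  Bonferroni and Benjamini–Hochberg are available (`correction=`), applied
  over all tested columns, with reported p-values kept raw;
* gap/`X` carriers are excluded from N, K, k and m (column-local panel), so
  the test stays exact for genes with missing species;
* exclusivity (k = m, the allele absent from all background species) is
  flagged in the output rather than required, since enrichment without
  exclusivity is also a reportable pattern.

The test deliberately ignores tree structure — species are exchangeable under
its null. On real clades this inflates apparent convergence where foreground
species are phylogenetically clustered; the screen is a ranking device, not a
calibrated phylogenetic test.

### Pathway score

S(A) = n(a)/N(a) + Σ_B (e(b)/N(b))·(O(ab)/N(a)) over pathways B with
O(ab) = |A ∩ B| > 0. Two readings of e(b) are possible from the verbal
definition; the default counts *varied* genes of B excluding members shared
with A, because the propagation term then transports observed variation
signal, not mere membership, into A. The alternative (all genes of B minus
shared) is available as `eb_mode="all-genes"`. Denominators N(a), N(b) are
the focal-species pathway sizes from the supplied table, not global database
sizes. Propagation is single-hop exactly as defined; terms are accumulated in
pathway-id order so sums are order-independent to machine precision.
Direct consequences used as tests: S is monotone in the varied set, and with
pairwise disjoint pathways S(A) = n(a)/N(a) exactly.

### 4-fold degenerate sites

A third-codon-position column is retained iff every species' codon belongs to
a 4-fold degenerate family *and* the first two codon positions are identical
across species. The 4D families are enumerated from the standard genetic code
at import (prefixes CT, GT, TC, CC, AC, GC, CG, GG). The cross-species
identity requirement is the stricter of the two possible readings of "sites
that do not change the amino acid": it guarantees the retained site is
synonymous in every species simultaneously. Codons containing `-` or `N`
drop the column without error; a length not divisible by 3 is an error.
Extraction is idempotent and invariant to species row order.

### Variant filter and consensus

Filters are stated as removal conditions with strict inequalities (quality
< 20; depth < 5 or > 120), so the boundaries 20, 5 and 120 are retained.
Consensus construction applies homozygous substitutions and anchored indels
(net length change ≤ 5 bp, mirroring short-indel calling scope; longer indels
are an error) right-to-left so coordinates stay valid; heterozygous records
are skipped with a logged count; overlapping edits and reference mismatches
are errors naming the position. Afterwards every reference position with
out-of-range depth is masked to `N`; an insertion anchored at a masked
position is masked with it, and a deleted position leaves nothing to mask.
Masking commutes with substitution at non-overlapping positions (property
tested). The pairwise divergence helper takes the callable-site denominator
explicitly — the package does not presume which denominator (assembly vs.
callable length) a user's headline percentage should use.

## The synthetic generator

The generator emulates the study conditions the screens assume, and its
defaults are those conditions: a 46-species panel with 7 foreground species
(with an 18-species / 2-foreground variant), 50 genes × 300 residues,
20 planted fully convergent foreground-exclusive sites on distinct genes, and
scan threshold α = 0.001.

* **Tree and panel.** Topology is a uniform random join of tips; every edge
  carries the same branch length (default 0.05 expected substitutions/site, a
  desk-scale stand-in for within-order divergence). Foreground tips are drawn
  at random, so the trait is phylogenetically scattered as in a convergence
  design. Branch lengths matter only to the simulator — both screens are
  set-based.
* **Substitution process.** Uniform exchange among the 20 amino acids with
  Poisson(t) event counts per site per branch — the simplest process with a
  known (uniform) stationary distribution, which the tests verify by χ²
  goodness-of-fit. Empirical exchange matrices (JTT and kin) would change
  nothing about the screens' set-based logic and are not modelled.
* **Planting** replaces the evolved column after simulation, guaranteeing the
  intended genotype pattern independent of branch lengths. Modes:
  fully convergent foreground-exclusive, partially penetrant (m of K), and
  background-polymorphic (a non-conserved background, for negative controls).
* **Pathway tables** draw each pathway's overlap share from a common core
  pool, so requested pairwise overlap is achieved in expectation (exactly,
  for equal sizes), with the remainders pairwise disjoint; infeasible
  requests error rather than silently truncate.
* **Variant tables** sample distinct positions with ref matching the
  reference; quality and depth come from caller-supplied distributions or
  sequences (cycled in order, which is how boundary values are planted), with
  defaults quality ~ Uniform(10, 50) and depth ~ Poisson(45) (≈45× genome
  coverage).

What the generator does *not* emulate: rate heterogeneity across sites and
lineages, indel evolution, codon-level selection, alignment error, and
correlated ortholog missingness. Passing tests therefore demonstrate the
screens' correctness and calibration under exchangeability — not robustness
to phylogenetic clustering of the foreground, which the underlying test
ignores by design.

## Numerical and engineering choices

* The hypergeometric tail uses Python integer binomials and `Fraction`
  division; values are exact until the final float conversion. The full-grid
  acceptance check against exhaustive subset enumeration runs at N ≤ 12
  (≈ 3,300 parameter combinations) — enumeration above that costs more than
  it verifies.
* Coordinates are 0-based half-open internally; 1-based only in output tables
  and when converting VCF POS.
* All tie-breaks are deterministic (alphabetical residue, pathway id, gene
  id); every simulation consumes a single integer seed; pipeline outputs are
  byte-identical across runs with the same scientific parameters, which is
  why stage timings are returned in memory but not written to the report
  file.
* The full synthetic pipeline clamps the pathway design to the simulated
  gene universe (sizes ≤ half the gene count, backing off the pathway count
  until the disjoint private portions fit) so that small runs remain valid.
* Problem sizes in the test and acceptance suites (50 × 300 panels, 10,000
  null columns, 500-codon toy alignments) are chosen as the smallest scales
  at which the statistical properties under test are sharp; everything runs
  in seconds on one CPU.

## Known limitations

* No phylogenetic correction in the association scan (by design, see above).
* The lineage screen's `allow_missing` mode cannot rescue genes with absent
  orthologs under the strict column rule; users wanting column-local
  background panels should use the association scan instead.
* Consensus construction is haploid: heterozygous calls are skipped, not
  encoded as IUPAC ambiguity.
* The divergence helper reports a proportion only; it takes no position on
  the correct denominator for any particular published figure.
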