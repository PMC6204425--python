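"""Site screen: column classification against a brute-force oracle, gene-level
aggregation over planted simulations, and 4D-site extraction against a
codon-table enumeration oracle."""

import random

import pytest

from orthoscreen.io import AMINO_ACIDS, OrthologAlignment, SpeciesPanel
from orthoscreen.io import ValidationError
from orthoscreen.simulate import (
    PlantedSite,
    SimulationConfig,
    make_panel,
    simulate_alignment_set,
    simulate_codon_alignment,
)
from orthoscreen.sites import (
    FOURFOLD_PREFIXES,
    classify_column,
    extract_4d_sites,
    lineage_specific_genes,
)

from conftest import make_alignment


def brute_force_status(fg: list[str], bg: list[str]) -> str:
    """Independent re-statement of the column rule by direct set comparison."""
    if any(r in "-X" for r in fg + bg):
        return "unevaluable"
    if len(set(bg)) == 1 and len(set(fg)) == 1 and set(fg) != set(bg):
        return "foreground_specific"
    if len(set(fg + bg)) == 1:
        return "conserved"
    return "variable"


def column_alignment(panel: SpeciesPanel, col: dict[str, str]) -> OrthologAlignment:
    return make_alignment({s: col[s] for s in panel.species_ids})


class TestClassifyColumn:
    def test_two_foreground_sixteen_background_specific(self, pheasant_style_panel):
        col = {s: "A" for s in pheasant_style_panel.background}
        col.update({s: "V" for s in pheasant_style_panel.foreground})
        call = classify_column(column_alignment(pheasant_style_panel, col),
                               pheasant_style_panel, 0)
        assert call.status == "foreground_specific"
        assert call.background_residue == "A"
        assert set(call.foreground_residues) == {"V"}

    def test_identity_column_conserved(self, pheasant_style_panel):
        col = {s: "A" for s in pheasant_style_panel.species_ids}
        call = classify_column(column_alignment(pheasant_style_panel, col),
                               pheasant_style_panel, 0)
        assert call.status == "conserved"

    def test_discordant_foreground_is_variable_not_specific(self, small_panel):
        col = {s: "A" for s in small_panel.background}
        col.update({"fg1": "V", "fg2": "I"})
        call = classify_column(column_alignment(small_panel, col), small_panel, 0)
        assert call.status == "variable"

    def test_gap_or_x_anywhere_makes_unevaluable(self, small_panel):
        for bad, where in [("-", "bg1"), ("X", "fg1")]:
            col = {s: "A" for s in small_panel.species_ids}
            col.update({"fg1": "V", "fg2": "V"})
            col[where] = bad
            call = classify_column(column_alignment(small_panel, col), small_panel, 0)
            assert call.status == "unevaluable"

    def test_background_carrier_of_foreground_residue_flips_to_variable(self, small_panel):
        col = {s: "A" for s in small_panel.background}
        col.update({"fg1": "V", "fg2": "V"})
        aln = column_alignment(small_panel, col)
        assert classify_column(aln, small_panel, 0).status == "foreground_specific"
        col["bg2"] = "V"  # one background species now carries the foreground residue
        aln2 = column_alignment(small_panel, col)
        assert classify_column(aln2, small_panel, 0).status == "variable"

    def test_foreground_any_relaxation(self, small_panel):
        col = {s: "A" for s in small_panel.background}
        col.update({"fg1": "V", "fg2": "I"})
        aln = column_alignment(small_panel, col)
        assert classify_column(aln, small_panel, 0).status == "variable"
        relaxed = classify_column(aln, small_panel, 0, foreground_any=True)
        assert relaxed.status == "foreground_specific"
        assert relaxed.background_residue == "A"

    def test_agrees_with_brute_force_on_random_columns(self):
        """1,000 random 10-species columns (2 foreground) match the oracle."""
        species = [f"s{i}" for i in range(10)]
        panel = SpeciesPanel(
            species_ids=species,
            phenotype={s: ("foreground" if i < 2 else "background")
                       for i, s in enumerate(species)},
        )
        rng = random.Random(42)
        residues = AMINO_ACIDS + "-X"
        for _ in range(1000):
            col = {s: rng.choice(residues) for s in species}
            aln = column_alignment(panel, col)
            expected = brute_force_status(
                [col[s] for s in panel.foreground], [col[s] for s in panel.background]
            )
            assert classify_column(aln, panel, 0).status == expected


class TestLineageScreen:
    def test_planted_genes_exactly_recovered(self):
        panel = make_panel(18, 2, seed=3, branch_length=0.0)
        planted = tuple(
            PlantedSite(gene=g, column=10 * g, mode="foreground_specific_convergent")
            for g in (1, 4, 7)
        )
        alignments = simulate_alignment_set(
            SimulationConfig(panel=panel, n_genes=10, gene_length=100,
                             planted_sites=planted, seed=3)
        )
        hits = lineage_specific_genes(alignments, panel)
        assert sorted(hits) == ["gene0002", "gene0005", "gene0008"]
        for gene, site in zip(sorted(hits), (10, 40, 70)):
            assert [c.column for c in hits[gene]] == [site]

    def test_zero_rate_no_planting_is_empty(self):
        panel = make_panel(18, 2, seed=3, branch_length=0.0)
        alignments = simulate_alignment_set(
            SimulationConfig(panel=panel, n_genes=5, gene_length=50, seed=3)
        )
        assert lineage_specific_genes(alignments, panel) == {}

    def test_gapped_neighbour_column_not_reported(self, small_panel):
        rows = {s: "AA" for s in small_panel.background}
        rows.update({"fg1": "V-", "fg2": "V-"})
        hits = lineage_specific_genes([make_alignment(rows)], small_panel)
        assert [c.column for c in hits["geneA"]] == [0]

    def test_missing_species_needs_flag(self, small_panel):
        rows = {s: "AA" for s in small_panel.species_ids[:-1]}
        with pytest.raises(ValidationError):
            lineage_specific_genes([make_alignment(rows)], small_panel)
        hits = lineage_specific_genes([make_alignment(rows)], small_panel,
                                      allow_missing=True)
        assert hits == {}  # padded 'X' rows make every column unevaluable


def oracle_translate(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def oracle_4d_columns(aln: OrthologAlignment) -> list[int]:
    """Codon-table enumeration oracle: retained codon indices."""
    species = list(aln.codon_rows)
    n = len(aln.codon_rows[species[0]]) // 3
    out = []
    for ci in range(n):
        codons = [aln.codon_rows[s][3 * ci: 3 * ci + 3] for s in species]
        if any(set(c) - set("ACGT") for c in codons):
            continue
        if len({c[:2] for c in codons}) != 1:
            continue
        # 4-fold: all four third bases give one amino acid, none a stop
        family = {oracle_translate(codons[0][:2] + b) for b in "ACGT"}
        if len(family) == 1 and "*" not in family:
            out.append(ci)
    return out


class TestFourfold:
    def test_known_codon_families(self):
        # Gly GGN retained; Met ATG and split-prefix columns dropped
        aln = OrthologAlignment(
            "g", rows={"s1": "GMG", "s2": "GMR"},
            codon_rows={"s1": "GGGATGGGA", "s2": "GGAATGCGA"},
        )
        matrix = extract_4d_sites([aln])
        assert matrix.retained == [("g", 0)]
        assert matrix.rows == {"s1": "G", "s2": "A"}

    def test_matches_enumeration_oracle_on_random_alignment(self):
        aln = simulate_codon_alignment([f"s{i}" for i in range(6)], 500, seed=11)
        matrix = extract_4d_sites([aln])
        assert [ci for g, ci in matrix.retained] == oracle_4d_columns(aln)

    def test_idempotent_and_row_order_invariant(self):
        aln = simulate_codon_alignment(["a", "b", "c"], 200, seed=5)
        m1 = extract_4d_sites([aln])
        rev = OrthologAlignment(
            aln.gene_id,
            rows=dict(reversed(list(aln.rows.items()))),
            codon_rows=dict(reversed(list(aln.codon_rows.items()))),
        )
        m2 = extract_4d_sites([rev])
        assert m1.retained == m2.retained
        assert m1.rows == m2.rows
        # idempotence: re-extracting from the emitted matrix retains everything
        if m1.length:
            again = OrthologAlignment(
                "m",
                rows={s: "G" * m1.length for s in m1.rows},  # placeholder protein
                codon_rows={s: "".join("GG" + b for b in seq) for s, seq in m1.rows.items()},
            )
            assert extract_4d_sites([again]).length == m1.length

    def test_frame_break_is_error(self):
        # bypass the container's own validation to hit the extractor's check
        broken = OrthologAlignment.__new__(OrthologAlignment)
        broken.gene_id = "g"
        broken.rows = {"s1": "GM", "s2": "GM"}
        broken.codon_rows = {"s1": "GGGAT", "s2": "GGAAT"}
        with pytest.raises(ValidationError, match="divisible by 3"):
            extract_4d_sites([broken])

    def test_prefix_set_matches_standard_code(self):
        assert FOURFOLD_PREFIXES == {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
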