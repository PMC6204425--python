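import pytest
from hypothesis import settings

from orthoscreen.io import OrthologAlignment, SpeciesPanel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_panel() -> SpeciesPanel:
    """2 foreground + 4 background species, no tree (screens are set-based)."""
    species = ["fg1", "fg2", "bg1", "bg2", "bg3", "bg4"]
    phenotype = {s: ("foreground" if s.startswith("fg") else "background") for s in species}
    return SpeciesPanel(species_ids=species, phenotype=phenotype)


@pytest.fixture
def pheasant_style_panel() -> SpeciesPanel:
    """2-of-18 partition mirroring the two-pheasant versus 16-bird design."""
    species = [f"fg{i}" for i in range(1, 3)] + [f"bg{i:02d}" for i in range(1, 17)]
    phenotype = {s: ("foreground" if s.startswith("fg") else "background") for s in species}
    return SpeciesPanel(species_ids=species, phenotype=phenotype)


def make_alignment(columns: dict[str, str], gene_id: str = "geneA") -> OrthologAlignment:
    """Build an alignment from per-species residue strings (each a row)."""
    return OrthologAlignment(gene_id=gene_id, rows=columns)
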