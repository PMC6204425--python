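"""End-to-end synthetic runs: simulate a panel, run both screens, score pathways.

A :func:`run_full_synthetic` run is fully determined by its
:class:`RunConfig`: output files are byte-identical across repeated runs with
the same config.  Every output file carries a header comment declaring the
tool version, a hash of the config, and the seed.  Stage timings are returned
in the in-memory report but kept out of the written report so the written
outputs stay reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import association_table, candidate_genes, site_association_scan
from .io import SpeciesPanel, ValidationError, write_alignment_fasta, write_pathways_gmt
from .pathways import rank_pathways, score_table
from .simulate import (
    PlantedSite,
    SimulationConfig,
    make_panel,
    simulate_alignment_set,
    simulate_pathway_table,
)
from .sites import lineage_specific_genes, lineage_table


@dataclass
class RunConfig:
    """Parameters of a full synthetic run.

    Defaults mirror the study design the screens target: a 46-species panel
    with 7 trait-positive species, 50 genes of 300 residues, 20 planted
    fully convergent foreground-exclusive sites on 20 distinct genes, and the
    raw significance threshold alpha = 0.001.
    """

    out_dir: str = "run"
    seed: int = 0
    n_species: int = 46
    n_foreground: int = 7
    n_genes: int = 50
    gene_length: int = 300
    n_planted: int = 20
    branch_length: float = 0.05
    alpha: float = 0.001
    correction: str = "none"
    n_pathways: int = 8
    pathway_size_range: tuple[int, int] = (5, 10)
    pathway_overlap: float = 0.3
    write_alignments: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.n_planted > self.n_genes:
            raise ValidationError("cannot plant more genes than simulated")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded, so
        the same run written elsewhere hashes identically)."""
        params = asdict(self)
        params.pop("out_dir")
        canonical = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# orthoscreen {__version__}\n"
        f"# config_hash={config.config_hash()}\n"
        f"# seed={config.seed}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def plan_planted_sites(config: RunConfig) -> tuple[PlantedSite, ...]:
    """Choose the planted convergent sites (distinct genes, random columns)."""
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(int(g) for g in rng.choice(config.n_genes, size=config.n_planted, replace=False))
    return tuple(
        PlantedSite(gene=g, column=int(rng.integers(config.gene_length)),
                    mode="foreground_specific_convergent")
        for g in genes
    )


def run_full_synthetic(config: RunConfig) -> dict:
    """Simulate, screen, test and score; write TSV outputs and a JSON report.

    Returns the report dict (which additionally carries per-stage timings);
    on any stage failure, partially written outputs are removed and the error
    re-raised with the failing stage named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    report: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    for p in written:
                        p.unlink(missing_ok=True)
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    with stage("simulate"):
        panel = make_panel(
            config.n_species, config.n_foreground,
            seed=config.seed, branch_length=config.branch_length,
        )
        planted = plan_planted_sites(config)
        sim = SimulationConfig(
            panel=panel, n_genes=config.n_genes, gene_length=config.gene_length,
            planted_sites=planted, seed=config.seed,
        )
        alignments = simulate_alignment_set(sim)
        panel_df = pd.DataFrame(
            {"species": panel.species_ids,
             "label": [panel.phenotype[s] for s in panel.species_ids]}
        )
        _write_tsv(panel_df, out_dir / "panel.tsv", config)
        written.append(out_dir / "panel.tsv")
        if config.write_alignments:
            aln_dir = out_dir / "alignments"
            aln_dir.mkdir(exist_ok=True)
            for aln in alignments:
                write_alignment_fasta(aln, aln_dir / f"{aln.gene_id}.fasta")
                written.append(aln_dir / f"{aln.gene_id}.fasta")

    planted_genes = sorted({f"gene{p.gene + 1:04d}" for p in planted})

    with stage("lineage_screen"):
        hits = lineage_specific_genes(alignments, panel)
        _write_tsv(lineage_table(hits), out_dir / "lineage_sites.tsv", config)
        written.append(out_dir / "lineage_sites.tsv")

    with stage("convergence_scan"):
        assoc = site_association_scan(
            alignments, panel, alpha=config.alpha, correction=config.correction,
        )
        _write_tsv(association_table(assoc), out_dir / "associations.tsv", config)
        written.append(out_dir / "associations.tsv")
        genes_df = candidate_genes(assoc)
        _write_tsv(genes_df, out_dir / "candidate_genes.tsv", config)
        written.append(out_dir / "candidate_genes.tsv")

    with stage("pathway_scoring"):
        gene_ids = [a.gene_id for a in alignments]
        # clamp the pathway design to the simulated universe: sizes cannot
        # exceed half the gene count, and the pathway count backs off until
        # the disjoint private portions fit
        lo, hi = config.pathway_size_range
        hi = min(hi, max(2, len(gene_ids) // 2))
        lo = min(lo, hi)
        n_pathways = config.n_pathways
        while True:
            try:
                table = simulate_pathway_table(
                    len(gene_ids), n_pathways, (lo, hi),
                    config.pathway_overlap, seed=config.seed + 2, universe=gene_ids,
                )
                break
            except ValidationError:
                if n_pathways == 1:
                    raise
                n_pathways -= 1
        write_pathways_gmt(table, out_dir / "pathways.gmt")
        written.append(out_dir / "pathways.gmt")
        varied = frozenset(hits)
        scores = rank_pathways(varied, table)
        _write_tsv(score_table(scores), out_dir / "pathway_scores.tsv", config)
        written.append(out_dir / "pathway_scores.tsv")

    lineage_genes = sorted(hits)
    assoc_genes = sorted({a.gene_id for a in assoc})
    report.update(
        {
            "planted_sites": len(planted),
            "planted_genes": planted_genes,
            "lineage_genes_found": lineage_genes,
            "lineage_recovered": sorted(set(planted_genes) & set(lineage_genes)),
            "lineage_false_positive_genes": sorted(set(lineage_genes) - set(planted_genes)),
            "assoc_genes_found": assoc_genes,
            "assoc_recovered": sorted(set(planted_genes) & set(assoc_genes)),
            "assoc_false_positive_genes": sorted(set(assoc_genes) - set(planted_genes)),
            "n_associations": len(assoc),
            "n_pathways_scored": len(table),
        }
    )
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(out_dir / "report.json")
    report["timings_seconds"] = timings
    return report
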