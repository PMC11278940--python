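"""End-to-end pipeline: ingest → prevalence filter → profiles → guilds →
cross-ecosystem comparison, with all artifacts exported as TSV/JSON.

Every number in the summary report is recomputable from the exported tables;
figures (UpSet, heatmap, network) are left to external plotting tools, for
which UpSetR-compatible matrices and annotated heatmap matrices are written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .compare import ecosystem_overlap
from .guilds import GUILDS, assign_guilds, guild_summary, heatmap_matrix
from .ingest import AnnotationTable, read_annotations
from .ontology import PATHWAYS, GuildRuleSet, PathwayOntology, load_pathway_ontology
from .profiles import (
    ProfileSet,
    apply_prevalence_filter,
    build_profiles,
    combination_counts,
    degree_distribution,
    percent_display,
    taxonomic_composition,
    versatile_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    inputs: dict[str, str | Path] = field(default_factory=dict)  # label -> path
    ontology_path: str | Path | None = None
    min_prevalence: int = 2
    other_threshold: int = 2
    outdir: str | Path = "nversa_out"

    def __post_init__(self) -> None:
        if self.min_prevalence < 1:
            raise ValueError("min_prevalence must be >= 1")


def export_upset(profiles: ProfileSet, path: str | Path,
                 counts_path: str | Path | None = None) -> None:
    """Write the binary taxon × pathway membership matrix (UpSet input).

    One row per taxon, one 0/1 column per pathway in canonical order.  When
    *counts_path* is given, the ranked exact-set combination counts are
    written alongside.
    """
    frame = profiles.to_frame()
    cols = ["taxon"] + [p.name for p in PATHWAYS]
    if frame.empty:
        frame = pd.DataFrame(columns=cols)
    frame[cols].to_csv(path, sep="\t", index=False)
    if counts_path is not None:
        combination_counts(profiles).to_frame().to_csv(
            counts_path, sep="\t", index=False
        )


def analyze_ecosystem(
    table: AnnotationTable,
    ontology: PathwayOntology,
    min_prevalence: int = 2,
    other_threshold: int = 2,
    outdir: str | Path | None = None,
) -> dict:
    """Analyze one ecosystem table; returns its summary block.

    When *outdir* is given, all per-ecosystem artifacts (profile tables,
    UpSet matrix, degree distribution, combination counts, guild
    assignments/summaries, heatmap matrices) are written there.
    """
    n_raw_species = len(set(table.species))
    filtered = apply_prevalence_filter(table, min_prevalence)
    species = build_profiles(filtered, ontology, level="species")
    genus = build_profiles(filtered, ontology, level="genus")

    sp_dist = degree_distribution(species)
    sp_count, sp_raw, sp_disp = versatile_fraction(sp_dist)
    g_dist = degree_distribution(genus)
    g_count, g_raw, g_disp = versatile_fraction(g_dist)

    versatile_combos = combination_counts(species, versatile_only=True)
    n_versatile = versatile_combos.total
    top = [
        {
            "pathways": "+".join(p.name for p in PATHWAYS if p in subset),
            "n": n,
            "percent_of_versatile": (
                percent_display(n, n_versatile) if n_versatile else 0
            ),
        }
        for subset, n in versatile_combos.ranked()[:10]
    ]

    composition = taxonomic_composition(
        species, versatile_only=True, other_threshold=other_threshold
    )
    assignments = assign_guilds(filtered, species, GuildRuleSet())
    summaries = {g: guild_summary(assignments, species, g) for g in GUILDS}

    block = {
        "ecosystem": table.ecosystem_label,
        "n_samples": len(table.samples),
        "n_species_raw": n_raw_species,
        "n_species": len(species),
        "n_genera": len(genus),
        "min_prevalence": min_prevalence,
        "species": {
            "degree_distribution": {
                str(k): sp_dist.counts.get(k, 0) for k in range(1, 9)
            },
            "versatile_count": sp_count,
            "versatile_percent_raw": sp_raw,
            "versatile_percent": sp_disp,
        },
        "genus": {
            "degree_distribution": {
                str(k): g_dist.counts.get(k, 0) for k in range(1, 9)
            },
            "versatile_count": g_count,
            "versatile_percent_raw": g_raw,
            "versatile_percent": g_disp,
        },
        "top_combinations": top,
        "versatile_taxonomic_composition": {
            label: {"n": n, "percent": pct} for label, (n, pct) in composition.items()
        },
        "guilds": {g: s.to_dict() for g, s in summaries.items()},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        species.to_frame().to_csv(outdir / "profiles_species.tsv", sep="\t", index=False)
        genus.to_frame().to_csv(outdir / "profiles_genus.tsv", sep="\t", index=False)
        sp_dist.to_frame().to_csv(
            outdir / "degree_distribution.tsv", sep="\t", index=False
        )
        export_upset(
            species, outdir / "upset_matrix.tsv", outdir / "combination_counts.tsv"
        )
        pd.DataFrame(
            [
                {
                    "species": a.species,
                    "guild": a.guild,
                    "nfixer": int(a.nfixer),
                    "evidence_genes": ",".join(sorted(a.evidence_genes)),
                    "flags": ",".join(sorted(a.flags)),
                }
                for a in assignments
            ]
        ).to_csv(outdir / "guild_assignments.tsv", sep="\t", index=False)
        with open(outdir / "guild_summary.json", "w", encoding="utf-8") as fh:
            json.dump({g: s.to_dict() for g, s in summaries.items()}, fh, indent=2)
        for g in GUILDS:
            hm = heatmap_matrix(assignments, species, g, other_threshold)
            hm.to_csv(outdir / f"heatmap_{g}.tsv", sep="\t", index=False)

    return block


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline over one or more ecosystem-labeled inputs.

    Returns the summary report (also written as ``summary.json`` under the
    output directory, with per-ecosystem artifacts in subdirectories); adds
    a cross-ecosystem overlap block when two or more inputs are given.
    """
    if not config.inputs:
        raise ValueError("no input tables configured")
    ontology = load_pathway_ontology(config.ontology_path)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"ecosystems": {}, "ontology_source": ontology.source}
    species_profiles: dict[str, ProfileSet] = {}
    for label, path in config.inputs.items():
        logger.info("ecosystem %r: reading %s", label, path)
        table = (
            path
            if isinstance(path, AnnotationTable)
            else read_annotations(path, ecosystem_label=label)
        )
        block = analyze_ecosystem(
            table,
            ontology,
            min_prevalence=config.min_prevalence,
            other_threshold=config.other_threshold,
            outdir=outdir / label,
        )
        report["ecosystems"][label] = block
        filtered = apply_prevalence_filter(table, config.min_prevalence)
        species_profiles[label] = build_profiles(filtered, ontology, "species")

    labels = list(species_profiles)
    if len(labels) >= 2:
        overlaps = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rep = ecosystem_overlap(
                    species_profiles[labels[i]], species_profiles[labels[j]]
                )
                overlaps.append(rep.to_dict())
        report["overlap"] = overlaps
        with open(outdir / "overlap_report.json", "w", encoding="utf-8") as fh:
            json.dump(overlaps, fh, indent=2)

    validate_summary(report)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report


def validate_summary(report: dict) -> None:
    """Schema/consistency check of a summary report.

    Verifies required keys and that every percentage is re-derivable from
    the adjacent counts under the shared display-rounding rule.
    """
    from .profiles import percent_display

    if "ecosystems" not in report:
        raise ValueError("summary missing 'ecosystems'")
    for label, block in report["ecosystems"].items():
        for key in ("n_species", "n_genera", "species", "genus", "guilds"):
            if key not in block:
                raise ValueError(f"summary[{label}] missing {key!r}")
        for level_key, n_key in (("species", "n_species"), ("genus", "n_genera")):
            lv = block[level_key]
            total = sum(lv["degree_distribution"].values())
            if total != block[n_key]:
                raise ValueError(
                    f"summary[{label}][{level_key}]: degree distribution sums to "
                    f"{total}, expected {block[n_key]}"
                )
            expect = percent_display(lv["versatile_count"], total) if total else 0
            if lv["versatile_percent"] != expect:
                raise ValueError(
                    f"summary[{label}][{level_key}]: versatile percent "
                    f"{lv['versatile_percent']} != recomputed {expect}"
                )
        for g, s in block["guilds"].items():
            if s["n_pure"] + s["n_versatile"] != s["n_total"]:
                raise ValueError(f"summary[{label}] guild {g}: pure+versatile != total")
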