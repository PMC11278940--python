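"""Pathway profiling: prevalence filtering, per-taxon pathway presence
vectors, versatility statistics, degree distributions, exact-set combination
counts and taxonomic composition.

A species detected in at least ``min_prevalence`` samples (default 2 — i.e.
"more than one sample") and carrying at least one gene of a nitrogen pathway
is a functional microbe of that pathway.  A taxon encoding two or more of the
eight pathways is *N-metabolically versatile*; the number of pathways it
encodes is its *degree* (1–8).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .ingest import AnnotationTable, Lineage, display_taxon, group_other
from .ontology import PATHWAYS, Pathway, PathwayOntology

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_display(numerator: int, denominator: int) -> int:
    return round_half_away(100.0 * numerator / denominator)


@dataclass(frozen=True)
class PathwayProfile:
    """Eight-way pathway presence vector of one taxon."""

    taxon: str
    lineage: Lineage
    pathways: frozenset[Pathway]
    n_samples_detected: int = 0

    @property
    def degree(self) -> int:
        return len(self.pathways)

    @property
    def versatile(self) -> bool:
        return self.degree >= 2

    def vector(self) -> tuple[int, ...]:
        """0/1 vector in canonical pathway order."""
        return tuple(int(p in self.pathways) for p in PATHWAYS)


@dataclass
class ProfileSet:
    """Pathway profiles of one ecosystem at species or genus level."""

    level: str  # "species" | "genus"
    profiles: dict[str, PathwayProfile]
    ecosystem_label: str = ""
    min_prevalence: int = 2

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles.values())

    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.profiles))

    def versatile_taxa(self) -> tuple[str, ...]:
        return tuple(sorted(t for t, p in self.profiles.items() if p.versatile))

    def to_frame(self) -> pd.DataFrame:
        """One row per taxon: lineage, 0/1 pathway columns, degree, prevalence."""
        rows = []
        for taxon in sorted(self.profiles):
            p = self.profiles[taxon]
            row = {"taxon": taxon, "lineage": p.lineage.to_string()}
            row.update(dict(zip((pw.name for pw in PATHWAYS), p.vector())))
            row["degree"] = p.degree
            row["n_samples_detected"] = p.n_samples_detected
            rows.append(row)
        return pd.DataFrame(rows)


def species_sample_prevalence(table: AnnotationTable) -> dict[str, int]:
    """Number of distinct samples each species is detected in (any gene)."""
    seen: dict[str, set[str]] = {}
    for r in table.records:
        seen.setdefault(r.lineage.species, set()).add(r.sample_id)
    return {sp: len(samples) for sp, samples in seen.items()}


def apply_prevalence_filter(
    table: AnnotationTable, min_prevalence: int = 2
) -> AnnotationTable:
    """Drop all records of species detected in fewer than *min_prevalence* samples.

    The default of 2 realizes the "detected in more than one sample" rule.
    Prevalence is assessed on species detection of any gene, before pathway
    mapping.
    """
    if min_prevalence < 1:
        raise ValueError(f"min_prevalence must be >= 1, got {min_prevalence}")
    prevalence = species_sample_prevalence(table)
    keep = {sp for sp, n in prevalence.items() if n >= min_prevalence}
    n_removed = len(prevalence) - len(keep)
    if n_removed:
        logger.info(
            "prevalence filter (>= %d samples) removed %d of %d species",
            min_prevalence, n_removed, len(prevalence),
        )
    return AnnotationTable(
        records=[r for r in table.records if r.lineage.species in keep],
        ecosystem_label=table.ecosystem_label,
    )


def _genus_lineage(lineage: Lineage) -> Lineage:
    return Lineage(
        domain=lineage.domain,
        phylum=lineage.phylum,
        class_=lineage.class_,
        order=lineage.order,
        family=lineage.family,
        genus=lineage.genus,
        species="",
    )


def build_profiles(
    table: AnnotationTable, ontology: PathwayOntology, level: str = "species"
) -> ProfileSet:
    """Build per-taxon pathway profiles from a (prevalence-filtered) table.

    Species level: pathway *p* is present iff the species has at least one
    record, in any sample, whose gene maps to *p* (evidence is unioned across
    samples).  Species carrying only genes unknown to the ontology are
    excluded (with one warning per unknown gene).  Genus level: the genus
    vector is the union of its member species' vectors.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"unknown profiling level {level!r}")

    pathway_sets: dict[str, set[Pathway]] = {}
    lineages: dict[str, Lineage] = {}
    samples_of: dict[str, set[str]] = {}
    unknown_warned: set[str] = set()
    for r in table.records:
        sp = r.lineage.species
        lineages.setdefault(sp, r.lineage)
        samples_of.setdefault(sp, set()).add(r.sample_id)
        pws = ontology.pathways_of(r.gene)
        if not pws:
            if r.gene not in unknown_warned:
                unknown_warned.add(r.gene)
                logger.warning(
                    "gene family %r is not in the ontology; its records are "
                    "ignored by pathway profiling", r.gene,
                )
            continue
        pathway_sets.setdefault(sp, set()).update(pws)

    species_profiles = {
        sp: PathwayProfile(
            taxon=sp,
            lineage=lineages[sp],
            pathways=frozenset(pws),
            n_samples_detected=len(samples_of[sp]),
        )
        for sp, pws in pathway_sets.items()
    }
    if level == "species":
        return ProfileSet(
            level="species",
            profiles=species_profiles,
            ecosystem_label=table.ecosystem_label,
        )

    genus_paths: dict[str, set[Pathway]] = {}
    genus_lineage: dict[str, Lineage] = {}
    genus_samples: dict[str, set[str]] = {}
    for sp, prof in species_profiles.items():
        genus = prof.lineage.genus
        if not genus:
            logger.warning("species %r has no genus rank; skipped at genus level", sp)
            continue
        genus_paths.setdefault(genus, set()).update(prof.pathways)
        genus_lineage.setdefault(genus, _genus_lineage(prof.lineage))
        genus_samples.setdefault(genus, set()).update(
            s for s in samples_of[sp]
        )
    genus_profiles = {
        g: PathwayProfile(
            taxon=g,
            lineage=genus_lineage[g],
            pathways=frozenset(pws),
            n_samples_detected=len(genus_samples[g]),
        )
        for g, pws in genus_paths.items()
    }
    return ProfileSet(
        level="genus", profiles=genus_profiles, ecosystem_label=table.ecosystem_label
    )


@dataclass
class DegreeDistribution:
    """Histogram of pathway degrees (1..8) over a profile set."""

    counts: dict[int, int]
    total: int

    @property
    def versatile_total(self) -> int:
        return sum(n for k, n in self.counts.items() if k >= 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree": list(range(1, 9)),
                "n_taxa": [self.counts.get(k, 0) for k in range(1, 9)],
            }
        )


def degree_distribution(profiles: ProfileSet) -> DegreeDistribution:
    counts = Counter(p.degree for p in profiles)
    return DegreeDistribution(counts=dict(counts), total=len(profiles))


def versatile_fraction(dist: DegreeDistribution) -> tuple[int, float, int]:
    """(count, raw percent, display percent) of taxa with degree >= 2."""
    if dist.total == 0:
        raise ValueError("cannot compute a versatile fraction of an empty set")
    count = dist.versatile_total
    raw = 100.0 * count / dist.total
    return count, raw, round_half_away(raw)


@dataclass
class CombinationCounts:
    """Exact-set (UpSet "distinct" mode) pathway-combination counts.

    Each taxon is counted exactly once, under the exact set of pathways it
    encodes — not under supersets.
    """

    counts: dict[frozenset[Pathway], int]
    mode: str = "distinct"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def ranked(self) -> list[tuple[frozenset[Pathway], int]]:
        """Combinations by descending count; ties by canonical pathway order
        then subset size."""
        def key(item):
            subset, n = item
            ordinals = tuple(sorted(p.ordinal for p in subset))
            return (-n, ordinals, len(subset))

        return sorted(self.counts.items(), key=key)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathways": combo_code(subset),
                "n_pathways": len(subset),
                "n_taxa": n,
            }
            for subset, n in self.ranked()
        ]
        return pd.DataFrame(rows)


def combo_code(subset: frozenset[Pathway]) -> str:
    """Serialize a pathway subset as '+'-joined codes in canonical order."""
    return "+".join(p.name for p in PATHWAYS if p in subset)


def parse_combo_code(code: str) -> frozenset[Pathway]:
    return frozenset(Pathway[name] for name in code.split("+") if name)


def combination_counts(
    profiles: ProfileSet, versatile_only: bool = False
) -> CombinationCounts:
    counts: Counter[frozenset[Pathway]] = Counter()
    for p in profiles:
        if versatile_only and not p.versatile:
            continue
        counts[p.pathways] += 1
    return CombinationCounts(counts=dict(counts))


def taxonomic_composition(
    profiles: ProfileSet,
    versatile_only: bool = False,
    other_threshold: int = 2,
) -> dict[str, tuple[int, int]]:
    """Display-taxon composition: label -> (count, display percent).

    Percentages are over the selected subset (all profiles, or only the
    versatile ones); labels carried by fewer than *other_threshold* taxa are
    merged into ``"Other"``.
    """
    selected = [p for p in profiles if (p.versatile or not versatile_only)]
    if not selected:
        return {}
    label_counts = Counter(display_taxon(p.lineage) for p in selected)
    grouped = group_other(dict(label_counts), other_threshold)
    total = len(selected)
    return {
        label: (n, percent_display(n, total))
        for label, n in sorted(grouped.items(), key=lambda kv: (-kv[1], kv[0]))
    }
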