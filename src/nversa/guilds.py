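"""Nitrifier and diazotroph guild classification and statistics.

Nitrifiers are species carrying ammonia-oxidation (amo/pmo/hao) or
nitrite-oxidation (nxr) gene evidence, partitioned into ammonia-oxidizing
archaea (AOA), ammonia-oxidizing bacteria (AOB) and nitrite-oxidizing
bacteria (NOB) with precedence AOA/AOB > NOB: ammonia-oxidation evidence
decides the subgroup (by lineage domain); only pure nxr carriers become NOB.
Species carrying nif nitrogenase genes are diazotrophs (N-fixers), a flag
that can co-occur with a nitrifier label.

A guild member is *pure* if its pathway profile contains only the guild's
defining pathway (nitrification, or nitrogen fixation); otherwise it is
versatile, and its accompanying pathways are ranked in exact-set mode.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .ingest import AnnotationTable, display_taxon, group_other
from .ontology import PATHWAYS, GuildRuleSet, Pathway
from .profiles import (
    CombinationCounts,
    ProfileSet,
    combo_code,
    percent_display,
)

logger = logging.getLogger(__name__)

NITRIFIER_GUILDS = ("AOA", "AOB", "NOB")
GUILDS = NITRIFIER_GUILDS + ("NFIXER",)

#: Defining pathway per guild.
DEFINING_PATHWAY = {
    "AOA": Pathway.NITRIFICATION,
    "AOB": Pathway.NITRIFICATION,
    "NOB": Pathway.NITRIFICATION,
    "NFIXER": Pathway.NITROGEN_FIXATION,
}


@dataclass(frozen=True)
class GuildAssignment:
    """Guild call for one species.

    ``guild`` is the nitrifier subgroup (AOA/AOB/NOB) or ``"NONE"``;
    ``nfixer`` is an independent flag.  ``flags`` records classification
    caveats: ``dual-evidence`` (both ammonia- and nitrite-oxidation genes)
    and ``pmo-only`` (ammonia-oxidation evidence restricted to pmo genes —
    putative methanotroph cross-hit).
    """

    species: str
    guild: str
    nfixer: bool
    evidence_genes: frozenset[str]
    flags: frozenset[str] = frozenset()


def assign_guilds(
    table: AnnotationTable,
    profiles: ProfileSet,
    rules: GuildRuleSet | None = None,
) -> list[GuildAssignment]:
    """Classify every profiled species into nitrifier subgroups / N-fixers.

    *table* must be the same prevalence-filtered table *profiles* was built
    from; species present in the table but absent from the profile set (e.g.
    only unmapped genes) are skipped with a warning.
    """
    if rules is None:
        rules = GuildRuleSet()
    genes_of: dict[str, set[str]] = {}
    domain_of: dict[str, str] = {}
    for r in table.records:
        sp = r.lineage.species
        genes_of.setdefault(sp, set()).add(r.gene)
        domain_of.setdefault(sp, r.lineage.domain)

    assignments: list[GuildAssignment] = []
    skipped = 0
    for sp in sorted(genes_of):
        if sp not in profiles.profiles:
            skipped += 1
            continue
        genes = genes_of[sp]
        amo_ev = genes & rules.ammonia_oxidation_genes
        nxr_ev = genes & rules.nitrite_oxidation_genes
        fix_ev = genes & rules.fixation_genes
        flags: set[str] = set()
        if amo_ev:
            guild = "AOA" if rules.is_archaeal(domain_of[sp]) else "AOB"
            if nxr_ev:
                flags.add("dual-evidence")
            if amo_ev <= {"pmoa", "pmob", "pmoc"}:
                flags.add("pmo-only")
        elif nxr_ev:
            guild = "NOB"
        else:
            guild = "NONE"
        assignments.append(
            GuildAssignment(
                species=sp,
                guild=guild,
                nfixer=bool(fix_ev),
                evidence_genes=frozenset(amo_ev | nxr_ev | fix_ev),
                flags=frozenset(flags),
            )
        )
    if skipped:
        logger.warning(
            "%d species in the table had no pathway profile and were skipped",
            skipped,
        )
    return assignments


def guild_members(assignments: list[GuildAssignment], guild: str) -> list[str]:
    if guild == "NFIXER":
        return [a.species for a in assignments if a.nfixer]
    return [a.species for a in assignments if a.guild == guild]


@dataclass
class GuildSummary:
    """Pure-vs-versatile statistics of one guild."""

    guild: str
    n_total: int
    n_pure: int
    n_versatile: int
    percent_pure: int
    percent_versatile: int
    #: ranked (accompanying pathway set, count, display percent of n_total)
    top_combinations: list[tuple[frozenset[Pathway], int, int]]

    def to_dict(self) -> dict:
        return {
            "guild": self.guild,
            "n_total": self.n_total,
            "n_pure": self.n_pure,
            "n_versatile": self.n_versatile,
            "percent_pure": self.percent_pure,
            "percent_versatile": self.percent_versatile,
            "top_combinations": [
                {"accompanying": combo_code(s), "n": n, "percent": pct}
                for s, n, pct in self.top_combinations
            ],
        }


def guild_summary(
    assignments: list[GuildAssignment], profiles: ProfileSet, guild: str
) -> GuildSummary:
    """Summarize pure/versatile membership of *guild*.

    Pure = profile degree 1 with the single pathway being the guild's
    defining pathway.  ``top_combinations`` ranks, over all members, the
    exact set of non-defining pathways accompanying the defining one
    (exact-set mode); percentages are of the guild total.
    """
    if guild not in GUILDS:
        raise ValueError(f"unknown guild {guild!r}")
    defining = DEFINING_PATHWAY[guild]
    members = guild_members(assignments, guild)
    n_total = len(members)
    if n_total == 0:
        return GuildSummary(guild, 0, 0, 0, 0, 0, [])
    n_pure = 0
    accompanying: Counter[frozenset[Pathway]] = Counter()
    for sp in members:
        prof = profiles.profiles[sp]
        if prof.pathways == frozenset({defining}):
            n_pure += 1
        else:
            accompanying[prof.pathways - {defining}] += 1
    n_versatile = n_total - n_pure
    ranked = CombinationCounts(counts=dict(accompanying)).ranked()
    return GuildSummary(
        guild=guild,
        n_total=n_total,
        n_pure=n_pure,
        n_versatile=n_versatile,
        percent_pure=percent_display(n_pure, n_total),
        percent_versatile=percent_display(n_versatile, n_total),
        top_combinations=[
            (subset, n, percent_display(n, n_total)) for subset, n in ranked
        ],
    )


def heatmap_matrix(
    assignments: list[GuildAssignment],
    profiles: ProfileSet,
    guild: str,
    other_threshold: int = 2,
) -> pd.DataFrame:
    """Binary species × pathway matrix of a guild, with a taxon annotation.

    Rows are guild member species sorted by display taxon then name; the
    eight pathway columns are 0/1 in canonical order; the ``taxon`` column
    carries the display label, with labels borne by fewer than
    *other_threshold* species merged into "Other".
    """
    members = guild_members(assignments, guild)
    rows = []
    for sp in members:
        prof = profiles.profiles[sp]
        rows.append(
            {
                "species": sp,
                "taxon": display_taxon(prof.lineage),
                **dict(zip((p.name for p in PATHWAYS), prof.vector())),
            }
        )
    df = pd.DataFrame(
        rows, columns=["species", "taxon"] + [p.name for p in PATHWAYS]
    )
    if df.empty:
        return df
    label_counts = Counter(df["taxon"])
    grouped = group_other(dict(label_counts), other_threshold)
    df["taxon"] = [
        t if t in grouped else "Other" for t in df["taxon"]
    ]
    return df.sort_values(["taxon", "species"], kind="mergesort").reset_index(
        drop=True
    )
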