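import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _brute
from conftest import make_lineage, make_table, random_rows
from nversa.guilds import (
    GUILDS,
    assign_guilds,
    guild_members,
    guild_summary,
    heatmap_matrix,
)
from nversa.ingest import table_from_rows
from nversa.ontology import GuildRuleSet, Pathway
from nversa.profiles import apply_prevalence_filter, build_profiles


def build(rows, ontology):
    """(filtered table, species profiles) from raw rows; min_prevalence=1 so
    small hand fixtures need no duplication across samples."""
    table = make_table(rows)
    profiles = build_profiles(table, ontology, "species")
    return table, profiles


def archaeal_rows(species, genes, sample="s1"):
    lin = make_lineage(species, genus=species.split(" ")[0],
                       phylum="Thaumarchaeota", domain="Archaea")
    return [(sample, g, lin, 1) for g in genes]


class TestAssignment:
    def test_archaeal_amo_carrier_is_aoa(self, ontology):
        rows = archaeal_rows("Nso sp1", ["amoA", "narG"])
        table = table_from_rows(rows)
        profiles = build_profiles(table, ontology, "species")
        (a,) = assign_guilds(table, profiles)
        assert a.guild == "AOA"
        assert a.evidence_genes == {"amoa"}

    def test_bacterial_hao_only_is_aob(self, ontology):
        table, profiles = build([("s1", "hao", "Nm sp1")], ontology)
        (a,) = assign_guilds(table, profiles)
        assert a.guild == "AOB"

    def test_comammox_like_dual_evidence_is_aob_with_flag(self, ontology):
        table, profiles = build(
            [("s1", "amoA", "Nsp sp1"), ("s1", "nxrB", "Nsp sp1")], ontology
        )
        (a,) = assign_guilds(table, profiles)
        assert a.guild == "AOB"
        assert "dual-evidence" in a.flags

    def test_pure_nxr_carrier_is_nob(self, ontology):
        table, profiles = build([("s1", "nxrA", "Nb sp1")], ontology)
        (a,) = assign_guilds(table, profiles)
        assert a.guild == "NOB"

    def test_pmo_only_carrier_flagged_as_putative_methanotroph(self, ontology):
        table, profiles = build([("s1", "pmoA", "Mm sp1")], ontology)
        (a,) = assign_guilds(table, profiles)
        assert a.guild == "AOB"
        assert "pmo-only" in a.flags

    def test_nif_carrier_gets_independent_fixer_flag(self, ontology):
        table, profiles = build(
            [("s1", "amoA", "X sp1"), ("s1", "nifH", "X sp1")], ontology
        )
        (a,) = assign_guilds(table, profiles)
        assert a.guild == "AOB"
        assert a.nfixer

    def test_nitrifier_partition_is_exhaustive_and_disjoint(self, ontology):
        rows = (
            archaeal_rows("A sp1", ["amoA"])
            + archaeal_rows("A sp2", ["amoB"], sample="s2")
        )
        rows += [
            ("s1", "amoA", make_lineage("B sp1", "B"), 1),
            ("s1", "hao", make_lineage("B sp2", "B"), 1),
            ("s1", "nxrA", make_lineage("C sp1", "C"), 1),
            ("s1", "glnA", make_lineage("D sp1", "D"), 1),
        ]
        table = table_from_rows(rows)
        profiles = build_profiles(table, ontology, "species")
        assignments = assign_guilds(table, profiles)
        aoa = guild_members(assignments, "AOA")
        aob = guild_members(assignments, "AOB")
        nob = guild_members(assignments, "NOB")
        assert sorted(aoa + aob + nob) == ["A sp1", "A sp2", "B sp1", "B sp2", "C sp1"]
        assert len(set(aoa) | set(aob) | set(nob)) == len(aoa) + len(aob) + len(nob)


class TestSummary:
    def test_pure_and_versatile_percentages(self, ontology):
        # 13 AOA: 2 pure, 11 with extra pathways -> 15% / 85%
        rows = []
        for i in range(13):
            genes = ["amoA"] if i < 2 else ["amoA", "glnA"]
            rows += archaeal_rows(f"Aoa sp{i}", genes)
        table = table_from_rows(rows)
        profiles = build_profiles(table, ontology, "species")
        summary = guild_summary(assign_guilds(table, profiles), profiles, "AOA")
        assert (summary.n_total, summary.n_pure) == (13, 2)
        assert summary.percent_pure == 15
        assert summary.percent_versatile == 85

    def test_accompanying_combinations_ranked_over_guild_total(self, ontology):
        rows = []
        for i in range(7):
            genes = ["nifH", "glnA"] if i < 4 else ["nifH", "nirK"]
            rows += [("s1", g, f"Fix sp{i}") for g in genes]
        rows += [("s1", "nifH", "Fix pure")]
        table, profiles = build(rows, ontology)
        summary = guild_summary(assign_guilds(table, profiles), profiles, "NFIXER")
        assert summary.n_total == 8
        top_set, top_n, top_pct = summary.top_combinations[0]
        assert top_set == {Pathway.AMMONIA_ASSIMILATION}
        assert (top_n, top_pct) == (4, 50)

    def test_every_member_profile_contains_defining_pathway(self, ontology):
        rows = [("s1", "nxrA", "N sp1"), ("s1", "nxrB", "N sp2"),
                ("s1", "nifH", "F sp1")]
        table, profiles = build(rows, ontology)
        assignments = assign_guilds(table, profiles)
        for guild, pathway in (("NOB", Pathway.NITRIFICATION),
                               ("NFIXER", Pathway.NITROGEN_FIXATION)):
            for sp in guild_members(assignments, guild):
                assert pathway in profiles.profiles[sp].pathways

    def test_all_pure_guild_has_zero_versatile_percent(self, ontology):
        table, profiles = build([("s1", "nifH", "F sp1"), ("s1", "nifD", "F sp2")],
                                ontology)
        summary = guild_summary(assign_guilds(table, profiles), profiles, "NFIXER")
        assert summary.percent_versatile == 0
        assert summary.top_combinations == []

    def test_empty_guild_summarizes_to_zeros(self, ontology):
        table, profiles = build([("s1", "glnA", "X sp1")], ontology)
        summary = guild_summary(assign_guilds(table, profiles), profiles, "AOA")
        assert summary.n_total == 0

    def test_invariant_to_record_order(self, ontology):
        rows = [("s1", "amoA", "A sp1"), ("s2", "glnA", "A sp1"),
                ("s1", "nxrA", "B sp1"), ("s1", "nifH", "C sp1"),
                ("s2", "nirK", "C sp1")]
        results = []
        for ordering in (rows, rows[::-1]):
            table, profiles = build(ordering, ontology)
            summaries = {
                g: guild_summary(assign_guilds(table, profiles), profiles, g).to_dict()
                for g in GUILDS
            }
            results.append(summaries)
        assert results[0] == results[1]


class TestHeatmap:
    def test_row_sums_equal_degrees(self, ontology):
        rows = [("s1", "nxrA", "N sp1"), ("s1", "glnA", "N sp1"),
                ("s1", "nxrB", "N sp2")]
        table, profiles = build(rows, ontology)
        matrix = heatmap_matrix(assign_guilds(table, profiles), profiles, "NOB")
        assert len(matrix) == 2
        sums = matrix.drop(columns=["species", "taxon"]).sum(axis=1)
        degrees = [profiles.profiles[sp].degree for sp in matrix["species"]]
        assert list(sums) == degrees

    def test_pure_fixer_row_has_single_one_in_fixation_column(self, ontology):
        table, profiles = build([("s1", "nifH", "F sp1")], ontology)
        matrix = heatmap_matrix(assign_guilds(table, profiles), profiles, "NFIXER")
        row = matrix.iloc[0]
        assert row["NITROGEN_FIXATION"] == 1
        assert row.drop(["species", "taxon"]).sum() == 1

    def test_empty_guild_gives_empty_matrix(self, ontology):
        table, profiles = build([("s1", "glnA", "X sp1")], ontology)
        assert heatmap_matrix(assign_guilds(table, profiles), profiles, "AOA").empty


class TestBruteForceOracle:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_guild_tallies_match_direct_enumeration(self, seed, ontology):
        rng = random.Random(seed)
        rows = random_rows(rng, max_rows=40, n_species=12)
        # mark a random subset of species archaeal
        domains = {
            f"sp {i}": rng.choice(["Bacteria", "Archaea"]) for i in range(1, 13)
        }
        full = [
            (s, g, make_lineage(sp, genus=sp.split(" ")[0], domain=domains[sp]), c)
            for s, g, sp, c in rows
        ]
        table = table_from_rows(full)
        profiles = build_profiles(table, ontology, "species")
        assignments = assign_guilds(table, profiles)
        gm = {g: {p.name for p in ontology.pathways_of(g)} for g in ontology.entries}
        aoa, aob, nob, fixers = _brute.guild_tallies(rows, gm, domains)
        assert set(guild_members(assignments, "AOA")) == aoa
        assert set(guild_members(assignments, "AOB")) == aob
        assert set(guild_members(assignments, "NOB")) == nob
        assert set(guild_members(assignments, "NFIXER")) == fixers
        for guild, members, defining in (
            ("AOA", aoa, "NITRIFICATION"),
            ("NOB", nob, "NITRIFICATION"),
            ("NFIXER", fixers, "NITROGEN_FIXATION"),
        ):
            summary = guild_summary(assignments, profiles, guild)
            pure, versatile = _brute.pure_versatile(rows, gm, members, defining)
            assert (summary.n_pure, summary.n_versatile) == (pure, versatile)
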