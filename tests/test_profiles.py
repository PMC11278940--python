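import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _brute
from conftest import GENE_POOL, make_table, random_rows
from nversa.ontology import Pathway
from nversa.profiles import (
    apply_prevalence_filter,
    build_profiles,
    combination_counts,
    degree_distribution,
    parse_combo_code,
    combo_code,
    round_half_away,
    species_sample_prevalence,
    taxonomic_composition,
    versatile_fraction,
)


def gene_map(ontology):
    return {
        g: {p.name for p in ontology.pathways_of(g)} for g in ontology.entries
    }


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(38.504, 39), (87.5, 88), (14.15, 14), (0.5, 1), (-0.5, -1), (35.12, 35)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestPrevalence:
    def test_distinct_sample_counting(self):
        table = make_table(
            [("s1", "amoA", "sp X"), ("s2", "nifH", "sp X"), ("s3", "narG", "sp X")]
            + [("s1", "amoA", "sp Y", 2)] * 5
        )
        prev = species_sample_prevalence(table)
        assert prev["sp X"] == 3
        assert prev["sp Y"] == 1

    def test_default_filter_removes_single_sample_species(self):
        table = make_table([("s1", "amoA", "sp X"), ("s1", "nifH", "sp Y"),
                            ("s2", "nifH", "sp Y")])
        filtered = apply_prevalence_filter(table)
        assert set(filtered.species) == {"sp Y"}

    def test_min_prevalence_one_is_identity(self):
        table = make_table([("s1", "amoA", "sp X"), ("s2", "nifH", "sp Y")])
        filtered = apply_prevalence_filter(table, 1)
        assert len(filtered.records) == len(table.records)

    def test_min_prevalence_below_one_rejected(self):
        table = make_table([("s1", "amoA", "sp X")])
        with pytest.raises(ValueError):
            apply_prevalence_filter(table, 0)

    def test_hand_counted_fixture(self):
        # six species at prevalences (1,1,2,2,3,5) -> 4 survive
        rows = []
        for i, prev in enumerate((1, 1, 2, 2, 3, 5)):
            rows += [(f"s{j}", "glnA", f"sp {i}") for j in range(prev)]
        filtered = apply_prevalence_filter(make_table(rows))
        assert len(set(filtered.species)) == 4

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_recount(self, seed):
        rows = random_rows(random.Random(seed))
        table = make_table(rows)
        assert species_sample_prevalence(table) == _brute.prevalence(rows)


class TestBuildProfiles:
    def test_union_of_gene_evidence_across_samples(self, ontology):
        table = make_table([("s1", "amoA", "sp X"), ("s2", "glnA", "sp X")])
        profiles = build_profiles(table, ontology, "species")
        p = profiles.profiles["sp X"]
        assert p.pathways == {Pathway.NITRIFICATION, Pathway.AMMONIA_ASSIMILATION}
        assert p.degree == 2
        assert p.n_samples_detected == 2

    def test_species_with_only_unmapped_genes_excluded(self, ontology):
        table = make_table([("s1", "unknownX", "sp X"), ("s1", "glnA", "sp Y"),
                            ("s2", "glnA", "sp Y")])
        profiles = build_profiles(table, ontology, "species")
        assert "sp X" not in profiles.profiles
        assert "sp Y" in profiles.profiles

    def test_genus_profile_is_union_of_member_species(self, ontology):
        table = make_table(
            [("s1", "amoA", "G sp1"), ("s2", "amoA", "G sp1"),
             ("s1", "nifH", "G sp2"), ("s2", "nifH", "G sp2")]
        )
        genus = build_profiles(table, ontology, "genus")
        assert genus.profiles["G"].pathways == {
            Pathway.NITRIFICATION, Pathway.NITROGEN_FIXATION,
        }
        assert genus.profiles["G"].degree == 2

    def test_unknown_level_rejected(self, ontology):
        with pytest.raises(ValueError):
            build_profiles(make_table([("s1", "amoA", "sp X")]), ontology, "family")


class TestDegreeAndVersatility:
    def test_degree_histogram(self, ontology):
        table = make_table(
            [("s1", "glnA", "sp A"),
             ("s1", "glnA", "sp B"), ("s1", "nifH", "sp B"),
             ("s1", "glnA", "sp C"), ("s1", "narG", "sp C")]
        )
        dist = degree_distribution(build_profiles(table, ontology, "species"))
        assert dist.counts == {1: 1, 2: 2}
        assert dist.total == 3
        assert dist.versatile_total == 2

    def test_versatile_fraction_all_specialists(self, ontology):
        table = make_table([("s1", "glnA", "sp A"), ("s1", "nifH", "sp B")])
        dist = degree_distribution(build_profiles(table, ontology, "species"))
        assert versatile_fraction(dist) == (0, 0.0, 0)

    def test_versatile_fraction_of_empty_set_is_an_error(self):
        from nversa.profiles import DegreeDistribution

        with pytest.raises(ValueError):
            versatile_fraction(DegreeDistribution(counts={}, total=0))


class TestCombinationCounts:
    def test_distinct_mode_semantics(self, ontology):
        table = make_table(
            [("s1", "glnA", "sp 1"), ("s1", "glnA", "sp 2"),
             ("s1", "glnA", "sp 3"), ("s1", "nifH", "sp 3")]
        )
        combos = combination_counts(build_profiles(table, ontology, "species"))
        aa = frozenset({Pathway.AMMONIA_ASSIMILATION})
        both = frozenset({Pathway.AMMONIA_ASSIMILATION, Pathway.NITROGEN_FIXATION})
        assert combos.counts == {aa: 2, both: 1}
        assert combos.total == 3

    def test_combo_code_round_trip(self):
        subset = frozenset({Pathway.NITRIFICATION, Pathway.AMMONIA_ASSIMILATION})
        assert parse_combo_code(combo_code(subset)) == subset
        # canonical order in the serialization
        assert combo_code(subset).startswith("AMMONIA_ASSIMILATION")

    def test_ranked_tie_break_uses_canonical_order(self, ontology):
        table = make_table(
            [("s1", "nifH", "sp 1"), ("s1", "glnA", "sp 2")]
        )
        ranked = combination_counts(build_profiles(table, ontology, "species")).ranked()
        # equal counts: ammonia assimilation (ordinal 0) ranks first
        assert ranked[0][0] == frozenset({Pathway.AMMONIA_ASSIMILATION})

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed, ontology):
        rows = random_rows(random.Random(seed))
        table = make_table(rows)
        profiles = build_profiles(table, ontology, "species")
        got = {
            frozenset(p.name for p in subset): n
            for subset, n in combination_counts(profiles).counts.items()
        }
        assert got == dict(_brute.combo_counts(rows, gene_map(ontology)))


class TestTaxonomicComposition:
    def test_simple_percentages(self, ontology):
        from nversa.ingest import Lineage
        from nversa.ingest import table_from_rows

        rows = []
        phyla = ["Actinobacteria", "Firmicutes", "Firmicutes", "Bacteroidetes",
                 "Bacteroidetes"]
        for i, phylum in enumerate(phyla):
            lin = Lineage(domain="Bacteria", phylum=phylum, genus="G",
                          species=f"G sp{i}")
            rows += [("s1", "glnA", lin, 1), ("s1", "nifH", lin, 1)]
        profiles = build_profiles(table_from_rows(rows), ontology, "species")
        comp = taxonomic_composition(profiles, versatile_only=True)
        # Actinobacteria has a single species -> grouped into Other
        assert comp["Firmicutes"] == (2, 40)
        assert comp["Other"] == (1, 20)

    def test_empty_selection_yields_empty_map(self, ontology):
        table = make_table([("s1", "glnA", "sp A")])
        profiles = build_profiles(table, ontology, "species")
        assert taxonomic_composition(profiles, versatile_only=True) == {}


class TestInvariants:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_of_totals(self, seed, ontology):
        """Degree histogram, combination counts and profile count agree."""
        table = make_table(random_rows(random.Random(seed)))
        profiles = build_profiles(table, ontology, "species")
        dist = degree_distribution(profiles)
        combos = combination_counts(profiles)
        assert dist.total == len(profiles) == combos.total
        assert sum(dist.counts.values()) == dist.total

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_prevalence_filter_monotonicity(self, seed, ontology):
        """A stricter prevalence filter never adds taxa nor raises a degree."""
        table = make_table(random_rows(random.Random(seed)))
        prev_sets = []
        for k in (1, 2, 3):
            profiles = build_profiles(
                apply_prevalence_filter(table, k), ontology, "species"
            )
            prev_sets.append(
                {t: p.degree for t, p in profiles.profiles.items()}
            )
        for strict, loose in zip(prev_sets[1:], prev_sets):
            assert set(strict) <= set(loose)
            for taxon, degree in strict.items():
                assert degree <= loose[taxon]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_adding_records_never_decreases_degree(self, seed, ontology):
        rng = random.Random(seed)
        rows = random_rows(rng)
        extra = random_rows(rng, max_rows=10)
        before = build_profiles(make_table(rows), ontology, "species")
        after = build_profiles(make_table(rows + extra), ontology, "species")
        for taxon, profile in before.profiles.items():
            assert after.profiles[taxon].degree >= profile.degree

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_genus_containing_versatile_species_is_versatile(self, seed, ontology):
        table = make_table(random_rows(random.Random(seed)))
        species = build_profiles(table, ontology, "species")
        genus = build_profiles(table, ontology, "genus")
        for sp, profile in species.profiles.items():
            g = profile.lineage.genus
            assert genus.profiles[g].degree >= profile.degree
            if profile.versatile:
                assert genus.profiles[g].versatile

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_degree_histogram_matches_brute_force(self, seed, ontology):
        rows = random_rows(random.Random(seed))
        table = make_table(rows)
        dist = degree_distribution(build_profiles(table, ontology, "species"))
        assert Counter(dist.counts) == _brute.degree_hist(rows, gene_map(ontology))
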