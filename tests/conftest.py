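import random

import pytest

from nversa.ingest import Lineage, table_from_rows
from nversa.ontology import load_pathway_ontology


@pytest.fixture(scope="session")
def ontology():
    return load_pathway_ontology()


def make_lineage(species, genus="", phylum="", class_="", domain="Bacteria"):
    return Lineage(
        domain=domain, phylum=phylum, class_=class_, genus=genus, species=species
    )


def make_table(rows, label="test"):
    """Table from (sample, gene, species[, count]) tuples; genus = species prefix."""
    full = []
    for row in rows:
        sample, gene, species = row[:3]
        count = row[3] if len(row) > 3 else 1
        full.append(
            (sample, gene, make_lineage(species, genus=species.split(" ")[0]), count)
        )
    return table_from_rows(full, ecosystem_label=label)


# A pool mixing mapped genes from several pathways with unmapped symbols.
GENE_POOL = [
    "amoA", "hao", "nxrA", "nifH", "nirK", "nosZ", "narG", "napA",
    "nirB", "nasA", "glnA", "ureC", "hzsA", "unknownX", "mysteryY",
]


def random_rows(rng: random.Random, max_rows=50, n_species=8, n_samples=5):
    """Random raw annotation rows for fuzz tests."""
    rows = []
    for _ in range(rng.randint(1, max_rows)):
        rows.append(
            (
                f"s{rng.randint(1, n_samples)}",
                rng.choice(GENE_POOL),
                f"sp {rng.randint(1, n_species)}",
                rng.randint(1, 3),
            )
        )
    return rows
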