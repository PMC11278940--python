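"""Independent brute-force recomputations used as oracles.

These functions work from raw (sample, gene, species, count) tuples and a
plain ``gene -> set of pathway-name strings`` dict, re-deriving every
statistic by direct enumeration, independently of the package's data
structures and code paths.
"""

from collections import Counter


def prevalence(rows):
    seen = {}
    for sample, gene, species, *_ in rows:
        seen.setdefault(species, set()).add(sample)
    return {sp: len(s) for sp, s in seen.items()}


def filter_rows(rows, min_prevalence=2):
    prev = prevalence(rows)
    return [r for r in rows if prev[r[2]] >= min_prevalence]


def species_pathways(rows, gene_map):
    """species -> set of pathway names (union over all rows, unmapped dropped)."""
    out = {}
    for sample, gene, species, *_ in rows:
        pws = gene_map.get(gene.lower(), set())
        if pws:
            out.setdefault(species, set()).update(pws)
    return out


def degree_hist(rows, gene_map):
    return Counter(len(p) for p in species_pathways(rows, gene_map).values())


def combo_counts(rows, gene_map):
    return Counter(
        frozenset(p) for p in species_pathways(rows, gene_map).values()
    )


def guild_tallies(rows, gene_map, domains):
    """(aoa, aob, nob, nfixer) species sets by direct gene scanning."""
    amo = {"amoa", "amob", "amoc", "pmoa", "pmob", "pmoc", "hao"}
    nxr = {"nxra", "nxrb"}
    nif = {"nifh", "nifd", "nifk"}
    genes_of = {}
    for sample, gene, species, *_ in rows:
        genes_of.setdefault(species, set()).add(gene.lower())
    profiled = set(species_pathways(rows, gene_map))
    aoa, aob, nob, fixers = set(), set(), set(), set()
    for sp, genes in genes_of.items():
        if sp not in profiled:
            continue
        if genes & amo:
            (aoa if domains.get(sp) == "Archaea" else aob).add(sp)
        elif genes & nxr:
            nob.add(sp)
        if genes & nif:
            fixers.add(sp)
    return aoa, aob, nob, fixers


def pure_versatile(rows, gene_map, members, defining):
    """(n_pure, n_versatile) of *members* by direct enumeration."""
    paths = species_pathways(rows, gene_map)
    pure = sum(1 for sp in members if paths[sp] == {defining})
    return pure, len(members) - pure
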