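"""Nitrogen-cycle pathway ontology: the eight-pathway enumeration, the
gene-family → pathway mapping, and guild-definition gene sets.

The microbial nitrogen cycle is modelled as eight transformation pathways
(ammonia assimilation, assimilatory nitrate reduction, dissimilatory
nitrate→nitrite, dissimilatory nitrite→ammonia, denitrification,
nitrification, nitrogen fixation, anammox).  Metagenomic annotation tools
report gene families (``amoA``, ``nifH``, ``nosZ`` ...); this module owns the
translation from gene family to pathway membership.  A curated default map is
shipped; users may override or extend it with a two-column TSV, e.g. to load
the full NCycDB category table.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "Pathway",
    "PATHWAYS",
    "PathwayOntology",
    "GuildRuleSet",
    "load_pathway_ontology",
    "pathways_of",
]


class Pathway(enum.Enum):
    """The eight nitrogen transformation pathways, in canonical order.

    The member order is stable and is the order used everywhere a pathway
    bit-vector is serialized (profile TSVs, UpSet matrices, heatmaps).
    """

    AMMONIA_ASSIMILATION = "ammonia assimilation"
    ASSIM_NITRATE_REDUCTION = "assimilatory nitrate reduction"
    DISSIM_NITRATE_TO_NITRITE = "dissimilatory nitrate to nitrite"
    DISSIM_NITRITE_TO_AMMONIA = "dissimilatory nitrite to ammonia"
    DENITRIFICATION = "denitrification"
    NITRIFICATION = "nitrification"
    NITROGEN_FIXATION = "nitrogen fixation"
    ANAMMOX = "anammox"

    @property
    def label(self) -> str:
        return self.value

    @property
    def ordinal(self) -> int:
        return _ORDINAL[self]


#: Canonical pathway order as a tuple (index == ordinal).
PATHWAYS: tuple[Pathway, ...] = tuple(Pathway)
_ORDINAL: dict[Pathway, int] = {p: i for i, p in enumerate(PATHWAYS)}


# Curated default gene-family → pathway table.  Gene symbols named in the
# nitrification / N-fixation / denitrification / nitrate-reduction literature
# are placed under their canonical pathways; nar/nap are kept under
# dissimilatory nitrate→nitrite only (overridable via TSV).
_BUILTIN_TABLE: dict[Pathway, tuple[str, ...]] = {
    Pathway.NITRIFICATION: (
        "amoA", "amoB", "amoC", "pmoA", "pmoB", "pmoC", "hao", "nxrA", "nxrB",
    ),
    Pathway.NITROGEN_FIXATION: ("nifH", "nifD", "nifK", "anfG", "vnfG"),
    Pathway.DENITRIFICATION: ("nirK", "nirS", "norB", "norC", "nosZ"),
    Pathway.DISSIM_NITRATE_TO_NITRITE: ("narG", "narH", "narI", "napA", "napB"),
    Pathway.DISSIM_NITRITE_TO_AMMONIA: ("nirB", "nirD", "nrfA", "nrfH"),
    Pathway.ASSIM_NITRATE_REDUCTION: ("nasA", "nasB", "narB", "nirA", "NR"),
    Pathway.AMMONIA_ASSIMILATION: (
        "glnA", "gltB", "gltD", "gdhA", "ureA", "ureB", "ureC",
    ),
    Pathway.ANAMMOX: ("hzsA", "hzsB", "hzsC", "hdh", "hzo"),
}


def normalize_gene(name: str) -> str:
    """Case-normalized lookup key of a gene-family symbol."""
    return name.strip().lower()


@dataclass(frozen=True)
class PathwayOntology:
    """Immutable gene-family → pathway-set mapping.

    Parameters
    ----------
    entries
        Mapping from case-normalized gene key to a non-empty frozenset of
        :class:`Pathway`.
    display
        Original (display) spelling per gene key.
    source
        Provenance: ``"builtin"`` or the override file path.
    """

    entries: Mapping[str, frozenset[Pathway]]
    display: Mapping[str, str] = field(default_factory=dict)
    source: str = "builtin"

    def __post_init__(self) -> None:
        for gene, pws in self.entries.items():
            if not pws:
                raise ValueError(f"gene {gene!r} maps to an empty pathway set")

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def pathways_of(self, gene: str) -> frozenset[Pathway]:
        """Pathway set of *gene* (case-insensitive); empty set if unmapped."""
        return self.entries.get(normalize_gene(gene), frozenset())

    def genes_of(self, pathway: Pathway) -> frozenset[str]:
        """All gene keys mapped to *pathway*."""
        return frozenset(g for g, pws in self.entries.items() if pathway in pws)

    def display_name(self, gene: str) -> str:
        key = normalize_gene(gene)
        return self.display.get(key, key)

    def to_tsv(self, path: str | Path) -> None:
        """Write the mapping as a 2-column TSV (one row per gene,pathway pair)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_family\tpathway\n")
            for key in sorted(self.entries):
                for pw in sorted(self.entries[key], key=lambda p: p.ordinal):
                    fh.write(f"{self.display_name(key)}\t{pw.name}\n")


def _builtin_entries() -> tuple[dict[str, frozenset[Pathway]], dict[str, str]]:
    entries: dict[str, set[Pathway]] = {}
    display: dict[str, str] = {}
    for pathway, genes in _BUILTIN_TABLE.items():
        for gene in genes:
            key = normalize_gene(gene)
            entries.setdefault(key, set()).add(pathway)
            display.setdefault(key, gene)
    return {k: frozenset(v) for k, v in entries.items()}, display


def load_pathway_ontology(path: str | Path | None = None) -> PathwayOntology:
    """Load the pathway ontology, optionally merged with an override TSV.

    The override file is a 2-column TSV ``gene_family<TAB>pathway`` with a
    header row; ``#`` comment lines are ignored.  A gene listed in the file
    has its pathway set *replaced* by the union of its file rows; genes not
    listed keep their builtin mapping.

    Raises
    ------
    ValueError
        On an unknown pathway code (the offending row is named), a malformed
        row, or an override file with no data rows.
    """
    entries, display = _builtin_entries()
    if path is None:
        return PathwayOntology(entries=entries, display=display, source="builtin")

    override: dict[str, set[Pathway]] = {}
    seen_pairs: set[tuple[str, Pathway]] = set()
    n_rows = 0
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split("\t")
            if not header_seen:
                header_seen = True
                if parts[0].lower() in ("gene_family", "gene"):
                    continue
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            gene, code = parts[0].strip(), parts[1].strip()
            if not gene:
                raise ValueError(f"{path}: line {lineno}: empty gene family")
            try:
                pathway = Pathway[code]
            except KeyError:
                raise ValueError(
                    f"{path}: line {lineno}: unknown pathway code {code!r} "
                    f"for gene {gene!r}"
                ) from None
            key = normalize_gene(gene)
            if (key, pathway) in seen_pairs:
                logger.warning(
                    "%s: line %d: duplicate (%s, %s) row ignored",
                    path, lineno, gene, pathway.name,
                )
                continue
            seen_pairs.add((key, pathway))
            override.setdefault(key, set()).add(pathway)
            display.setdefault(key, gene)
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: ontology override file contains no data rows")
    for key, pws in override.items():
        entries[key] = frozenset(pws)
    return PathwayOntology(entries=entries, display=display, source=str(path))


def pathways_of(ontology: PathwayOntology, gene: str) -> frozenset[Pathway]:
    """Functional alias for :meth:`PathwayOntology.pathways_of`."""
    return ontology.pathways_of(gene)


@dataclass(frozen=True)
class GuildRuleSet:
    """Gene evidence defining the nitrifier subgroups and diazotrophs.

    ``ammonia_oxidation_genes`` covers amo, pmo and hao families (pmo genes
    are retained as ammonia-oxidation evidence but pmo-only species are
    flagged downstream as putative methanotroph cross-hits);
    ``nitrite_oxidation_genes`` the nxr families; ``fixation_genes`` the nif
    nitrogenase subunits.  ``archaeal_domain_labels`` are matched against the
    lineage domain rank to split AOA from AOB.
    """

    ammonia_oxidation_genes: frozenset[str] = frozenset(
        {"amoa", "amob", "amoc", "pmoa", "pmob", "pmoc", "hao"}
    )
    nitrite_oxidation_genes: frozenset[str] = frozenset({"nxra", "nxrb"})
    fixation_genes: frozenset[str] = frozenset({"nifh", "nifd", "nifk"})
    archaeal_domain_labels: frozenset[str] = frozenset({"Archaea", "archaea"})

    def __post_init__(self) -> None:
        sets = (
            self.ammonia_oxidation_genes,
            self.nitrite_oxidation_genes,
            self.fixation_genes,
        )
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError(
                        "guild gene sets must be pairwise disjoint; overlap: "
                        f"{sorted(sets[i] & sets[j])}"
                    )

    def validate_against(self, ontology: PathwayOntology) -> None:
        """Require every rule gene to exist in *ontology*."""
        missing = [
            g
            for g in (
                self.ammonia_oxidation_genes
                | self.nitrite_oxidation_genes
                | self.fixation_genes
            )
            if g not in ontology
        ]
        if missing:
            raise ValueError(
                f"guild rule genes absent from the ontology: {sorted(missing)}"
            )

    def is_archaeal(self, domain: str) -> bool:
        return domain in self.archaeal_domain_labels or (
            domain.lower() in {d.lower() for d in self.archaeal_domain_labels}
        )
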