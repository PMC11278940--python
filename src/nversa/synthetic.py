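"""Synthetic annotation-table generation with known ground truth.

Two generators are provided:

* :func:`generate_community` — a stochastic presence/absence simulator.  Each
  species draws a pathway repertoire, concrete gene families for each owned
  pathway, a per-sample occupancy probability ψ ~ Beta(α, β), realized
  per-sample presence, and finally per-(gene, occupied sample) Bernoulli(δ)
  detection.  The ground truth (true repertoires, genes, ψ, realized
  presence) is returned alongside the table so recovery can be scored.

* :func:`reference_soil_community` / :func:`reference_marine_community` —
  deterministic, noiseless benchmark communities whose marginal statistics
  (degree distribution, guild composition, top pathway combinations,
  taxonomic quotas, genus structure, cross-ecosystem overlap) match the
  headline counts of the soil and marine metagenome surveys this package
  models.  They are synthetic stand-ins for the surveys' deposited raw data
  and are used by the worked examples and the acceptance checks.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .ingest import AnnotationTable, Lineage, table_from_rows
from .ontology import PATHWAYS, Pathway, PathwayOntology, load_pathway_ontology
from .profiles import ProfileSet, round_half_away

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SpeciesTruth",
    "generate_community",
    "recovery_report",
    "RecoveryReport",
    "reference_soil_community",
    "reference_marine_community",
]

# Short aliases for the canonical pathways (construction tables below).
AA, ANR, DNANI, DNIA, DEN, NIT, FIX, ANA = PATHWAYS
FIVESET = frozenset({AA, ANR, DNANI, DNIA, DEN})
ALL8 = frozenset(PATHWAYS)

#: Representative marker gene used for each pathway in noiseless fixtures.
_DEFAULT_GENE = {
    AA: "glnA",
    ANR: "nasA",
    DNANI: "narG",
    DNIA: "nirB",
    DEN: "nirK",
    ANA: "hzsA",
    NIT: "amoA",
    FIX: "nifH",
}

_DEFAULT_TAXON_WEIGHTS = {
    "Actinobacteria": 0.20,
    "Alphaproteobacteria": 0.15,
    "Betaproteobacteria": 0.13,
    "Gammaproteobacteria": 0.12,
    "Bacteroidetes": 0.12,
    "Firmicutes": 0.10,
    "Chloroflexi": 0.08,
    "Acidobacteria": 0.06,
    "Thaumarchaeota": 0.04,
}

_PROTEO_CLASSES = {
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Deltaproteobacteria",
}
_ARCHAEAL_PHYLA = {"Thaumarchaeota", "Crenarchaeota", "Euryarchaeota"}


def _make_lineage(label: str, genus: str, species: str) -> Lineage:
    """Lineage from a display label (phylum, or proteobacterial class)."""
    if label in _PROTEO_CLASSES:
        return Lineage(
            domain="Bacteria", phylum="Proteobacteria", class_=label,
            genus=genus, species=species,
        )
    domain = "Archaea" if label in _ARCHAEAL_PHYLA else "Bacteria"
    return Lineage(domain=domain, phylum=label, genus=genus, species=species)


@dataclass
class GeneratorConfig:
    """Parameters of the stochastic community generator.

    Defaults emulate a marine-sized survey: 500 species observed across 19
    samples, sparse per-species occupancy (ψ ~ Beta(2, 6), mean 0.25), and a
    0.9 per-gene detection probability in occupied samples.  The repertoire
    model is either ``pathway_probs`` (independent per-pathway inclusion,
    conditioned on owning at least one pathway) or ``repertoire_probs`` (an
    explicit distribution over non-empty pathway subsets).
    """

    n_species: int = 500
    n_samples: int = 19
    taxon_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXON_WEIGHTS)
    )
    pathway_probs: tuple[float, ...] = (0.12,) * 8
    repertoire_probs: dict[frozenset[Pathway], float] | None = None
    genes_per_pathway: tuple[int, int] = (1, 3)
    occupancy_alpha: float = 2.0
    occupancy_beta: float = 6.0
    occupancy_fixed: float | None = None  # force ψ (e.g. 1.0 for full occupancy)
    detection_prob: float = 0.9
    seed: int = 0
    ecosystem_label: str = "synthetic"

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.repertoire_probs is not None:
            if any(len(s) == 0 for s in self.repertoire_probs):
                raise ValueError(
                    "explicit repertoire model must not contain the empty set"
                )
            total = sum(self.repertoire_probs.values())
            if total <= 0:
                raise ValueError("repertoire probabilities must sum to > 0")
        else:
            if len(self.pathway_probs) != len(PATHWAYS):
                raise ValueError("pathway_probs must have 8 entries")
            if not any(p > 0 for p in self.pathway_probs):
                raise ValueError("at least one pathway probability must be > 0")
        lo, hi = self.genes_per_pathway
        if lo < 1 or hi < lo:
            raise ValueError("genes_per_pathway must be a range with 1 <= lo <= hi")
        if sum(self.taxon_weights.values()) <= 0:
            raise ValueError("taxon weights must sum to > 0")


@dataclass(frozen=True)
class SpeciesTruth:
    pathways: frozenset[Pathway]
    genes: frozenset[str]
    psi: float
    presence: tuple[bool, ...]

    @property
    def degree(self) -> int:
        return len(self.pathways)

    @property
    def n_samples_present(self) -> int:
        return sum(self.presence)


@dataclass
class GroundTruth:
    """True repertoires and occupancy of a generated community."""

    species: dict[str, SpeciesTruth]
    seed: int

    def versatile_fraction(self, subset: Sequence[str] | None = None) -> float:
        names = list(self.species) if subset is None else list(subset)
        if not names:
            return 0.0
        n_vers = sum(1 for n in names if self.species[n].degree >= 2)
        return 100.0 * n_vers / len(names)


def generate_community(
    config: GeneratorConfig, ontology: PathwayOntology | None = None
) -> tuple[AnnotationTable, GroundTruth]:
    """Draw a community and its annotation table from *config*.

    Deterministic given ``config.seed``.  Species that emit zero records
    (never occupied, or all detections missed) are kept in the ground truth
    but are absent from the table, exactly as an undetected species would be.
    """
    config.validate()
    if ontology is None:
        ontology = load_pathway_ontology()
    rng = np.random.default_rng(config.seed)

    labels = sorted(config.taxon_weights)
    weights = np.array([config.taxon_weights[l] for l in labels], dtype=float)
    weights = weights / weights.sum()

    if config.repertoire_probs is not None:
        subsets = sorted(
            config.repertoire_probs,
            key=lambda s: tuple(sorted(p.ordinal for p in s)),
        )
        sub_w = np.array([config.repertoire_probs[s] for s in subsets], dtype=float)
        sub_w = sub_w / sub_w.sum()
    else:
        subsets = None
        probs = np.array(config.pathway_probs, dtype=float)

    genes_by_pathway = {
        p: sorted(ontology.genes_of(p)) for p in PATHWAYS
    }
    lo, hi = config.genes_per_pathway

    rows: list[tuple[str, str, Lineage, int]] = []
    truth: dict[str, SpeciesTruth] = {}
    genus_counters: dict[str, int] = {}
    for i in range(config.n_species):
        label = labels[int(rng.choice(len(labels), p=weights))]
        k = genus_counters.get(label, 0)
        genus_counters[label] = k + 1
        genus = f"{label[:4].lower()}_g{k // 4:04d}"
        name = f"{genus} sp{k % 4 + 1}"
        lineage = _make_lineage(label, genus, name)

        if subsets is not None:
            repertoire = subsets[int(rng.choice(len(subsets), p=sub_w))]
        else:
            while True:  # condition on >= 1 pathway
                mask = rng.random(len(PATHWAYS)) < probs
                if mask.any():
                    break
            repertoire = frozenset(p for p, m in zip(PATHWAYS, mask) if m)

        genes: set[str] = set()
        for p in sorted(repertoire, key=lambda p: p.ordinal):
            pool = genes_by_pathway[p]
            k_genes = min(int(rng.integers(lo, hi + 1)), len(pool))
            picked = rng.choice(len(pool), size=k_genes, replace=False)
            genes.update(pool[j] for j in sorted(picked))

        psi = (
            config.occupancy_fixed
            if config.occupancy_fixed is not None
            else float(rng.beta(config.occupancy_alpha, config.occupancy_beta))
        )
        presence = tuple(bool(u < psi) for u in rng.random(config.n_samples))

        for s_idx, present in enumerate(presence):
            if not present:
                continue
            sample_id = f"s{s_idx + 1:03d}"
            for gene in sorted(genes):
                if rng.random() < config.detection_prob:
                    rows.append((sample_id, gene, lineage, 1))

        truth[name] = SpeciesTruth(
            pathways=repertoire,
            genes=frozenset(genes),
            psi=psi,
            presence=presence,
        )

    table = table_from_rows(rows, ecosystem_label=config.ecosystem_label)
    return table, GroundTruth(species=truth, seed=config.seed)


@dataclass
class RecoveryReport:
    """Recovery of true repertoires by the pipeline, over profiled species."""

    n_eval: int
    exact_match_rate: float
    degree_mae: float
    versatile_fraction_true: float
    versatile_fraction_recovered: float
    versatile_bias: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def recovery_report(truth: GroundTruth, profiles: ProfileSet) -> RecoveryReport:
    """Score recovered profiles against the ground truth.

    Restricted to species present in *profiles* (i.e. those that survived
    the prevalence filter and carried at least one mapped gene).
    """
    names = [n for n in profiles.profiles if n in truth.species]
    if not names:
        return RecoveryReport(0, float("nan"), float("nan"), 0.0, 0.0, 0.0)
    exact = 0
    abs_err = 0
    n_vers_true = 0
    n_vers_rec = 0
    for n in names:
        rec = profiles.profiles[n].pathways
        tru = truth.species[n].pathways
        exact += rec == tru
        abs_err += abs(len(rec) - len(tru))
        n_vers_true += len(tru) >= 2
        n_vers_rec += len(rec) >= 2
    n = len(names)
    vf_true = 100.0 * n_vers_true / n
    vf_rec = 100.0 * n_vers_rec / n
    return RecoveryReport(
        n_eval=n,
        exact_match_rate=exact / n,
        degree_mae=abs_err / n,
        versatile_fraction_true=vf_true,
        versatile_fraction_recovered=vf_rec,
        versatile_bias=vf_rec - vf_true,
    )


# ---------------------------------------------------------------------------
# Deterministic "exact marginal" reference communities
# ---------------------------------------------------------------------------


@dataclass
class _Sp:
    """Internal species spec used by the reference-community builders."""

    pathways: frozenset[Pathway]
    nit_gene: str | None = None  # gene evidencing NITRIFICATION, if owned
    fix: bool = False  # carries nifH
    label: str | None = None  # display taxon; None = filled from quotas
    domain: str | None = None
    role: str = "bulk"  # genus-grouping role
    genus: str | None = None
    name: str | None = None


def _genes_of(sp: _Sp) -> list[str]:
    genes = []
    for p in sorted(sp.pathways, key=lambda p: p.ordinal):
        if p is NIT:
            genes.append(sp.nit_gene or "amoA")
        elif p is FIX:
            genes.append("nifH")
        else:
            genes.append(_DEFAULT_GENE[p])
    return genes


def _emit_table(
    species: list[_Sp], sample_ids: list[str], ecosystem_label: str
) -> AnnotationTable:
    """Noiseless emission: every species in exactly two rotating samples."""
    n = len(sample_ids)
    rows: list[tuple[str, str, Lineage, int]] = []
    for i, sp in enumerate(species):
        lineage = _make_lineage(sp.label, sp.genus, sp.name)
        if sp.domain:  # explicit domain override (guild archaea)
            lineage = lineage._replace(domain=sp.domain)
        for sample in (sample_ids[i % n], sample_ids[(i + 1) % n]):
            for gene in _genes_of(sp):
                rows.append((sample, gene, lineage, 1))
    return table_from_rows(rows, ecosystem_label=ecosystem_label)


def _block(count: int, **kwargs) -> list[_Sp]:
    return [_Sp(**kwargs) for _ in range(count)]


def reference_soil_community() -> AnnotationTable:
    """Deterministic noiseless community matching the soil-survey marginals.

    5363 species in 1144 genera across 83 samples; degree distribution
    (3298, 1021, 490, 292, 201, 46, 14, 1) for degrees 1–8; nitrifier guild
    of 147 species (13 AOA / 99 AOB / 35 NOB, with 2 / 12 / 2 pure members);
    106 diazotrophs (15 pure); top versatile combinations 337 × {ammonia
    assimilation, assimilatory nitrate reduction} and 215 × {ammonia
    assimilation, dissimilatory nitrite→ammonia}; versatile-species taxonomy
    led by Actinobacteria (496), Alphaproteobacteria (310) and
    Betaproteobacteria (289); 532 genera holding versatile species plus 74
    genera versatile only by union of their members.
    """
    sp: list[_Sp] = []

    # --- nitrifiers (147 = 13 AOA + 99 AOB + 35 NOB) --------------------
    aoa = dict(nit_gene="amoA", domain="Archaea", label="Thaumarchaeota")
    sp += _block(2, pathways=frozenset({NIT}), role="pure_aoa", **aoa)
    sp += _block(4, pathways=FIVESET | {NIT}, role="versatile", **aoa)
    sp += _block(3, pathways=frozenset({NIT, AA}), role="versatile", **aoa)
    sp += _block(2, pathways=frozenset({NIT, ANR}), role="versatile", **aoa)
    sp += _block(2, pathways=frozenset({NIT, DNIA}), role="versatile", **aoa)

    aob = dict(nit_gene="amoA")
    sp += _block(12, pathways=frozenset({NIT}), role="pure_aob", **aob)
    sp += _block(14, pathways=FIVESET | {NIT}, role="versatile", **aob)
    sp += _block(1, pathways=ALL8, fix=True, role="versatile", **aob)
    sp += _block(7, pathways=ALL8 - {FIX}, nit_gene="hao", role="versatile")
    for pw, n in (((AA,), 13), ((ANR,), 13), ((DNANI,), 13), ((DNIA,), 13), ((DEN,), 8)):
        sp += _block(n, pathways=frozenset({NIT, *pw}), role="versatile", **aob)
    sp += _block(5, pathways=frozenset({NIT, AA, ANR}), role="versatile", **aob)

    nob = dict(nit_gene="nxrA")
    sp += _block(2, pathways=frozenset({NIT}), role="pure_nob", **nob)
    sp += _block(12, pathways=FIVESET | {NIT}, role="versatile", **nob)
    sp += _block(21, pathways=frozenset({NIT, AA}), role="versatile", **nob)

    # --- diazotrophs (106 incl. the all-8 species above) ----------------
    sp += _block(15, pathways=frozenset({FIX}), fix=True, role="pure_nfix")
    sp += _block(16, pathways=FIVESET | {FIX}, fix=True, role="versatile")
    sp += _block(10, pathways=frozenset({FIX, AA}), fix=True, role="versatile")
    sp += _block(7, pathways=ALL8 - {NIT}, fix=True, role="versatile")
    for p in (ANR, DNANI, DNIA, DEN, ANA):
        sp += _block(9, pathways=frozenset({FIX, p}), fix=True, role="versatile")
    for p in (ANR, DNANI):
        sp += _block(6, pathways=frozenset({FIX, AA, p}), fix=True, role="versatile")

    # --- non-guild versatile species ------------------------------------
    deg2 = (
        (frozenset({AA, ANR}), 337),
        (frozenset({AA, DNIA}), 215),
        (frozenset({AA, DEN}), 109),
        (frozenset({ANR, DNANI}), 109),
        (frozenset({DNIA, DEN}), 108),
    )
    deg3 = (
        (frozenset({AA, ANR, DNANI}), 158),
        (frozenset({AA, ANR, DNIA}), 158),
        (frozenset({AA, DNIA, DEN}), 157),
    )
    deg45 = (
        (frozenset({AA, ANR, DNANI, DNIA}), 146),
        (frozenset({AA, ANR, DNIA, DEN}), 146),
        (FIVESET, 100),
        (frozenset({AA, ANR, DNANI, DNIA, ANA}), 101),
    )
    for pws, n in deg2 + deg3 + deg45:
        sp += _block(n, pathways=pws, role="versatile")

    # --- taxonomy quotas for versatile species (non-archaeal) -----------
    quotas = (
        ["Actinobacteria"] * 496
        + ["Alphaproteobacteria"] * 310
        + ["Betaproteobacteria"] * 289
        + ["Bacteroidetes"] * 240
        + ["Firmicutes"] * 240
        + ["Gammaproteobacteria"] * 240
        + ["Chloroflexi"] * 239
    )
    qi = 0
    for s in sp:
        if s.role == "versatile" and s.label is None:
            s.label = quotas[qi]
            qi += 1
    assert qi == len(quotas)

    # --- degree-1 singles -----------------------------------------------
    union_labels = ("Actinobacteria", "Bacteroidetes", "Firmicutes", "Gammaproteobacteria")
    union_pairs: list[_Sp] = []
    for j in range(74):
        label = union_labels[j % 4]
        union_pairs.append(_Sp(pathways=frozenset({AA}), label=label, role=f"union{j}"))
        union_pairs.append(_Sp(pathways=frozenset({ANR}), label=label, role=f"union{j}"))
    sp += union_pairs

    bulk_labels = (
        "Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
        "Bacteroidetes", "Firmicutes", "Gammaproteobacteria", "Chloroflexi",
        "Acidobacteria",
    )
    single_pool = (AA, ANR, DNANI, DNIA, DEN, ANA)
    bulk: list[_Sp] = []
    for j in range(534):  # 449 genera of 6 species + 85 of 5 -> 3119
        size = 6 if j < 449 else 5
        bulk += _block(
            size,
            pathways=frozenset({single_pool[j % 6]}),
            label=bulk_labels[j % 8],
            role=f"bulkgenus{j}",
        )
    sp += bulk
    for s in sp:  # remaining unlabeled: pure guild members
        if s.label is None:
            s.label = {
                "pure_aob": "Betaproteobacteria",
                "pure_nob": "Nitrospirae",
                "pure_nfix": "Alphaproteobacteria",
            }[s.role]

    _assign_soil_genera(sp)
    samples = [f"soil{j + 1:02d}" for j in range(83)]
    return _emit_table(sp, samples, "soil")


def _assign_soil_genera(sp: list[_Sp]) -> None:
    """Genus structure: 532 genera of versatile species (63×3 + 469×4),
    74 two-species union genera, 4 pure-guild genera, 534 bulk genera."""
    counter = 0

    def new_genus() -> str:
        nonlocal counter
        counter += 1
        return f"sgen{counter:04d}"

    versatile = [s for s in sp if s.role == "versatile"]
    versatile.sort(key=lambda s: s.label)  # stable: keeps phyla contiguous
    sizes = [3] * 63 + [4] * 469
    idx = 0
    for size in sizes:
        genus = new_genus()
        for k in range(size):
            versatile[idx + k].genus = genus
            versatile[idx + k].name = f"{genus} sp{k + 1}"
        idx += size
    assert idx == len(versatile)

    by_role: dict[str, list[_Sp]] = {}
    for s in sp:
        if s.genus is None:
            by_role.setdefault(s.role, []).append(s)
    # pure guilds share one genus per guild
    for role in ("pure_aoa", "pure_aob", "pure_nob", "pure_nfix"):
        genus = new_genus()
        for k, s in enumerate(by_role.pop(role)):
            s.genus = genus
            s.name = f"{genus} sp{k + 1}"
    for role in sorted(by_role):  # union genera then bulk genera
        genus = new_genus()
        for k, s in enumerate(by_role[role]):
            s.genus = genus
            s.name = f"{genus} sp{k + 1}"


def reference_marine_community(
    soil_species: Sequence[str] | None = None,
) -> AnnotationTable:
    """Deterministic noiseless community matching the marine-survey marginals.

    9117 species across 19 samples; degree distribution
    (5915, 1630, 725, 444, 291, 90, 14, 8) for degrees 1–8 (3202 versatile,
    35%); versatile taxonomy led by Alphaproteobacteria (897),
    Gammaproteobacteria (736) and Bacteroidetes (288).  When *soil_species*
    is given, 2462 species reuse soil species names so that 73% of the 9117
    marine species are not detected in soil.
    """
    sp: list[_Sp] = []

    # marine nitrifiers and diazotrophs (not marginal-pinned, but present)
    aoa = dict(nit_gene="amoA", domain="Archaea", label="Thaumarchaeota")
    sp += _block(2, pathways=frozenset({NIT}), **aoa)
    sp += _block(5, pathways=frozenset({NIT, AA}), role="versatile", **aoa)
    sp += _block(2, pathways=frozenset({NIT}), nit_gene="amoA")
    sp += _block(10, pathways=frozenset({NIT, AA}), nit_gene="amoA", role="versatile")
    sp += _block(2, pathways=frozenset({NIT}), nit_gene="nxrA")
    sp += _block(8, pathways=frozenset({NIT, AA}), nit_gene="nxrA", role="versatile")
    sp += _block(7, pathways=ALL8 - {FIX}, nit_gene="hao", role="versatile")
    sp += _block(8, pathways=ALL8, fix=True, role="versatile")
    sp += _block(5, pathways=frozenset({FIX}), fix=True)
    sp += _block(20, pathways=frozenset({FIX, AA}), fix=True, role="versatile")
    sp += _block(7, pathways=ALL8 - {NIT}, fix=True, role="versatile")

    pool = (AA, ANR, DNANI, DNIA, DEN, ANA)

    def subsets_of(size: int) -> list[frozenset[Pathway]]:
        from itertools import combinations

        return [frozenset(c) for c in combinations(pool, size)]

    def spread(total: int, subsets: list[frozenset[Pathway]]) -> None:
        base, extra = divmod(total, len(subsets))
        for j, pws in enumerate(subsets):
            sp.extend(_block(base + (1 if j < extra else 0),
                             pathways=pws, role="versatile"))

    spread(1587, subsets_of(2))  # 1630 deg-2 minus 43 guild deg-2
    spread(725, subsets_of(3))
    spread(444, subsets_of(4))
    spread(291, subsets_of(5))
    spread(90, subsets_of(6))

    # versatile taxonomy quotas (non-archaeal versatile: 3202 - 5 AOA)
    quotas = (
        ["Alphaproteobacteria"] * 897
        + ["Gammaproteobacteria"] * 736
        + ["Bacteroidetes"] * 288
        + ["Actinobacteria"] * 256
        + ["Firmicutes"] * 255
        + ["Chloroflexi"] * 255
        + ["Cyanobacteria"] * 255
        + ["Planctomycetes"] * 255
    )
    qi = 0
    for s in sp:
        if s.role == "versatile" and s.label is None:
            s.label = quotas[qi]
            qi += 1
    assert qi == len(quotas)

    # degree-1 singles (5915 total, 11 of them pure guild members above)
    labels = (
        "Alphaproteobacteria", "Gammaproteobacteria", "Bacteroidetes",
        "Actinobacteria", "Firmicutes", "Chloroflexi", "Cyanobacteria",
        "Planctomycetes",
    )
    for j in range(5904):
        sp.append(
            _Sp(pathways=frozenset({pool[j % 6]}), label=labels[j % 8])
        )
    for s in sp:
        if s.label is None:
            s.label = labels[len(sp) % 8]

    # genus structure: consecutive chunks of 8 species
    for i, s in enumerate(sp):
        genus = f"mgen{i // 8 + 1:04d}"
        s.genus = genus
        s.name = f"{genus} sp{i % 8 + 1}"

    # overlay shared species names from the soil registry
    if soil_species is not None:
        shared = sorted(soil_species)[:2462]
        for s, name in zip(sp, shared):
            s.name = name
            s.genus = name.split(" ")[0]

    samples = [f"mar{j + 1:02d}" for j in range(19)]
    return _emit_table(sp, samples, "marine")
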