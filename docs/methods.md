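# Methods

## Model and definitions

The unit of analysis is a per-sample gene-family detection table
*(sample, gene family, lineage, count)*, the standard downstream product of
annotating assembled metagenomic ORFs against a nitrogen-cycle gene
catalogue with NR taxonomy. Counts are carried through ingestion (duplicate
*(sample, gene, species)* triples are merged by summing) but all downstream
statistics are presence/absence: a pathway is either encoded or not, and no
abundance weighting is applied.

**Prevalence filter.** A species enters the analysis only if it is detected
(any gene, mapped or not) in at least `min_prevalence` distinct samples of
the ecosystem; the default of 2 encodes "detected in more than one sample".
Prevalence is assessed before pathway mapping, on raw detections.

**Pathway assignment.** Gene families map to one or more of the eight
canonical nitrogen pathways (ammonia assimilation, assimilatory nitrate
reduction, dissimilatory nitrate→nitrite, dissimilatory nitrite→ammonia,
denitrification, nitrification, nitrogen fixation, anammox — this order is
used in every serialized bit-vector). A species encodes pathway *p* iff at
least one of its records, in any sample, carries a gene mapped to *p*:
evidence is unioned across samples after the prevalence filter, so a
nitrification gene seen in a single sample suffices once the species itself
is prevalent. Species whose genes are all unknown to the ontology are
excluded from profiling (the catalogue contains families outside the eight
pathways); each unknown gene is warned once. Genus profiles are the logical
OR of member-species vectors — a genus can therefore be versatile without
containing any versatile species, which is why versatile-genus counts exceed
counts of genera containing versatile species.

**Versatility.** Degree = number of encoded pathways (1–8); versatile =
degree ≥ 2. Combination counts use exact-set ("distinct" UpSet) semantics:
each taxon is counted once, under exactly its pathway set. Ranking ties are
broken by canonical pathway order, then subset size.

**Guilds.** Nitrifiers are species carrying ammonia-oxidation evidence
(amoABC, pmoABC, hao) or nitrite-oxidation evidence (nxrAB). Precedence:
ammonia-oxidation evidence wins — archaeal lineages become AOA, bacterial
ones AOB — and only pure nxr carriers become NOB, making AOA/AOB/NOB a
partition of the nitrifiers. Species with both kinds of evidence
(comammox-like) are labelled AOB and flagged `dual-evidence`; species whose
ammonia-oxidation evidence is pmo-only are flagged as putative methanotroph
cross-hits. An archaeal hao-only carrier classifies as AOA under this rule;
the alternative (hao restricted to bacteria) would leave such species
outside the partition. Diazotrophs carry nifH/nifD/nifK; the flag is
independent of the nitrifier label. A guild member is *pure* when its
profile is exactly the guild's defining pathway (nitrification, or nitrogen
fixation) — a pathway-level notion, deliberately consistent with the
versatility definition even where gene-level phrasing ("only the amo gene")
would give the same answer.

**Display rounding.** All reported percentages round half away from zero to
the nearest integer; raw values are kept alongside. One headline figure is
conventionally quoted as a floor ("more than 38 %" where the raw value is
38.5 %), so the raw percentage is the value to compare there.

## The gene→pathway map

The builtin ontology places every gene symbol the nitrogen-cycle literature
attaches to a specific pathway where that literature puts it: nitrification
← {amoA/B/C, pmoA/B/C, hao, nxrA/B}; fixation ← {nifH/D/K, anfG, vnfG};
denitrification ← {nirK, nirS, norB/C, nosZ}; dissimilatory nitrate→nitrite
← {narG/H/I, napA/B}; dissimilatory nitrite→ammonia ← {nirB/D, nrfA/H};
assimilatory nitrate reduction ← {nasA/B, narB, nirA, NR}; ammonia
assimilation ← {glnA, gltB/D, gdhA, ureA/B/C}; anammox ← {hzsA/B/C, hdh,
hzo}. Two judgement calls are deliberate and overridable via the TSV
interface: narG/napA sit only under dissimilatory nitrate→nitrite (not
additionally under denitrification), and the ammonia-assimilation list
(including the urease operon) approximates a catalogue category whose exact
composition varies between releases. Overriding a gene replaces its builtin
pathway set entirely.

## Synthetic communities

**Stochastic generator.** Each species draws a display taxon (weights
roughly matching soil phylum frequencies), a pathway repertoire, 1–3 marker
genes per owned pathway from the ontology, an occupancy ψ ~ Beta(2, 6)
(mean 0.25 — most species occur in a minority of samples, as is typical for
species-level incidence in environmental surveys), per-sample presence ~
Bernoulli(ψ), and per-(gene, occupied sample) detection ~ Bernoulli(δ).
Defaults (500 species, 19 samples, δ = 0.9) mirror the marine survey's
sample count and a realistic per-gene detection rate; the default
per-pathway inclusion probability of 0.12 (independent, conditioned on ≥ 1
pathway) yields a true versatile fraction near 39 %, in the range the
surveys report. The generator is fully deterministic given its seed, and
detection is monotonically coupled in δ under a fixed seed (lowering δ can
only remove records), which the degradation tests exploit.

What the generator does *not* emulate: read-level error, assembly chimeras,
phylogenetic correlation of repertoires, abundance structure (records carry
count 1), and mis-annotation (a detected gene is always a true gene).
Passing recovery tests therefore show that the *inference side* — filtering,
mapping, union, counting — is unbiased under occupancy and detection noise,
not that upstream annotation of real reads is reliable.

**Benchmark communities.** Two deterministic, noiseless tables reproduce
the marginal statistics of the modelled surveys exactly through the real
pipeline: soil (5363 species / 1144 genera / 83 samples; degree counts
3298, 1021, 490, 292, 201, 46, 14, 1; nitrifiers 13 AOA + 99 AOB + 35 NOB
with 2/12/2 pure; 106 diazotrophs with 15 pure; top combinations 337 and
215; versatile taxonomy 496/310/289 across Actinobacteria, Alpha- and
Betaproteobacteria; 532 genera holding versatile species plus 74 versatile
only by union) and marine (9117 species / 19 samples; degree counts 5915,
1630, 725, 444, 291, 90, 14, 8; versatile taxonomy 897/736/288; 2462
species shared with the soil registry, leaving 73 % marine-only). Where the
printed marginals underdetermine the construction, pathway identities are
assigned in canonical order and each species occupies exactly two rotating
samples (the minimum passing the prevalence filter). One marginal is
genuinely unrealizable: with 4 + 14 + 16 degree-6 slots consumed by AOA,
AOB and diazotroph blocks, at most 12 of the 46 degree-6 species can be
NOB, so the benchmark realizes 12 rather than the 13 that a 38 %-of-NOB
sub-statistic would need; no acceptance check depends on it.

## Numerical and design choices

* Species identity is the species-rank string verbatim; cross-ecosystem
  matching is exact-string, with no synonym resolution.
* Lineages are seven-rank, semicolon-delimited; the `d__` prefix dialect is
  auto-detected and both dialects round-trip. Rows without a species rank
  are dropped at ingestion (tallied); how ambiguous NR hits should be
  treated is genuinely open, and dropping is this package's pinned choice.
* Proteobacteria are displayed at class level, everything else at phylum
  level; labels carried by fewer than 2 taxa collapse into "Other".
* Ecosystems are always processed independently (separate tables, separate
  filters); the overlap report is computed on the filtered registries by
  default.
* `summary.json` is self-consistent by construction and re-validated on
  write: degree distributions sum to the taxon totals and every display
  percentage is re-derivable from its adjacent counts.
* Problem sizes in the test and acceptance runs (benchmark communities at
  full survey scale, recovery at 500 species × 19 samples × 20 seeds,
  oracle fuzzing at ≤ 50 records × 220 tables) keep the whole suite in the
  tens of seconds while leaving every statistic at its published scale.

## Known limitations

* Pathway presence is genomic potential, not activity; no
  expression or rate inference is attempted.
* A single detected gene asserts a whole pathway; partial-operon evidence
  (e.g. amoA without amoB/C) is not distinguished.
* Guild calls trust the lineage's domain rank to split AOA from AOB;
  ambiguous or unannotated domains default to the bacterial branch.
* The overall nitrifier versatile fraction computed from the benchmark's
  printed pure counts is 89 % (131/147); a conventionally quoted 85 %
  for that pool is inconsistent with its own pure counts and is not
  asserted anywhere.
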