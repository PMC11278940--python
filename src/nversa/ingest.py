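"""Reading and normalizing per-sample gene annotation tables.

Input is the tabular product of a functional/taxonomic annotation run over
assembled metagenomes: one row per detected gene occurrence, carrying the
sample identifier, the gene-family symbol, the full seven-rank taxonomic
lineage of the best taxonomic hit, and an optional occurrence count.
Normalization drops rows without a species-rank assignment (species-level
analysis is impossible for them) and merges duplicate
(sample, gene, species) triples by summing counts.
"""

from __future__ import annotations

import gzip
import io
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .ontology import normalize_gene

logger = logging.getLogger(__name__)

RANK_NAMES = ("domain", "phylum", "class_", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class Lineage(NamedTuple):
    """Seven-rank taxonomic lineage; missing ranks are empty strings."""

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def to_string(self, prefix_style: str = "bare") -> str:
        if prefix_style == "prefixed":
            return ";".join(p + r for p, r in zip(_PREFIXES, self))
        return ";".join(self)


def parse_lineage(raw: str, prefix_style: str | None = None) -> Lineage:
    """Parse a semicolon-delimited lineage string into a seven-rank tuple.

    ``prefix_style`` is ``"bare"`` (plain rank names) or ``"prefixed"``
    (``d__``/``p__``/... markers); ``None`` auto-detects by the presence of
    ``d__``.  Fewer than seven fields are padded with empty strings; more
    than seven is an error.
    """
    fields = [f.strip() for f in raw.split(";")]
    if len(fields) > 7:
        raise ValueError(f"lineage has {len(fields)} fields (max 7): {raw!r}")
    if prefix_style is None:
        prefix_style = "prefixed" if any(f.startswith("d__") for f in fields) else "bare"
    if prefix_style == "prefixed":
        stripped = []
        for f in fields:
            if len(f) >= 3 and f[1:3] == "__" and f[0] in "dpcofgs":
                f = f[3:]
            stripped.append(f.strip())
        fields = stripped
    elif prefix_style != "bare":
        raise ValueError(f"unknown prefix_style {prefix_style!r}")
    fields += [""] * (7 - len(fields))
    return Lineage(*fields)


def display_taxon(lineage: Lineage) -> str:
    """Display label of a lineage: class for Proteobacteria, else phylum.

    Proteobacterial species are conventionally reported at the class level
    (Alpha-/Beta-/Gammaproteobacteria); everything else at the phylum level.
    An empty phylum yields ``"Unclassified"``.
    """
    if not lineage.phylum:
        return "Unclassified"
    if lineage.phylum == "Proteobacteria" and lineage.class_:
        return lineage.class_
    return lineage.phylum


def group_other(counts: dict[str, int], other_threshold: int = 2) -> dict[str, int]:
    """Merge labels carried by fewer than *other_threshold* items into "Other"."""
    out: dict[str, int] = {}
    other = 0
    for label, n in counts.items():
        if n < other_threshold:
            other += n
        else:
            out[label] = n
    if other:
        out["Other"] = out.get("Other", 0) + other
    return out


@dataclass(frozen=True)
class AnnotationRecord:
    """One normalized gene detection: (sample, gene family, lineage, count)."""

    sample_id: str
    gene: str  # case-normalized key
    lineage: Lineage
    count: int = 1


@dataclass
class AnnotationTable:
    """Normalized per-sample gene-family detections for one ecosystem.

    ``records`` holds one entry per distinct (sample, gene, species) triple;
    ``samples`` is the sorted tuple of distinct sample ids.
    """

    records: list[AnnotationRecord]
    ecosystem_label: str = ""

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({r.sample_id for r in self.records}))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({r.lineage.species for r in self.records}))

    def __len__(self) -> int:
        return len(self.records)

    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per record) used by writers and profiling."""
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "gene_family": [r.gene for r in self.records],
                "lineage": [r.lineage.to_string() for r in self.records],
                "count": [r.count for r in self.records],
            }
        )


def _normalize(
    rows: Iterable[tuple[str, str, Lineage, int]], ecosystem_label: str
) -> AnnotationTable:
    merged: dict[tuple[str, str, str], list] = {}
    n_dropped_species = 0
    n_dropped_zero = 0
    for sample_id, gene, lineage, count in rows:
        if not lineage.species:
            n_dropped_species += 1
            continue
        if count <= 0:
            n_dropped_zero += 1
            continue
        key = (sample_id, gene, lineage.species)
        if key in merged:
            merged[key][1] += count
        else:
            merged[key] = [lineage, count]
    if n_dropped_species:
        logger.info(
            "dropped %d rows lacking a species-rank assignment", n_dropped_species
        )
    if n_dropped_zero:
        logger.info("dropped %d zero-count rows", n_dropped_zero)
    records = [
        AnnotationRecord(sample_id=k[0], gene=k[1], lineage=v[0], count=v[1])
        for k, v in merged.items()
    ]
    return AnnotationTable(records=records, ecosystem_label=ecosystem_label)


def table_from_rows(
    rows: Iterable[tuple[str, str, Lineage, int]], ecosystem_label: str = ""
) -> AnnotationTable:
    """Build a normalized table from in-memory (sample, gene, lineage, count) rows."""
    return _normalize(
        ((s, normalize_gene(g), lin, c) for s, g, lin, c in rows), ecosystem_label
    )


def read_annotations(path: str | Path, ecosystem_label: str = "") -> AnnotationTable:
    """Read an annotation TSV (optionally gzipped) into a normalized table.

    The file must carry a header with columns ``sample_id``, ``gene_family``
    and ``lineage``; ``count`` is optional and defaults to 1.  Rows with an
    empty species rank are dropped with a logged tally; duplicate
    (sample, gene, species) triples are merged by summing counts.

    Raises
    ------
    ValueError
        If a mandatory column is missing, a count fails to parse (the line
        number is named), or the file holds no rows.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene_family", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: annotation file contains no rows")

    if "count" in df.columns:
        counts = []
        for i, raw in enumerate(df["count"]):
            raw = raw.strip()
            if raw == "":
                counts.append(1)
                continue
            try:
                counts.append(int(raw))
            except ValueError:
                # header is line 1, first data row line 2
                raise ValueError(
                    f"{path}: line {i + 2}: unparseable count {raw!r}"
                ) from None
    else:
        counts = [1] * len(df)

    rows = (
        (
            sample.strip(),
            normalize_gene(gene),
            parse_lineage(lineage),
            count,
        )
        for sample, gene, lineage, count in zip(
            df["sample_id"], df["gene_family"], df["lineage"], counts
        )
    )
    table = _normalize(rows, ecosystem_label)
    if not table.records:
        raise ValueError(f"{path}: no usable rows after normalization")
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    """Write a table back to the annotation TSV schema (round-trips exactly)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = sorted(
        table.records, key=lambda r: (r.sample_id, r.gene, r.lineage.species)
    )
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgene_family\tlineage\tcount\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.gene}\t{r.lineage.to_string()}\t{r.count}\n"
            )
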