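"""Cross-ecosystem comparison of N-transforming species registries.

Species registries from two ecosystems (e.g. soil vs. marine) are matched by
exact species-name string and summarized as an overlap report: shared and
exclusive counts, display percentages, and the Jaccard index of the two sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import ProfileSet, percent_display


@dataclass
class OverlapReport:
    """Set overlap between two species registries A and B."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_shared: int
    pct_a_only: int
    pct_b_only: int
    pct_shared_of_b: int
    jaccard: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def ecosystem_overlap(profiles_a: ProfileSet, profiles_b: ProfileSet) -> OverlapReport:
    """Overlap of two species-level profile sets (exact-name matching)."""
    if profiles_a.level != "species" or profiles_b.level != "species":
        raise ValueError(
            "ecosystem_overlap requires species-level profile sets, got "
            f"{profiles_a.level!r} and {profiles_b.level!r}"
        )
    set_a = set(profiles_a.profiles)
    set_b = set(profiles_b.profiles)
    shared = set_a & set_b
    union = set_a | set_b
    return OverlapReport(
        label_a=profiles_a.ecosystem_label,
        label_b=profiles_b.ecosystem_label,
        n_a=len(set_a),
        n_b=len(set_b),
        n_shared=len(shared),
        pct_a_only=percent_display(len(set_a) - len(shared), len(set_a)) if set_a else 0,
        pct_b_only=percent_display(len(set_b) - len(shared), len(set_b)) if set_b else 0,
        pct_shared_of_b=percent_display(len(shared), len(set_b)) if set_b else 0,
        jaccard=(len(shared) / len(union)) if union else 1.0,
    )
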