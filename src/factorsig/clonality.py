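"""Trunk/branch classification of mutations and the associated sample filters.

Mutations present in the founding tumor cell (clonal) appear at high variant
allele frequency; mutations acquired during growth (subclonal) at low VAF.
After restricting to high-purity samples (purity >= 0.70 by default), a
mutation with VAF >= 0.25 is labelled ``trunk`` and the rest ``branch``.
Samples in which either group ends up with fewer than a minimum number of
mutations (default 10) are excluded entirely — both matched groups — since
the downstream paired exposure test needs both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .catalog_io import MutationRecord

DEFAULT_MIN_PURITY = 0.70
DEFAULT_VAF_THRESHOLD = 0.25
DEFAULT_MIN_MUTATIONS = 10

TRUNK = "trunk"
BRANCH = "branch"


@dataclass
class ClonalityAssignment:
    """Per-mutation trunk/branch labels and per-sample inclusion status."""

    records: list[MutationRecord]
    labels: list[str]  # parallel to records, "trunk" / "branch"
    sample_status: dict[str, str]  # included / excluded_purity / excluded_min_mutations
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels differ in length")

    def included_samples(self) -> list[str]:
        return [s for s, st in self.sample_status.items() if st == "included"]

    def group_counts(self) -> dict[str, dict[str, int]]:
        """Per included sample: number of trunk and branch mutations."""
        out: dict[str, Counter] = {}
        for rec, lab in zip(self.records, self.labels):
            if self.sample_status.get(rec.sample_id) == "included":
                out.setdefault(rec.sample_id, Counter())[lab] += 1
        return {
            s: {TRUNK: c.get(TRUNK, 0), BRANCH: c.get(BRANCH, 0)} for s, c in out.items()
        }

    def as_grouped_records(self) -> list[MutationRecord]:
        """Records of included samples with sample_id suffixed _trunk/_branch.

        The result is a flat record list consumable by the catalog builder
        and the paired exposure test.
        """
        out = []
        for rec, lab in zip(self.records, self.labels):
            if self.sample_status.get(rec.sample_id) == "included":
                out.append(replace(rec, sample_id=f"{rec.sample_id}_{lab}"))
        return out


def filter_by_purity(
    sample_meta: Mapping[str, Mapping], min_purity: float = DEFAULT_MIN_PURITY
) -> set[str]:
    """Samples whose tumor purity is at or above ``min_purity`` (inclusive)."""
    missing = [s for s, m in sample_meta.items() if m.get("purity") is None]
    if missing:
        raise ValueError(f"samples missing purity: {sorted(missing)}")
    return {s for s, m in sample_meta.items() if float(m["purity"]) >= min_purity}


def classify_trunk_branch(
    records: Iterable[MutationRecord],
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
    included_samples: Sequence[str] | None = None,
) -> ClonalityAssignment:
    """Label each mutation trunk (VAF >= threshold, inclusive) or branch.

    ``included_samples``, typically the output of :func:`filter_by_purity`,
    restricts the assignment; mutations of other samples are kept in the
    record list but their samples are marked ``excluded_purity``.
    """
    records = list(records)
    status: dict[str, str] = {}
    labels: list[str] = []
    include = None if included_samples is None else set(included_samples)
    missing = [
        r for r in records
        if (include is None or r.sample_id in include) and r.vaf is None
    ]
    if missing:
        names = sorted({r.sample_id for r in missing})
        raise ValueError(f"records missing VAF in samples: {names}")
    for rec in records:
        if include is not None and rec.sample_id not in include:
            status.setdefault(rec.sample_id, "excluded_purity")
            labels.append(BRANCH if rec.vaf is None or rec.vaf < vaf_threshold else TRUNK)
            continue
        status.setdefault(rec.sample_id, "included")
        labels.append(TRUNK if rec.vaf >= vaf_threshold else BRANCH)
    return ClonalityAssignment(records, labels, status, vaf_threshold=vaf_threshold)


def apply_min_mutation_filter(
    assignment: ClonalityAssignment, min_n: int = DEFAULT_MIN_MUTATIONS
) -> ClonalityAssignment:
    """Exclude samples in which either matched group has fewer than ``min_n``.

    The trunk and branch groups of a sample are matched pairs: if one falls
    below the minimum, the whole sample (both groups) is excluded.
    """
    counts = assignment.group_counts()
    status = dict(assignment.sample_status)
    for sample, gc in counts.items():
        if gc[TRUNK] < min_n or gc[BRANCH] < min_n:
            status[sample] = "excluded_min_mutations"
    return ClonalityAssignment(
        assignment.records, assignment.labels, status,
        vaf_threshold=assignment.vaf_threshold,
    )
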