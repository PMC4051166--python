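"""Stringent classification of mapper output against simulated truth.

A read counts as correctly mapped only if at least one reported hit recovers
the read's original start and end positions AND reports exactly the original
numbers of insertions, deletions and substitutions.  Because indels inside a
homopolymer that touches an alignment end are invisible to a mapper (the
observed start/end simply shift), a per-end *shift* allowance reconciles
them: a start/end offset is re-counted as that many missing deletions and
clipped read bases as missing insertions, and the correctness test is
re-applied to the augmented counts.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import ConfigurationError
from .genome_forge import RepeatMap
from .io_formats import (
    AlignmentObservation,
    Contig,
    ReadTruth,
    encode_truth_name,
)
from .simulate import reverse_complement


class Category(enum.Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"
    UNMAPPED = "UNMAPPED"
    RANDOM_REJECTED = "RANDOM_REJECTED"
    RANDOM_MAPPED = "RANDOM_MAPPED"


@dataclass(frozen=True)
class ShiftPolicy:
    """Per-end positional allowance absorbing homopolymer indels at
    alignment extremities. ``max_shift`` bounds, per end, the sum of the
    positional offset (missing deletions) and clipped bases (missing
    insertions)."""

    max_shift: int = 5

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")


@dataclass(frozen=True)
class ClassificationOutcome:
    read_id: str
    category: Category
    satisfying_hit: AlignmentObservation | None = None


@dataclass(frozen=True)
class EvaluationSummary:
    """TP/FP/FN counts and the derived mapping-robustness metrics."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    fraction_mapped: float
    category_counts: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f_measure": self.f_measure,
            "fraction_mapped": self.fraction_mapped,
            "categories": dict(self.category_counts),
        }


def hit_satisfies(
    truth: ReadTruth, hit: AlignmentObservation, policy: ShiftPolicy
) -> bool:
    """Does one hit satisfy the correctness rule under the shift policy?

    The start offset (hit.start - truth.start) and end offset
    (truth.end - hit.end) are read as missing deletions at the respective
    end; clipped bases are missing insertions.  Each end's total absorbed
    shift is bounded by ``max_shift``, and the augmented counts must equal
    the truth counts exactly (substitutions have no allowance).
    """
    if not hit.mapped:
        return False
    if hit.contig != truth.contig or hit.strand != truth.strand:
        return False
    md_left = hit.start - truth.start
    md_right = truth.end - hit.end
    if md_left < 0 or md_right < 0:
        return False
    if md_left > policy.max_shift or md_right > policy.max_shift:
        return False
    mi_left = hit.clip_left
    mi_right = hit.clip_right
    if md_left + mi_left > policy.max_shift:
        return False
    if md_right + mi_right > policy.max_shift:
        return False
    return (
        hit.n_del + md_left + md_right == truth.n_del
        and hit.n_ins + mi_left + mi_right == truth.n_ins
        and hit.n_sub == truth.n_sub
    )


def classify_read(
    truth: ReadTruth,
    hits: Sequence[AlignmentObservation],
    policy: ShiftPolicy,
) -> ClassificationOutcome:
    """Classify one read given all its reported hits."""
    for h in hits:
        if h.read_id != truth.read_id:
            raise ValueError(
                f"hit read_id {h.read_id!r} does not match truth {truth.read_id!r}"
            )
    any_mapped = any(h.mapped for h in hits)
    if truth.is_random:
        cat = Category.RANDOM_MAPPED if any_mapped else Category.RANDOM_REJECTED
        return ClassificationOutcome(truth.read_id, cat)
    if not any_mapped:
        return ClassificationOutcome(truth.read_id, Category.UNMAPPED)
    for hit in hits:
        if hit_satisfies(truth, hit, policy):
            return ClassificationOutcome(truth.read_id, Category.CORRECT, hit)
    return ClassificationOutcome(truth.read_id, Category.INCORRECT)


RANDOM_POLICIES = ("exclude_random", "literal")


def summarize(
    outcomes: Sequence[ClassificationOutcome],
    random_policy: str = "exclude_random",
) -> EvaluationSummary:
    """Aggregate outcomes into TP/FP/FN, precision, recall and F-measure.

    ``exclude_random`` (default): correctly rejected random reads are true
    negatives and leave the formulas; random reads that map anywhere are
    false positives.  ``literal``: unmapped random reads enter FN, applying
    the printed formulas verbatim.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    if random_policy not in RANDOM_POLICIES:
        raise ValueError(f"random_policy must be one of {RANDOM_POLICIES}")
    counts = {c.name: 0 for c in Category}
    for o in outcomes:
        counts[o.category.name] += 1
    tp = counts["CORRECT"]
    fp = counts["INCORRECT"] + counts["RANDOM_MAPPED"]
    fn = counts["UNMAPPED"]
    if random_policy == "literal":
        fn += counts["RANDOM_REJECTED"]
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_measure = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    n_mapped = counts["CORRECT"] + counts["INCORRECT"] + counts["RANDOM_MAPPED"]
    return EvaluationSummary(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f_measure=f_measure,
        fraction_mapped=n_mapped / len(outcomes),
        category_counts=counts,
    )


def evaluate_mapping(
    truths: Sequence[ReadTruth],
    grouped_hits: Mapping[str, Sequence[AlignmentObservation]],
    policy: ShiftPolicy = ShiftPolicy(),
    random_policy: str = "exclude_random",
) -> tuple[list[ClassificationOutcome], EvaluationSummary]:
    """Classify every truth read against its hits and summarize.

    Reads absent from the SAM entirely count as unmapped.
    """
    outcomes = [
        classify_read(t, grouped_hits.get(t.read_id, ()), policy) for t in truths
    ]
    return outcomes, summarize(outcomes, random_policy)


# ---------------------------------------------------------------------------
# Repeat-recovery evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatEvaluation:
    """Per-read distinct-copy hit counts and their percentage histogram."""

    per_read: Mapping[str, int]
    histogram: Mapping[int, float]  # class (0..n_copies) -> % of repeat reads
    n_repeat_reads: int


def evaluate_repeats(
    truths: Sequence[ReadTruth],
    grouped_hits: Mapping[str, Sequence[AlignmentObservation]],
    repeat_map: RepeatMap,
    policy: ShiftPolicy = ShiftPolicy(),
) -> RepeatEvaluation:
    """Count, per repeat-located read, the distinct repeat copies recovered.

    A read is repeat-located iff its truth start lies inside a repeat
    interval.  A copy counts as recovered when at least one hit starts at
    the read's equivalent within-copy offset, up to ``max_shift``.
    """
    per_read: dict[str, int] = {}
    for truth in truths:
        if truth.is_random:
            continue
        copy_idx = repeat_map.containing(truth.start)
        if copy_idx is None:
            continue
        offset = truth.start - repeat_map.intervals[copy_idx][0]
        hits = [h for h in grouped_hits.get(truth.read_id, ()) if h.mapped]
        recovered = 0
        for c_start, _ in repeat_map.intervals:
            expected = c_start + offset
            if any(abs(h.start - expected) <= policy.max_shift for h in hits):
                recovered += 1
        per_read[truth.read_id] = recovered
    n = len(per_read)
    histogram = {
        k: (100.0 * sum(1 for v in per_read.values() if v == k) / n if n else 0.0)
        for k in range(repeat_map.n_copies + 1)
    }
    return RepeatEvaluation(per_read, histogram, n)


# ---------------------------------------------------------------------------
# Truth-derived SAM (the "perfect mapper")
# ---------------------------------------------------------------------------

def _truth_cigar(truth: ReadTruth) -> str:
    """A CIGAR consistent with the truth span and canonical counts."""
    read_len = truth.read_length
    m_total = read_len - truth.n_ins
    parts: list[str] = []
    if truth.n_ins == 0 and truth.n_del == 0:
        return f"{read_len}M"
    if m_total < 2 + (truth.n_ins > 0 and truth.n_del > 0):
        raise ValueError(
            f"read {truth.read_id}: too few matched bases to build a CIGAR"
        )
    if truth.n_ins > 0 and truth.n_del > 0:
        parts = [f"1M{truth.n_ins}I1M{truth.n_del}D{m_total - 2}M"]
    elif truth.n_ins > 0:
        parts = [f"1M{truth.n_ins}I{m_total - 1}M"]
    else:
        parts = [f"1M{truth.n_del}D{m_total - 1}M"]
    return parts[0]


def build_truth_sam(
    truths: Sequence[ReadTruth],
    reference: Sequence[Contig],
    path: str | Path,
    sequences: Sequence[str] | None = None,
    encode_names: bool = True,
) -> None:
    """Write the SAM an ideal mapper would produce from the truth table.

    Non-random reads get one hit at the exact truth position with a CIGAR
    and NM tag reproducing the canonical counts; random reads are emitted as
    unmapped records.  Useful as a round-trip check of the whole evaluation
    chain (every read must classify CORRECT) and as a corruption baseline.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in reference:
            fh.write(f"@SQ\tSN:{c.name}\tLN:{c.length}\n")
        for i, t in enumerate(truths):
            name = encode_truth_name(t) if encode_names else t.read_id
            seq = sequences[i] if sequences is not None else "*"
            if t.is_random:
                fh.write(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            flag = 16 if t.strand == "-" else 0
            if flag and seq != "*":
                seq = reverse_complement(seq)  # SAM stores the forward strand
            nm = t.n_ins + t.n_del + t.n_sub
            fh.write(
                f"{name}\t{flag}\t{t.contig}\t{t.start}\t60\t{_truth_cigar(t)}"
                f"\t*\t0\t0\t{seq}\t*\tNM:i:{nm}\n"
            )


def write_report(summary: EvaluationSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
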