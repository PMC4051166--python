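"""Score variant-caller output against introduced-mutation truth.

Truth mutations live in ORIGINAL-genome coordinates and describe the edit
original -> mutated.  A caller, however, maps sample reads (drawn from the
original genome) against the *mutated* genome used as reference, so its VCF
reports each introduced mutation in mirror orientation — at mutated-genome
coordinates, with ref/alt swapped and insertions appearing as deletions.
Matching therefore lifts every call back to original coordinates via the
cumulative indel offset of preceding mutations, inverts it, and left-
normalizes both sides before comparing kind, position and alleles.

Metrics follow the CM/IM/NM convention: CM correctly identified mutations
(same kind, same or equivalent position), IM incorrectly identified, NM not
found; precision = CM/(CM+IM) and recall = CM/(CM+IM+NM).  Note the recall
denominator includes IM — the conventional CM/(CM+NM) is available behind a
flag.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .exceptions import CoordinateSystemError
from .genome_forge import MutationRecord
from .io_formats import Contig, VariantCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationMatchResult:
    cm: int
    im: int
    nm: int
    precision: float
    recall: float
    recall_conventional: float

    def to_dict(self) -> dict:
        return {
            "CM": self.cm, "IM": self.im, "NM": self.nm,
            "precision": self.precision, "recall": self.recall,
            "recall_conventional": self.recall_conventional,
        }


def variant_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "substitution"
    return "insertion" if len(alt) > len(ref) else "deletion"


def normalize_variant(
    call: VariantCall, reference: Mapping[str, str]
) -> VariantCall:
    """Canonicalize a variant: trim shared context, left-align indels.

    Follows the standard normalization loop: truncate shared rightmost
    bases, extending indels leftward with reference context when an allele
    would empty; then truncate shared leftmost bases while both alleles keep
    length >= 2.  Substitutions pass through unchanged.  Idempotent.
    """
    seq = reference.get(call.contig)
    if seq is None:
        raise CoordinateSystemError(f"unknown contig {call.contig!r}")
    pos, ref, alt = call.position, call.ref_allele, call.alt_allele
    if seq[pos - 1:pos - 1 + len(ref)] != ref:
        raise CoordinateSystemError(
            f"ref allele {ref!r} disagrees with reference at "
            f"{call.contig}:{pos}"
        )
    changed = True
    while changed:
        changed = False
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] \
                and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 1:
            base = seq[pos - 2]
            ref, alt = base + ref, base + alt
            pos -= 1
            changed = True
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:
        raise CoordinateSystemError(
            f"variant at {call.contig}:{call.position} cannot be anchored "
            "(indel at contig start)"
        )
    if (pos, ref, alt) == (call.position, call.ref_allele, call.alt_allele):
        return call
    return VariantCall(
        call.contig, pos, ref, alt, call.depth, call.alt_fraction
    )


# ---------------------------------------------------------------------------
# Coordinate lift between original and mutated genomes
# ---------------------------------------------------------------------------

class CoordinateLift:
    """Maps coordinates between the original genome and its mutated copy.

    Built from the sorted mutation records of one contig; positions strictly
    after a mutation's anchor shift by its cumulative length change.
    """

    def __init__(self, records: Sequence[MutationRecord]):
        recs = sorted(records, key=lambda r: (r.contig, r.position))
        self._by_contig: dict[str, tuple[list[int], list[int], list[int]]] = {}
        for rec in recs:
            orig_pos, mut_pos, deltas = self._by_contig.setdefault(
                rec.contig, ([], [], [])
            )
            prev_delta = deltas[-1] if deltas else 0
            orig_pos.append(rec.position)
            mut_pos.append(rec.position + prev_delta)
            deltas.append(prev_delta + rec.length_change)

    def to_mutated(self, contig: str, position: int) -> int:
        orig_pos, _, deltas = self._by_contig.get(contig, ([], [], []))
        i = bisect_right(orig_pos, position - 1)  # mutations strictly before
        return position + (deltas[i - 1] if i else 0)

    def to_original(self, contig: str, position: int) -> int:
        _, mut_pos, deltas = self._by_contig.get(contig, ([], [], []))
        i = bisect_right(mut_pos, position)
        if i and mut_pos[i - 1] == position:
            # the anchor itself maps back under the *preceding* offset
            i -= 1
        return position - (deltas[i - 1] if i else 0)


def invert_call(
    call: VariantCall, lift: CoordinateLift
) -> VariantCall:
    """Re-express a call made against the mutated reference as the
    introduced original->mutated mutation it detects: lift the position to
    original coordinates and swap ref/alt."""
    return VariantCall(
        contig=call.contig,
        position=lift.to_original(call.contig, call.position),
        ref_allele=call.alt_allele,
        alt_allele=call.ref_allele,
        depth=call.depth,
        alt_fraction=call.alt_fraction,
    )


# ---------------------------------------------------------------------------
# Matching and scoring
# ---------------------------------------------------------------------------

def match_and_score(
    truth: Sequence[MutationRecord],
    calls: Sequence[VariantCall],
    original_reference: Sequence[Contig],
    orientation: str = "mutated_ref",
    conventional_recall: bool = False,
) -> MutationMatchResult:
    """Match filtered calls against introduced mutations and score CM/IM/NM.

    ``orientation='mutated_ref'`` (default) treats the calls as made against
    the mutated genome and lifts/inverts them first;
    ``orientation='original_ref'`` compares directly.  Calls whose
    (inverted) ref allele disagrees with the original reference are counted
    IM with a warning; if more than half the calls fail the check a
    :class:`CoordinateSystemError` is raised instead.
    """
    if orientation not in ("mutated_ref", "original_ref"):
        raise ValueError(f"unknown orientation {orientation!r}")
    ref_map = {c.name: c.sequence for c in original_reference}
    lift = CoordinateLift(truth) if orientation == "mutated_ref" else None

    normalized_calls: list[VariantCall] = []
    n_bad = 0
    for call in calls:
        candidate = invert_call(call, lift) if lift is not None else call
        try:
            normalized_calls.append(normalize_variant(candidate, ref_map))
        except CoordinateSystemError as exc:
            n_bad += 1
            logger.warning("call does not fit original reference (IM): %s", exc)
            normalized_calls.append(None)  # type: ignore[arg-type]
    if calls and n_bad > len(calls) / 2:
        raise CoordinateSystemError(
            f"{n_bad}/{len(calls)} calls disagree with the original "
            "reference — truth and calls are likely on different coordinate "
            "systems"
        )

    def key(contig: str, pos: int, ref: str, alt: str) -> tuple:
        return (contig, pos, ref, alt, variant_kind(ref, alt))

    available: dict[tuple, int] = {}
    for nc in normalized_calls:
        if nc is not None:
            k = key(nc.contig, nc.position, nc.ref_allele, nc.alt_allele)
            available[k] = available.get(k, 0) + 1

    cm = 0
    for rec in sorted(truth, key=lambda r: (r.contig, r.position)):
        norm = normalize_variant(
            VariantCall(rec.contig, rec.position, rec.ref_allele,
                        rec.alt_allele, depth=1, alt_fraction=1.0),
            ref_map,
        )
        k = key(norm.contig, norm.position, norm.ref_allele, norm.alt_allele)
        if available.get(k, 0) > 0:
            available[k] -= 1
            cm += 1
    nm = len(truth) - cm
    im = len(calls) - cm
    precision = cm / (cm + im) if cm + im else 0.0
    recall_printed = cm / (cm + im + nm) if cm + im + nm else 0.0
    recall_conv = cm / (cm + nm) if cm + nm else 0.0
    return MutationMatchResult(
        cm=cm, im=im, nm=nm,
        precision=precision,
        recall=recall_conv if conventional_recall else recall_printed,
        recall_conventional=recall_conv,
    )


# ---------------------------------------------------------------------------
# Truth-derived VCF (the "perfect caller")
# ---------------------------------------------------------------------------

def vcf_from_truth(
    truth: Sequence[MutationRecord],
    mutated_reference: Sequence[Contig],
    path: str | Path,
    depth: int = 50,
) -> None:
    """Write the VCF an ideal caller would produce against the mutated
    genome: each introduced mutation in mirror orientation at its
    mutated-genome coordinate, full depth and frequency 1."""
    lift = CoordinateLift(truth)
    mut_map = {c.name: c.sequence for c in mutated_reference}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate observations">',
    ]
    for c in mutated_reference:
        lines.append(f"##contig=<ID={c.name},length={c.length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = []
    for rec in sorted(truth, key=lambda r: (r.contig, r.position)):
        pos = lift.to_mutated(rec.contig, rec.position)
        ref, alt = rec.alt_allele, rec.ref_allele  # mirror orientation
        seq = mut_map[rec.contig]
        if seq[pos - 1:pos - 1 + len(ref)] != ref:
            raise CoordinateSystemError(
                f"internal lift error at {rec.contig}:{rec.position}"
            )
        rows.append((pos, f"{rec.contig}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS"
                     f"\tDP={depth};AO={depth}"))
    rows.sort(key=lambda r: r[0])
    lines.extend(r[1] for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(result: MutationMatchResult, path: str | Path,
                 metadata: dict | None = None) -> None:
    payload = result.to_dict()
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
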