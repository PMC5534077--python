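"""Sequential per-amplicon error correction for amplicon variant tables.

Among each amplicon's top-50 variants, variants that differ from a deeper
variant by one or two substitutions, or by a single-base indel inside a
homopolymer run, are candidate artefacts.  Depth ratios and cross-amplicon
occurrence decide the verdict:

* 454-style data: a 1-2 nt variant below 50% of its putative parent's
  depth is an artefact if it occurs in exactly one amplicon of the whole
  run, and a true allele if it occurs in more than one.
* MiSeq-style data (substitution errors recur at the same sites across
  amplicons): a 1-2 nt variant is a true allele only if it occurs at over
  50% of the parent's depth in *every* amplicon where the two co-occur, or
  if it appears in at least one amplicon without the parent; otherwise it
  is an artefact.
* Homopolymer-indel variants (both platforms): artefact when shallower
  than the parent and never observed in an amplicon lacking the parent.

Artefact reads are never discarded: their depth is added to the parent
variant, so per-amplicon totals are conserved.  Cross-amplicon evidence is
evaluated on a snapshot of the uncorrected table, so the sequential
processing order cannot erase evidence of multi-amplicon presence.
A variant private to a single sample is never deleted for privacy alone —
rare alleles are expected — only via a qualifying parent relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

from .preprocess import VariantTable


@dataclass(frozen=True)
class VariantRelation:
    """Alignment relation between a variant and a candidate parent."""

    variant: str
    candidate_parent: str
    substitutions: int
    indels: int
    homopolymer_indel: bool
    depth_ratio: float = 0.0


@dataclass(frozen=True)
class CorrectionDecision:
    """One correction verdict for a variant within an amplicon."""

    amplicon: str
    variant: str
    verdict: str  # artefact | true_allele | untouched
    rule: str  # ratio_454 | ratio_miseq | homopolymer | none
    parent: Optional[str] = None
    amplicons_consulted: int = 0


def top_variants(
    entry: dict[str, int], k: int = 50
) -> list[tuple[str, int]]:
    """The k deepest variants of an amplicon, depth-descending with
    deterministic lexicographic tie-breaking."""
    ranked = sorted(entry.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def _parse_cigar(cigar: str) -> tuple[int, int]:
    """(substitutions, indel bases) from an edlib extended CIGAR."""
    subs = indels = 0
    n = ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            length = int(n)
            n = ""
            if c == "X":
                subs += length
            elif c in "ID":
                indels += length
    return subs, indels


def _single_indel_info(longer: str, shorter: str) -> tuple[int, str] | None:
    """If deleting exactly one base of ``longer`` yields ``shorter``,
    return (leftmost deletable position, base); else None."""
    if len(longer) - len(shorter) != 1:
        return None
    i = 0
    while i < len(shorter) and longer[i] == shorter[i]:
        i += 1
    if longer[:i] + longer[i + 1 :] == shorter:
        return i, longer[i]
    return None


def _run_length_at(seq: str, pos: int) -> int:
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1


def variant_distance(a: str, b: str, run_min: int = 3) -> VariantRelation:
    """Substitution/indel counts from an optimal unit-cost global alignment,
    plus a homopolymer flag.

    ``homopolymer_indel`` is True iff the only difference is a single-base
    insertion/deletion whose base sits in a run of length >= ``run_min``
    in the longer sequence (run length measured with the base present).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return VariantRelation(a, b, 0, 0, False)
    if len(a) == len(b):
        subs = sum(x != y for x, y in zip(a, b))
        # an equal-length pair may still align better with indels
        if subs <= 2:
            return VariantRelation(a, b, subs, 0, False)
    res = edlib.align(a, b, mode="NW", task="path")
    subs, indels = _parse_cigar(res["cigar"])
    homopolymer = False
    if subs == 0 and indels == 1:
        longer, shorter = (a, b) if len(a) > len(b) else (b, a)
        info = _single_indel_info(longer, shorter)
        if info is not None:
            pos, _base = info
            homopolymer = _run_length_at(longer, pos) >= run_min
    return VariantRelation(a, b, subs, indels, homopolymer)


# ---------------------------------------------------------------------------
# per-amplicon correction


def _relation_type(a: str, b: str, run_min: int) -> str | None:
    """Fast qualifying-relation check: 'sub' (1-2 substitutions, no indels)
    or 'homopolymer' (single homopolymer indel), else None."""
    la, lb = len(a), len(b)
    if la == lb:
        subs = 0
        for x, y in zip(a, b):
            if x != y:
                subs += 1
                if subs > 2:
                    return None
        return "sub" if 1 <= subs <= 2 else None
    if abs(la - lb) == 1:
        longer, shorter = (a, b) if la > lb else (b, a)
        info = _single_indel_info(longer, shorter)
        if info is not None and _run_length_at(longer, info[0]) >= run_min:
            return "homopolymer"
    return None


class _Snapshot:
    """Occurrence index over the uncorrected, length-filtered table."""

    def __init__(self, table: VariantTable):
        self.depth: dict[str, dict[str, int]] = {
            a: dict(v) for a, v in table.entries.items()
        }
        self.occ: dict[str, set[str]] = {}
        for amplicon, variants in table.entries.items():
            for seq in variants:
                self.occ.setdefault(seq, set()).add(amplicon)

    def amplicons_with(self, seq: str) -> set[str]:
        return self.occ.get(seq, set())


def _correct_entry(
    amplicon_id: str,
    entry: dict[str, int],
    snapshot: _Snapshot,
    platform: str,
    top_k: int,
    run_min: int,
) -> tuple[dict[str, int], list[CorrectionDecision]]:
    current = dict(entry)
    top_set = {seq for seq, _ in top_variants(entry, top_k)}
    decisions: list[CorrectionDecision] = []
    decided_true: set[str] = set()

    # candidate artefacts in ascending depth order so cascades resolve
    # shallow-first (an artefact-of-artefact folds into its parent before
    # that parent is evaluated)
    for seq in sorted(top_set, key=lambda s: (entry[s], s)):
        if seq not in current or seq in decided_true:
            continue
        depth = current[seq]
        # candidate parent: deepest co-occurring top-k variant with a
        # qualifying relation and at least this variant's depth
        parent = None
        rel_type = None
        for cand, cand_depth in sorted(
            current.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            if cand == seq or cand not in top_set or cand_depth < depth:
                continue
            rt = _relation_type(seq, cand, run_min)
            if rt is not None:
                parent, rel_type = cand, rt
                break
        if parent is None:
            continue

        occ = snapshot.amplicons_with(seq)
        if rel_type == "homopolymer":
            without_parent = {
                a for a in occ if parent not in snapshot.depth[a]
            }
            if depth < current[parent] and not without_parent:
                current[parent] += current.pop(seq)
                decisions.append(
                    CorrectionDecision(
                        amplicon_id, seq, "artefact", "homopolymer", parent, len(occ)
                    )
                )
            else:
                decided_true.add(seq)
                decisions.append(
                    CorrectionDecision(
                        amplicon_id, seq, "true_allele", "homopolymer", parent, len(occ)
                    )
                )
        elif platform == "454":
            if depth < 0.5 * current[parent]:
                if len(occ) <= 1:
                    current[parent] += current.pop(seq)
                    verdict = "artefact"
                else:
                    decided_true.add(seq)
                    verdict = "true_allele"
                decisions.append(
                    CorrectionDecision(
                        amplicon_id, seq, verdict, "ratio_454", parent, len(occ)
                    )
                )
            else:
                decisions.append(
                    CorrectionDecision(
                        amplicon_id, seq, "untouched", "none", parent, 1
                    )
                )
        else:  # miseq
            without_parent = {
                a for a in occ if parent not in snapshot.depth[a]
            }
            co_occurring = occ - without_parent
            always_over_half = all(
                snapshot.depth[a][seq] > 0.5 * snapshot.depth[a][parent]
                for a in co_occurring
            )
            if without_parent or always_over_half:
                decided_true.add(seq)
                decisions.append(
                    CorrectionDecision(
                        amplicon_id, seq, "true_allele", "ratio_miseq", parent, len(occ)
                    )
                )
            else:
                current[parent] += current.pop(seq)
                decisions.append(
                    CorrectionDecision(
                        amplicon_id, seq, "artefact", "ratio_miseq", parent, len(occ)
                    )
                )
    return current, decisions


def correct_amplicon_454(
    amplicon_id: str,
    table: VariantTable,
    top_k: int = 50,
    run_min: int = 3,
) -> tuple[dict[str, int], list[CorrectionDecision]]:
    """Correct one amplicon with the 454 cross-amplicon occurrence rule."""
    snapshot = _Snapshot(table)
    return _correct_entry(
        amplicon_id, table.entries[amplicon_id], snapshot, "454", top_k, run_min
    )


def correct_amplicon_miseq(
    amplicon_id: str,
    table: VariantTable,
    top_k: int = 50,
    run_min: int = 3,
) -> tuple[dict[str, int], list[CorrectionDecision]]:
    """Correct one amplicon with the MiSeq always-over-50% rule."""
    snapshot = _Snapshot(table)
    return _correct_entry(
        amplicon_id, table.entries[amplicon_id], snapshot, "miseq", top_k, run_min
    )


def correct_table(
    table: VariantTable,
    top_k: int = 50,
    run_min: int = 3,
    amplicon_order: Iterable[str] | None = None,
) -> tuple[VariantTable, list[CorrectionDecision]]:
    """Correct every amplicon of a length-filtered table, sequentially in
    amplicon-id order, dispatching on the table's platform.  Returns the
    corrected table and the full decision log."""
    snapshot = _Snapshot(table)
    corrected = table.copy()
    decisions: list[CorrectionDecision] = []
    order = list(amplicon_order) if amplicon_order is not None else sorted(table.entries)
    for amplicon_id in order:
        entry, dec = _correct_entry(
            amplicon_id,
            table.entries[amplicon_id],
            snapshot,
            table.platform,
            top_k,
            run_min,
        )
        corrected.entries[amplicon_id] = entry
        decisions.extend(dec)
    corrected.record_stage(
        "error_correction",
        sum(1 for d in decisions if d.verdict == "artefact"),
    )
    return corrected, decisions


def write_decision_log(
    decisions: Iterable[CorrectionDecision], path
) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon\tvariant\tverdict\trule\tparent\tamplicons_consulted\n")
        for d in decisions:
            fh.write(
                f"{d.amplicon}\t{d.variant}\t{d.verdict}\t{d.rule}\t"
                f"{d.parent or ''}\t{d.amplicons_consulted}\n"
            )
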