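"""Raw reads -> per-amplicon variant x depth table.

Re-implements the preprocessing chain of an MHC amplicon study: paired-end
merging on long exact-ish overlaps, a mean-Q30 quality filter, dual-tag
demultiplexing with primer trimming (IUPAC degeneracy honoured), an exact
sequence tally per amplicon, singleton removal, and the classical-allele
length filter (239-242 bp retained, co-amplified 236 bp non-classical
variants removed).

Every stage appends to the table's provenance log so read counts reconcile
from raw input to the final table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from ._util import iupac_match, revcomp
from .simdata import CLASSICAL_LENGTH_RANGE, PRIMER_FWD, PRIMER_REV, TAG_LENGTH


@dataclass
class ReadRecord:
    """A read with optional per-base Phred scores."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id}: qualities/sequence length mismatch")

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            raise ValueError(f"read {self.id} has no qualities")
        return float(np.mean(self.qualities))


@dataclass
class StageRecord:
    """Provenance entry: per-amplicon total depth after one stage, plus the
    number of reads (or read pairs) removed at that stage."""

    stage: str
    depth_by_amplicon: dict[str, int]
    removed: int = 0

    @property
    def total(self) -> int:
        return sum(self.depth_by_amplicon.values())


@dataclass
class VariantTable:
    """Per-amplicon mapping of distinct trimmed insert sequences to read
    depth (the style of table a tag-sorting tool like jMHC produces)."""

    entries: dict[str, dict[str, int]]
    platform: str
    log: list[StageRecord] = field(default_factory=list)

    def total_depth(self, amplicon_id: str) -> int:
        return sum(self.entries[amplicon_id].values())

    @property
    def amplicon_ids(self) -> list[str]:
        return sorted(self.entries)

    def record_stage(self, stage: str, removed: int = 0) -> None:
        self.log.append(
            StageRecord(
                stage,
                {a: sum(v.values()) for a, v in self.entries.items()},
                removed,
            )
        )

    def copy(self) -> "VariantTable":
        return VariantTable(
            {a: dict(v) for a, v in self.entries.items()},
            self.platform,
            list(self.log),
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("amplicon_id\tvariant_seq\tdepth\n")
            for amplicon in sorted(self.entries):
                variants = self.entries[amplicon]
                for seq in sorted(variants, key=lambda s: (-variants[s], s)):
                    fh.write(f"{amplicon}\t{seq}\t{variants[seq]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, platform: str) -> "VariantTable":
        entries: dict[str, dict[str, int]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("amplicon_id"):
                raise ValueError(f"{path}: missing variant-table header")
            for line in fh:
                amplicon, seq, depth = line.rstrip("\n").split("\t")
                entries.setdefault(amplicon, {})[seq] = int(depth)
        return cls(entries, platform)

    def write_stage_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\ttotal_reads\tn_amplicons\tremoved\n")
            for rec in self.log:
                fh.write(
                    f"{rec.stage}\t{rec.total}\t{len(rec.depth_by_amplicon)}\t{rec.removed}\n"
                )


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 100,
    max_mismatch_fraction: float = 0.25,
) -> ReadRecord | None:
    """Merge a read pair on the best ungapped overlap.

    ``r2`` is reverse-complemented; the suffix of ``r1`` is aligned against
    the prefix of revcomp(r2) at every overlap length >= ``min_overlap``
    and the overlap with the lowest mismatch fraction (ties: longest) is
    taken.  Overlap disagreements resolve to the higher-quality base;
    agreeing positions keep the higher of the two qualities.  Returns None
    (rejection) when no overlap qualifies.
    """
    if not r1.sequence or not r2.sequence:
        raise ValueError("reads must be non-empty")
    if r1.qualities is None or r2.qualities is None:
        raise ValueError("merge_pairs requires qualities")
    s1 = r1.sequence
    s2 = revcomp(r2.sequence)
    q1 = r1.qualities
    q2 = r2.qualities[::-1]
    max_len = min(len(s1), len(s2))
    if max_len < min_overlap:
        return None

    best: tuple[float, int] | None = None  # (mismatch fraction, overlap)
    # fast path: a long exact overlap found by substring search
    probe = s2[: min(25, max_len)]
    start = 0
    while True:
        idx = s1.find(probe, start)
        if idx < 0:
            break
        overlap = len(s1) - idx
        if min_overlap <= overlap <= max_len and s1[idx:] == s2[:overlap]:
            best = (0.0, overlap)
            break
        start = idx + 1

    if best is None:
        a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
        for overlap in range(max_len, min_overlap - 1, -1):
            mism = int(np.count_nonzero(a1[len(s1) - overlap :] != a2[:overlap]))
            frac = mism / overlap
            if frac <= max_mismatch_fraction and (best is None or frac < best[0]):
                best = (frac, overlap)
                if mism == 0:
                    break
        if best is None:
            return None

    _, overlap = best
    off = len(s1) - overlap
    merged_seq = list(s1[:off])
    merged_q = list(q1[:off])
    for i in range(overlap):
        b1, b2 = s1[off + i], s2[i]
        p1, p2 = q1[off + i], q2[i]
        if b1 == b2:
            merged_seq.append(b1)
            merged_q.append(max(p1, p2))
        elif p1 >= p2:
            merged_seq.append(b1)
            merged_q.append(p1)
        else:
            merged_seq.append(b2)
            merged_q.append(p2)
    merged_seq.extend(s2[overlap:])
    merged_q.extend(q2[overlap:])
    return ReadRecord(r1.id, "".join(merged_seq), merged_q)


def merge_read_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    min_overlap: int = 100,
    max_mismatch_fraction: float = 0.25,
) -> tuple[list[ReadRecord], int]:
    """Merge a stream of pairs; returns (merged reads, rejected pair count)."""
    merged, rejected = [], 0
    for r1, r2 in pairs:
        m = merge_pairs(r1, r2, min_overlap, max_mismatch_fraction)
        if m is None:
            rejected += 1
        else:
            merged.append(m)
    return merged, rejected


# ---------------------------------------------------------------------------
# quality filter


def filter_quality(
    reads: Iterable[ReadRecord], min_mean_phred: float = 30.0
) -> tuple[list[ReadRecord], int]:
    """Keep reads whose mean Phred score is >= ``min_mean_phred``; reads
    strictly below the threshold are removed (a mean of exactly 30 passes)."""
    kept, dropped = [], 0
    for r in reads:
        if r.mean_quality >= min_mean_phred:
            kept.append(r)
        else:
            dropped += 1
    return kept, dropped


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex_trim(
    reads: Iterable[ReadRecord],
    tags: Mapping[str, tuple[str, str]],
    primers: tuple[str, str] = (PRIMER_FWD, PRIMER_REV),
    primer_mismatch_budget: int = 0,
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to amplicons by their dual 6 bp tags and trim tags and
    primers away.

    A read is assigned iff, in forward or reverse-complement orientation,
    it begins with ``fwd_tag + fwd_primer`` and ends with
    ``revcomp(rev_primer) + revcomp(rev_tag)`` for some sample's tag pair.
    Degenerate IUPAC codes in the primers match their degeneracy set; tag
    matching is exact.  Returns (amplicon -> trimmed inserts, unassigned).
    """
    pair_to_sample: dict[tuple[str, str], str] = {}
    for sample, pair in tags.items():
        if tuple(pair) in pair_to_sample:
            raise ValueError(f"duplicate tag pair {pair} in tag table")
        pair_to_sample[tuple(pair)] = sample

    fwd_primer, rev_primer = primers
    rev_primer_rc = revcomp(rev_primer)
    n_f, n_r = len(fwd_primer), len(rev_primer)

    out: dict[str, list[str]] = {sample: [] for sample in tags}
    unassigned = 0
    for read in reads:
        assigned = False
        for seq in (read.sequence, revcomp(read.sequence)):
            if len(seq) < 2 * TAG_LENGTH + n_f + n_r + 1:
                continue
            fwd_tag = seq[:TAG_LENGTH]
            rev_tag = revcomp(seq[-TAG_LENGTH:])
            sample = pair_to_sample.get((fwd_tag, rev_tag))
            if sample is None:
                continue
            if not iupac_match(
                fwd_primer, seq[TAG_LENGTH : TAG_LENGTH + n_f], primer_mismatch_budget
            ):
                continue
            if not iupac_match(
                rev_primer_rc,
                seq[-TAG_LENGTH - n_r : -TAG_LENGTH],
                primer_mismatch_budget,
            ):
                continue
            out[sample].append(seq[TAG_LENGTH + n_f : -TAG_LENGTH - n_r])
            assigned = True
            break
        if not assigned:
            unassigned += 1
    return out, unassigned


# ---------------------------------------------------------------------------
# tally and filters


def tally_variants(
    inserts_by_amplicon: Mapping[str, Iterable[str]], platform: str
) -> VariantTable:
    """Group trimmed inserts by exact sequence into a depth table.  Empty
    amplicons are retained with an empty entry (depth sum 0)."""
    entries = {
        amplicon: dict(Counter(inserts))
        for amplicon, inserts in inserts_by_amplicon.items()
    }
    table = VariantTable(entries, platform)
    table.record_stage("tally")
    return table


def table_from_simulated(amplicons, platform: str) -> VariantTable:
    """Tally simulated amplicons (see :mod:`mhcdoc.simdata`) straight into
    a variant table, bypassing read emission and demultiplexing — the
    entry point for amplicon-level simulation studies."""
    entries: dict[str, dict[str, int]] = {}
    for sample, amp in amplicons.items():
        counts: Counter = Counter()
        for (seq, _label), n in amp.counts.items():
            counts[seq] += n
        entries[sample] = dict(counts)
    table = VariantTable(entries, platform)
    table.record_stage("tally")
    return table


def drop_singletons(table: VariantTable) -> VariantTable:
    """Remove variants with read depth 1 within their amplicon."""
    out = table.copy()
    removed = 0
    for amplicon, variants in out.entries.items():
        singletons = [seq for seq, depth in variants.items() if depth == 1]
        removed += len(singletons)
        for seq in singletons:
            del variants[seq]
    out.record_stage("drop_singletons", removed)
    return out


def length_filter(
    table: VariantTable,
    retain_range: tuple[int, int] = CLASSICAL_LENGTH_RANGE,
) -> VariantTable:
    """Keep only variants whose trimmed length is inside ``retain_range``
    (inclusive); this removes the 236 bp co-amplified non-classical
    variants along with any other off-length sequence."""
    lo, hi = retain_range
    out = table.copy()
    removed_reads = 0
    for amplicon, variants in out.entries.items():
        bad = [seq for seq in variants if not lo <= len(seq) <= hi]
        removed_reads += sum(variants[seq] for seq in bad)
        for seq in bad:
            del variants[seq]
    out.record_stage("length_filter", removed_reads)
    return out


# ---------------------------------------------------------------------------
# file-level drivers


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(
                title.split()[0], seq.upper(), [ord(c) - 33 for c in qual]
            )


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield ReadRecord(rec.id, str(rec.seq).upper())


def read_tag_table(path: str | Path) -> dict[str, tuple[str, str]]:
    tags: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError(f"{path}: missing tag-table header")
        for line in fh:
            sample, fwd, rev = line.rstrip("\n").split("\t")
            tags[sample] = (fwd, rev)
    return tags


def preprocess_run(
    platform: str,
    reads: str | Path | tuple[str | Path, str | Path],
    tags: Mapping[str, tuple[str, str]] | str | Path,
    primers: tuple[str, str] = (PRIMER_FWD, PRIMER_REV),
    min_overlap: int = 100,
    max_mismatch_fraction: float = 0.25,
    min_mean_phred: float = 30.0,
    retain_range: tuple[int, int] = CLASSICAL_LENGTH_RANGE,
) -> VariantTable:
    """Full preprocessing: (merge ->) (Q30 ->) demultiplex/trim -> tally ->
    drop singletons -> length filter.

    454-style input is a single FASTA/FASTQ of full-length reads (no
    quality filter is applied to FASTA); MiSeq-style input is an (R1, R2)
    FASTQ pair merged on >=``min_overlap`` bp overlaps.
    """
    if not isinstance(tags, Mapping):
        tags = read_tag_table(tags)
    n_input = 0
    if platform == "miseq":
        r1_path, r2_path = reads
        pairs = zip(read_fastq(r1_path), read_fastq(r2_path))
        merged, n_rejected = [], 0
        for r1, r2 in pairs:
            n_input += 1
            m = merge_pairs(r1, r2, min_overlap, max_mismatch_fraction)
            if m is None:
                n_rejected += 1
            else:
                merged.append(m)
        passing, n_lowq = filter_quality(merged, min_mean_phred)
    elif platform == "454":
        path = Path(reads if not isinstance(reads, tuple) else reads[0])
        reader = read_fastq if path.suffix in (".fastq", ".fq") else read_fasta
        passing = list(reader(path))
        n_input = len(passing)
        n_rejected = n_lowq = 0
    else:
        raise ValueError("platform must be '454' or 'miseq'")

    inserts, unassigned = demultiplex_trim(passing, tags, primers)
    table = tally_variants(inserts, platform)
    table.log.insert(
        0,
        StageRecord("input", {"(run)": n_input}, 0),
    )
    if platform == "miseq":
        table.log.insert(
            1, StageRecord("merge_pairs", {"(run)": n_input - n_rejected}, n_rejected)
        )
        table.log.insert(
            2,
            StageRecord(
                "quality_filter", {"(run)": n_input - n_rejected - n_lowq}, n_lowq
            ),
        )
    table.log.insert(
        len(table.log) - 1,
        StageRecord(
            "demultiplex", {"(run)": sum(len(v) for v in inserts.values())}, unassigned
        ),
    )
    table = drop_singletons(table)
    table = length_filter(table, retain_range)
    return table
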