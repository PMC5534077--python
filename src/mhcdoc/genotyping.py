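"""Degree-of-change (DOC) allele calling over corrected variant tables.

True alleles amplify at markedly higher depth than residual artefacts, so
when an amplicon's variants are ranked by depth there is an inflection in
the cumulative depth curve at the allele/artefact boundary.  The DOC
statistic expresses the rate of change (ROC) around each break between
successive ranked variants as a percentage of the total change; the
maximum locates the boundary and its rank is the inferred allele count
A_i.  Profiles are computed over the top 12 variants (more than the up-to
eight classical alleles expected per individual, leaving room for higher
copy numbers).

Amplicons whose profile shows no clear, unique inflection are classified
'poor' and excluded from genotyping, replacing the multi-evaluator visual
inspection of cumulative depth plots with an explicit threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .preprocess import VariantTable

DEFAULT_N_MAX = 12
DEFAULT_TAU = 50.0


@dataclass
class DocProfile:
    """Ranked-depth DOC profile of one amplicon.

    ``roc`` holds the per-break rate-of-change values and ``doc`` the same
    values normalised to percentages (summing to 100 when at least one
    break exists).  ``a_i`` is the rank of the maximal DOC break, i.e. the
    inferred allele count, undefined for degenerate profiles.
    """

    amplicon_id: str
    ranked: list[tuple[str, int]]
    mode: str
    cumulative: list[int] = field(default_factory=list)
    roc: list[float] = field(default_factory=list)
    doc: list[float] = field(default_factory=list)
    a_i: Optional[int] = None
    max_doc: Optional[float] = None
    tie_at_max: bool = False

    @property
    def n(self) -> int:
        return len(self.ranked)

    @property
    def total_depth(self) -> int:
        return sum(d for _, d in self.ranked)


@dataclass
class GenotypeCall:
    """Final per-amplicon call: quality class, allele count and, for good
    amplicons, the called allele sequences (depth-ranked)."""

    amplicon_id: str
    quality: str  # good | poor
    a_i: Optional[int]
    max_doc: Optional[float]
    alleles: tuple[str, ...] = ()

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)


def doc_profile(
    entry: Mapping[str, int],
    amplicon_id: str = "",
    n_max: int = DEFAULT_N_MAX,
    mode: str = "adjacent_ratio",
) -> DocProfile:
    """Compute the DOC profile of one amplicon entry.

    Depths are ranked descending (ties broken lexicographically) and
    truncated to ``n_max`` observed variants; no zero-depth padding is
    applied.  In ``adjacent_ratio`` mode ROC_i = d_i/d_{i+1} for
    i = 1..n-1 and DOC_i = 100 * ROC_i / sum(ROC).  In ``cumulative_roc``
    mode ROC_i = c_i/c_{i-1} over running sums and DOC is the normalised
    absolute successive ROC difference.  Both are scale invariant and sum
    to 100 whenever any break exists.
    """
    ranked = sorted(entry.items(), key=lambda kv: (-kv[1], kv[0]))[:n_max]
    if any(d <= 0 for _, d in ranked):
        raise ValueError("depths must be positive")
    prof = DocProfile(amplicon_id, ranked, mode)
    depths = [d for _, d in ranked]
    prof.cumulative = list(np.cumsum(depths).astype(int))
    n = len(depths)
    if n < 2:
        return prof

    if mode == "adjacent_ratio":
        roc = [depths[i] / depths[i + 1] for i in range(n - 1)]
        doc = list(100.0 * np.asarray(roc) / sum(roc))
        break_ranks = list(range(1, n))
    elif mode == "cumulative_roc":
        c = prof.cumulative
        roc = [c[i] / c[i - 1] for i in range(1, n)]
        if len(roc) < 2:
            prof.roc = roc
            prof.doc = [100.0]
            prof.a_i = 1
            prof.max_doc = 100.0
            return prof
        diffs = [abs(roc[i] - roc[i + 1]) for i in range(len(roc) - 1)]
        total = sum(diffs)
        if total == 0:
            prof.roc = roc
            prof.doc = [0.0] * len(diffs)
            prof.tie_at_max = True
            return prof
        doc = [100.0 * d / total for d in diffs]
        break_ranks = list(range(2, n))
    else:
        raise ValueError(f"unknown DOC mode {mode!r}")

    prof.roc = roc
    prof.doc = doc
    arr = np.asarray(doc)
    imax = int(arr.argmax())
    prof.max_doc = float(arr[imax])
    prof.tie_at_max = bool(np.sum(np.isclose(arr, arr[imax], rtol=0, atol=1e-12)) > 1)
    prof.a_i = break_ranks[imax]
    return prof


def call_genotype(
    profile: DocProfile,
    tau: float = DEFAULT_TAU,
    plateau_ratio: float = 2.0,
    min_plateau_depth: int = 50,
    min_allele_fraction: float = 0.05,
    n_max: int = DEFAULT_N_MAX,
) -> GenotypeCall:
    """Classify an amplicon as good/poor and extract its allele set.

    Good iff the maximal DOC reaches ``tau`` percent with a unique argmax
    *and* the variants below the inflection sit at artefact-like relative
    depths (below ``min_allele_fraction`` of the amplicon — an inflection
    whose "artefact tail" starts at allele-like depth is not a credible
    allele/artefact boundary); the allele set is then the top ``a_i``
    ranked variants.  One clean-data escape applies: when the observed
    variant list is exhausted below ``n_max``, every adjacent ratio stays
    below ``plateau_ratio``, the shallowest variant holds at least
    ``min_allele_fraction`` of the amplicon and the total depth is at
    least ``min_plateau_depth``, the profile is a pure allele plateau with
    no artefact tail and all observed variants are called (a_i = n).
    Shallow or ambiguous profiles are poor.
    """
    if profile.n < 3:
        # one variant has no break; two variants have a single break whose
        # DOC is 100 by construction — neither carries inflection evidence
        return GenotypeCall(profile.amplicon_id, "poor", None, profile.max_doc)
    total = profile.total_depth
    if (
        profile.max_doc is not None
        and profile.max_doc >= tau
        and not profile.tie_at_max
        and profile.ranked[profile.a_i][1] < min_allele_fraction * total
    ):
        a_i = profile.a_i
        alleles = tuple(seq for seq, _ in profile.ranked[:a_i])
        return GenotypeCall(profile.amplicon_id, "good", a_i, profile.max_doc, alleles)
    if (
        profile.mode == "adjacent_ratio"
        and profile.n < n_max
        and profile.roc
        and max(profile.roc) <= plateau_ratio
        and profile.ranked[-1][1] >= min_allele_fraction * profile.total_depth
        and profile.total_depth >= min_plateau_depth
    ):
        alleles = tuple(seq for seq, _ in profile.ranked)
        return GenotypeCall(
            profile.amplicon_id, "good", profile.n, profile.max_doc, alleles
        )
    return GenotypeCall(profile.amplicon_id, "poor", None, profile.max_doc)


def genotype_table(
    table: VariantTable,
    n_max: int = DEFAULT_N_MAX,
    mode: str = "adjacent_ratio",
    tau: float = DEFAULT_TAU,
    plateau_ratio: float = 2.0,
    min_plateau_depth: int = 50,
    min_allele_fraction: float = 0.05,
) -> tuple[dict[str, GenotypeCall], dict[str, DocProfile]]:
    """DOC-profile and call every amplicon of a corrected table."""
    calls: dict[str, GenotypeCall] = {}
    profiles: dict[str, DocProfile] = {}
    for amplicon_id in sorted(table.entries):
        entry = table.entries[amplicon_id]
        if not entry:
            calls[amplicon_id] = GenotypeCall(amplicon_id, "poor", None, None)
            profiles[amplicon_id] = DocProfile(amplicon_id, [], mode)
            continue
        prof = doc_profile(entry, amplicon_id, n_max, mode)
        profiles[amplicon_id] = prof
        calls[amplicon_id] = call_genotype(
            prof, tau, plateau_ratio, min_plateau_depth, min_allele_fraction, n_max
        )
    return calls, profiles


def export_curves(
    profiles: Mapping[str, DocProfile] | Iterable[DocProfile],
    out_dir: str | Path,
    plot: bool = False,
) -> list[Path]:
    """Write one cumulative-depth curve CSV per amplicon (rank, depth,
    cumulative depth, DOC at the break following the rank).  With
    ``plot=True`` a PNG of each curve is written as well (requires
    matplotlib).  An empty profile set writes nothing."""
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for prof in sorted(profiles, key=lambda p: p.amplicon_id):
        if prof.n == 0:
            continue
        path = out_dir / f"{prof.amplicon_id}_curve.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rank", "depth", "cumulative_depth", "doc_pct"])
            for i, (_, depth) in enumerate(prof.ranked):
                doc = prof.doc[i] if i < len(prof.doc) else ""
                writer.writerow([i + 1, depth, prof.cumulative[i], doc])
        written.append(path)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 3))
            ax.plot(range(1, prof.n + 1), prof.cumulative, marker="o")
            ax.set_xlabel("variant rank")
            ax.set_ylabel("cumulative depth")
            ax.set_title(prof.amplicon_id)
            fig.tight_layout()
            fig.savefig(out_dir / f"{prof.amplicon_id}_curve.png", dpi=80)
            plt.close(fig)
    return written


def write_genotypes(
    calls: Mapping[str, GenotypeCall], path: str | Path
) -> None:
    """Genotype TSV: amplicon, quality, A_i, max DOC, ;-separated alleles."""
    with open(path, "w") as fh:
        fh.write("amplicon_id\tquality\ta_i\tmax_doc\talleles\n")
        for amplicon_id in sorted(calls):
            c = calls[amplicon_id]
            fh.write(
                f"{c.amplicon_id}\t{c.quality}\t"
                f"{'' if c.a_i is None else c.a_i}\t"
                f"{'' if c.max_doc is None else f'{c.max_doc:.4f}'}\t"
                f"{';'.join(c.alleles)}\n"
            )


def read_genotypes(path: str | Path) -> dict[str, GenotypeCall]:
    calls: dict[str, GenotypeCall] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("amplicon_id"):
            raise ValueError(f"{path}: missing genotype header")
        for line in fh:
            amplicon, quality, a_i, max_doc, alleles = line.rstrip("\n").split("\t")
            calls[amplicon] = GenotypeCall(
                amplicon,
                quality,
                int(a_i) if a_i else None,
                float(max_doc) if max_doc else None,
                tuple(alleles.split(";")) if alleles else (),
            )
    return calls
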