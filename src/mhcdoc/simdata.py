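"""Synthetic tagged-amplicon sequencing runs with known ground truth.

The generator emulates the statistical structure a degree-of-change (DOC)
genotyping analysis of a highly duplicated MHC class I amplicon assumes:

* a shared pool of classical alleles (trimmed length 239-242 bp) and
  co-amplified non-classical alleles (236 bp),
* per-individual genotypes of several alleles, optionally organised into
  families with Mendelian haplotype inheritance,
* unequal per-allele amplification efficiency (lognormal weights),
* platform depth regimes (negative-binomial read counts around a mean of
  63 reads/amplicon for 454-like runs and 2818 for MiSeq-like runs),
* platform-specific artefacts: 1-2 nt substitution errors (repeatable at a
  fixed set of global sites for MiSeq), single-base homopolymer indels
  (454-biased), PCR chimeras, cross-sample contamination and one-off
  singleton errors.

Every simulated read carries a source label (true allele id or artefact
type plus parent), so downstream correction and genotyping can be scored
against the truth.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from ._util import BASES, hamming, random_sequence, revcomp, spawn_seed

#: Amplification primers for MHC class I exon 3 (forward HNalla, reverse
#: Rv3; the Y in Rv3 is a degenerate C/T position).
PRIMER_FWD = "TCCCCACAGGTCTCCACAC"
PRIMER_REV = "TGCGCTCCAGCTCCYTCTGCC"

CLASSICAL_LENGTH_RANGE = (239, 242)
NONCLASSICAL_LENGTH = 236

TAG_LENGTH = 6
READ_LENGTH = 250


# ---------------------------------------------------------------------------
# allele pool


@dataclass(frozen=True)
class Allele:
    """One true allele: an id, its trimmed insert sequence, and whether it
    belongs to the classical (239-242 bp, polymorphic, genotyped) or
    non-classical (236 bp, co-amplified, filtered out) class."""

    id: str
    sequence: str
    is_classical: bool

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(BASES):
            raise ValueError(f"allele {self.id}: sequence must be non-empty A/C/G/T")
        n = len(self.sequence)
        if self.is_classical:
            lo, hi = CLASSICAL_LENGTH_RANGE
            if not lo <= n <= hi:
                raise ValueError(f"classical allele {self.id} has length {n}")
        elif n != NONCLASSICAL_LENGTH:
            raise ValueError(f"non-classical allele {self.id} has length {n}")


@dataclass
class AllelePool:
    """Catalogue of true allele sequences.

    Classical alleles of equal length are kept at least
    ``min_pairwise_substitutions`` apart so that 1-2 nt artefact rules in
    the correction stage cannot collapse two simulated true alleles.
    """

    alleles: list[Allele]
    min_pairwise_substitutions: int = 3

    def __post_init__(self) -> None:
        ids = [a.id for a in self.alleles]
        if len(set(ids)) != len(ids):
            raise ValueError("allele ids must be unique")
        self._by_id = {a.id: a for a in self.alleles}
        for a, b in itertools.combinations(self.classical, 2):
            if len(a.sequence) == len(b.sequence):
                d = hamming(a.sequence, b.sequence)
                if d < self.min_pairwise_substitutions:
                    raise ValueError(
                        f"alleles {a.id}/{b.id} differ by {d} < "
                        f"min_pairwise_substitutions={self.min_pairwise_substitutions}"
                    )

    @property
    def classical(self) -> list[Allele]:
        return [a for a in self.alleles if a.is_classical]

    @property
    def nonclassical(self) -> list[Allele]:
        return [a for a in self.alleles if not a.is_classical]

    def __getitem__(self, allele_id: str) -> Allele:
        return self._by_id[allele_id]

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self._by_id

    def sequences(self, ids: Iterable[str]) -> list[str]:
        return [self._by_id[i].sequence for i in ids]


def make_allele_pool(
    n_classical: int,
    n_nonclassical: int = 0,
    min_pairwise_substitutions: int = 3,
    seed: int = 0,
    divergence: int = 8,
) -> AllelePool:
    """Generate an allele pool.

    Classical alleles are derived from one random ancestor per length class
    (lengths drawn from 239-242) by ``divergence`` random substitutions,
    which mimics a family of similar gene copies while a rejection step
    enforces the minimum pairwise distance among same-length alleles.

    Raises ``ValueError`` if the divergence constraint cannot be satisfied
    (too many alleles for the requested minimum distance).
    """
    if n_classical < 0 or n_nonclassical < 0:
        raise ValueError("allele counts must be non-negative")
    if min_pairwise_substitutions < 1:
        raise ValueError("min_pairwise_substitutions must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = CLASSICAL_LENGTH_RANGE
    ancestors = {n: random_sequence(rng, n) for n in range(lo, hi + 1)}
    ancestors[NONCLASSICAL_LENGTH] = random_sequence(rng, NONCLASSICAL_LENGTH)

    def mutate(base: str, k: int) -> str:
        pos = rng.choice(len(base), size=k, replace=False)
        s = list(base)
        for p in pos:
            s[p] = rng.choice([b for b in BASES if b != s[p]])
        return "".join(s)

    alleles: list[Allele] = []
    by_length: dict[int, list[str]] = {}
    for i in range(n_classical):
        length = int(rng.integers(lo, hi + 1))
        for _ in range(1000):
            seq = mutate(ancestors[length], divergence)
            if all(
                hamming(seq, other) >= min_pairwise_substitutions
                for other in by_length.get(length, [])
            ):
                break
        else:
            raise ValueError(
                f"cannot place {n_classical} classical alleles with "
                f"min_pairwise_substitutions={min_pairwise_substitutions} "
                f"at divergence={divergence}"
            )
        by_length.setdefault(length, []).append(seq)
        alleles.append(Allele(f"UA{i + 1:03d}", seq, True))
    for i in range(n_nonclassical):
        seq = mutate(ancestors[NONCLASSICAL_LENGTH], divergence)
        alleles.append(Allele(f"UN{i + 1:02d}", seq, False))
    return AllelePool(alleles, min_pairwise_substitutions)


# ---------------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class Family:
    father_id: str
    mother_id: str
    chick_ids: tuple[str, ...]


@dataclass
class PedigreeDesign:
    """Families plus per-individual haplotypes (pairs of allele-id sets).

    An individual's genotype is the union of its two haplotypes; chicks
    inherit one haplotype from each parent, so every chick allele is
    present in at least one parent (Mendelian closure).
    """

    families: list[Family]
    haplotypes: dict[str, tuple[frozenset[str], frozenset[str]]]

    def genotype(self, individual: str) -> frozenset[str]:
        h1, h2 = self.haplotypes[individual]
        return h1 | h2

    @property
    def individuals(self) -> list[str]:
        out: list[str] = []
        for fam in self.families:
            out.extend([fam.father_id, fam.mother_id, *fam.chick_ids])
        return out

    def to_rows(self) -> list[tuple[str, str, str, str]]:
        """(family, father, mother, chick) rows, one per chick."""
        rows = []
        for k, fam in enumerate(self.families, start=1):
            for chick in fam.chick_ids:
                rows.append((f"F{k:02d}", fam.father_id, fam.mother_id, chick))
        return rows


def make_pedigree(
    n_families: int,
    chicks_per_family: tuple[int, int],
    pool: AllelePool,
    haplotype_size_range: tuple[int, int] = (2, 5),
    a_i_range: tuple[int, int] = (3, 9),
    seed: int = 0,
) -> PedigreeDesign:
    """Simulate families with Mendelian haplotype inheritance.

    Each parent receives two haplotypes (sets of classical allele ids with
    sizes drawn from ``haplotype_size_range``); each chick inherits one
    haplotype from each parent, chosen uniformly.  Haplotypes are resampled
    until every individual's allele count falls within ``a_i_range``.
    """
    classical_ids = [a.id for a in pool.classical]
    h_lo, h_hi = haplotype_size_range
    if len(classical_ids) < 2 * h_hi:
        raise ValueError("pool too small for requested haplotype sizes")
    rng = np.random.default_rng(seed)

    def draw_haplotype() -> frozenset[str]:
        size = int(rng.integers(h_lo, h_hi + 1))
        return frozenset(rng.choice(classical_ids, size=size, replace=False))

    families: list[Family] = []
    haplotypes: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    a_lo, a_hi = a_i_range
    c_lo, c_hi = chicks_per_family
    for k in range(1, n_families + 1):
        father, mother = f"F{k:02d}-S", f"F{k:02d}-D"
        n_chicks = int(rng.integers(c_lo, c_hi + 1))
        chicks = tuple(f"F{k:02d}-C{j}" for j in range(1, n_chicks + 1))
        for _ in range(500):
            fh = (draw_haplotype(), draw_haplotype())
            mh = (draw_haplotype(), draw_haplotype())
            members = {father: fh, mother: mh}
            for chick in chicks:
                members[chick] = (
                    fh[int(rng.integers(2))],
                    mh[int(rng.integers(2))],
                )
            if all(a_lo <= len(h1 | h2) <= a_hi for h1, h2 in members.values()):
                haplotypes.update(members)
                families.append(Family(father, mother, chicks))
                break
        else:
            raise ValueError(
                f"cannot satisfy allele-count range {a_i_range} with "
                f"haplotype sizes {haplotype_size_range}"
            )
    return PedigreeDesign(families, haplotypes)


def sample_genotypes(
    pool: AllelePool,
    n_samples: int,
    a_i_range: tuple[int, int] = (3, 9),
    seed: int = 0,
    prefix: str = "S",
) -> dict[str, frozenset[str]]:
    """Unrelated per-sample genotypes: allele counts uniform in ``a_i_range``,
    alleles drawn without replacement from the classical pool."""
    classical_ids = [a.id for a in pool.classical]
    lo, hi = a_i_range
    if hi > len(classical_ids):
        raise ValueError("a_i_range exceeds pool size")
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(1, n_samples + 1):
        k = int(rng.integers(lo, hi + 1))
        out[f"{prefix}{i:02d}"] = frozenset(rng.choice(classical_ids, size=k, replace=False))
    return out


# ---------------------------------------------------------------------------
# error profile


@dataclass(frozen=True)
class ErrorProfile:
    """Platform error/depth regime for amplicon simulation.

    Rates are per read.  ``mean_depth``/``depth_dispersion`` parameterise a
    negative-binomial read count per amplicon (dispersion is the NB size
    parameter; larger means closer to Poisson).  ``efficiency_sd`` is the
    log-scale spread of per-allele amplification weights.  For MiSeq-like
    runs, substitution artefacts recur at a fixed global set of
    ``repeatable_substitution_positions`` (position, base) sites shared
    across amplicons; 454-like substitution errors hit random positions.
    """

    platform: str
    mean_depth: float
    depth_dispersion: float = 20.0
    substitution_artefact_rate: float = 0.03
    repeatable_substitution_positions: int = 0
    homopolymer_indel_rate: float = 0.02
    chimera_rate: float = 0.01
    contamination_rate: float = 0.005
    singleton_rate: float = 0.05
    efficiency_sd: float = 0.35
    run_min: int = 3
    base_quality: int = 37
    low_quality_fraction: float = 0.02
    low_quality_value: int = 20
    repeatable_sites: tuple[tuple[int, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("454", "miseq"):
            raise ValueError("platform must be '454' or 'miseq'")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in (
            "substitution_artefact_rate",
            "homopolymer_indel_rate",
            "chimera_rate",
            "contamination_rate",
            "singleton_rate",
            "low_quality_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def default(cls, platform: str, **overrides) -> "ErrorProfile":
        """Default regimes: ~63 reads/amplicon with homopolymer-indel-heavy
        errors for 454, ~2818 reads/amplicon with repeatable substitution
        sites for MiSeq."""
        if platform == "454":
            base = dict(
                platform="454",
                mean_depth=63.0,
                depth_dispersion=19.0,
                substitution_artefact_rate=0.03,
                repeatable_substitution_positions=0,
                homopolymer_indel_rate=0.08,
                chimera_rate=0.01,
                contamination_rate=0.01,
                singleton_rate=0.06,
            )
        elif platform == "miseq":
            base = dict(
                platform="miseq",
                mean_depth=2818.0,
                depth_dispersion=27.0,
                substitution_artefact_rate=0.05,
                repeatable_substitution_positions=10,
                homopolymer_indel_rate=0.005,
                chimera_rate=0.01,
                contamination_rate=0.005,
                singleton_rate=0.05,
            )
        else:
            raise ValueError("platform must be '454' or 'miseq'")
        base.update(overrides)
        return cls(**base)

    def noise_free(self) -> "ErrorProfile":
        """Copy with all artefact rates zeroed (clean reads only)."""
        return replace(
            self,
            substitution_artefact_rate=0.0,
            homopolymer_indel_rate=0.0,
            chimera_rate=0.0,
            contamination_rate=0.0,
            singleton_rate=0.0,
            low_quality_fraction=0.0,
        )

    def with_repeatable_sites(self, seed: int) -> "ErrorProfile":
        """Realise the global (position, base) repeatable-error sites from a
        run-level seed so all amplicons of the run share them."""
        n = self.repeatable_substitution_positions
        if n == 0:
            return replace(self, repeatable_sites=())
        rng = np.random.default_rng(seed)
        pos = rng.choice(NONCLASSICAL_LENGTH, size=n, replace=False)
        sites = tuple(
            (int(p), str(rng.choice(list(BASES)))) for p in sorted(pos)
        )
        return replace(self, repeatable_sites=sites)

    def _sites(self) -> tuple[tuple[int, str], ...]:
        if self.repeatable_sites is not None:
            return self.repeatable_sites
        # stable fallback so standalone amplicons still share one global set
        return self.with_repeatable_sites(
            20170728 + self.repeatable_substitution_positions
        ).repeatable_sites


# ---------------------------------------------------------------------------
# amplicon simulation

#: read source-label prefixes
SRC_ALLELE = "allele"
SRC_SUBSTITUTION = "substitution"
SRC_HOMOPOLYMER = "homopolymer"
SRC_CHIMERA = "chimera"
SRC_CONTAMINATION = "contamination"
SRC_SINGLETON = "singleton"

_CATEGORIES = (
    SRC_SUBSTITUTION,
    SRC_HOMOPOLYMER,
    SRC_CHIMERA,
    SRC_CONTAMINATION,
    SRC_SINGLETON,
)


@dataclass
class SimulatedAmplicon:
    """Reads of one amplicon as a multiset of (sequence, source label)."""

    sample_id: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def reads(self) -> Iterable[tuple[str, str]]:
        """Expand to one (sequence, label) per read, deterministic order."""
        for (seq, label), n in sorted(self.counts.items()):
            for _ in range(n):
                yield seq, label

    def depth_by_source(self) -> Counter:
        """Read counts per source category (label prefix)."""
        out: Counter = Counter()
        for (_, label), n in self.counts.items():
            out[label.split(":", 1)[0]] += n
        return out

    def true_variant_counts(self) -> Counter:
        """Per-sequence counts of clean (true-allele) reads only."""
        out: Counter = Counter()
        for (seq, label), n in self.counts.items():
            if label.startswith(SRC_ALLELE + ":"):
                out[seq] += n
        return out


def _homopolymer_runs(seq: str, run_min: int) -> list[tuple[int, int]]:
    """(start, length) of runs of identical bases with length >= run_min."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= run_min:
            runs.append((i, j - i))
        i = j
    return runs


def simulate_amplicon(
    genotype: Iterable[str],
    pool: AllelePool,
    profile: ErrorProfile,
    coamplified_nonclassical: Iterable[str] = (),
    seed: int = 0,
    sample_id: str = "S01",
    contaminant_ids: Sequence[str] | None = None,
) -> SimulatedAmplicon:
    """Simulate one amplicon's reads with per-read source labels.

    The read count is negative-binomial around ``profile.mean_depth``;
    clean reads are multinomial across the amplifying alleles with
    lognormal efficiency weights; artefact reads are generated per the
    profile's rates.  Deterministic given ``seed``.
    """
    genotype = sorted(set(genotype))
    coamp = sorted(set(coamplified_nonclassical))
    if not genotype:
        raise ValueError("genotype must be non-empty")
    for allele_id in (*genotype, *coamp):
        if allele_id not in pool:
            raise ValueError(f"unknown allele id {allele_id!r}")

    rng = np.random.default_rng(seed)
    amplified = [*genotype, *coamp]
    seqs = pool.sequences(amplified)
    weights = rng.lognormal(0.0, profile.efficiency_sd, size=len(amplified))
    weights /= weights.sum()

    disp = profile.depth_dispersion
    p_nb = disp / (disp + profile.mean_depth)
    n_reads = int(rng.negative_binomial(disp, p_nb))

    rates = [
        profile.substitution_artefact_rate,
        profile.homopolymer_indel_rate,
        profile.chimera_rate,
        profile.contamination_rate,
        profile.singleton_rate,
    ]
    probs = np.array([1.0 - sum(rates), *rates])
    if probs[0] < 0:
        raise ValueError("artefact rates sum to more than 1")
    cat_counts = rng.multinomial(n_reads, probs)

    amp = SimulatedAmplicon(sample_id)
    # clean reads: one multinomial across amplifying alleles
    clean_alloc = rng.multinomial(cat_counts[0], weights)
    for allele_id, seq, k in zip(amplified, seqs, clean_alloc):
        if k:
            amp.counts[(seq, f"{SRC_ALLELE}:{allele_id}")] += int(k)

    sites = profile._sites() if profile.platform == "miseq" else ()
    if contaminant_ids is None:
        contaminant_ids = [
            a.id for a in pool.classical if a.id not in set(genotype)
        ]

    def pick_parent() -> tuple[str, str]:
        i = int(rng.choice(len(amplified), p=weights))
        return amplified[i], seqs[i]

    for category, n_cat in zip(_CATEGORIES, cat_counts[1:]):
        for _ in range(int(n_cat)):
            if category == SRC_SUBSTITUTION:
                parent_id, parent_seq = pick_parent()
                n_subs = 1 if rng.random() < 0.7 else 2
                s = list(parent_seq)
                if sites:
                    usable = [
                        (p, b) for p, b in sites if p < len(s) and s[p] != b
                    ]
                    chosen = rng.choice(len(usable), size=min(n_subs, len(usable)), replace=False)
                    for c in chosen:
                        p, b = usable[int(c)]
                        s[p] = b
                else:
                    pos = rng.choice(len(s), size=n_subs, replace=False)
                    for p in pos:
                        s[p] = rng.choice([b for b in BASES if b != s[p]])
                amp.counts[("".join(s), f"{SRC_SUBSTITUTION}:{parent_id}")] += 1
            elif category == SRC_HOMOPOLYMER:
                parent_id, parent_seq = pick_parent()
                runs = _homopolymer_runs(parent_seq, profile.run_min)
                if not runs:
                    amp.counts[(parent_seq, f"{SRC_ALLELE}:{parent_id}")] += 1
                    continue
                start, length = runs[int(rng.integers(len(runs)))]
                if rng.random() < 0.5:
                    seq = parent_seq[:start] + parent_seq[start + 1 :]  # deletion
                else:
                    seq = parent_seq[:start] + parent_seq[start] + parent_seq[start:]
                amp.counts[(seq, f"{SRC_HOMOPOLYMER}:{parent_id}")] += 1
            elif category == SRC_CHIMERA:
                if len(amplified) < 2:
                    pid, pseq = pick_parent()
                    amp.counts[(pseq, f"{SRC_ALLELE}:{pid}")] += 1
                    continue
                i, j = rng.choice(len(amplified), size=2, replace=False, p=weights)
                a, b = seqs[int(i)], seqs[int(j)]
                bp = int(rng.integers(1, min(len(a), len(b))))
                amp.counts[
                    (a[:bp] + b[bp:], f"{SRC_CHIMERA}:{amplified[int(i)]}+{amplified[int(j)]}")
                ] += 1
            elif category == SRC_CONTAMINATION:
                if not contaminant_ids:
                    pid, pseq = pick_parent()
                    amp.counts[(pseq, f"{SRC_ALLELE}:{pid}")] += 1
                    continue
                cid = contaminant_ids[int(rng.integers(len(contaminant_ids)))]
                amp.counts[(pool[cid].sequence, f"{SRC_CONTAMINATION}:{cid}")] += 1
            else:  # singleton: unique random error
                parent_id, parent_seq = pick_parent()
                s = list(parent_seq)
                pos = rng.choice(len(s), size=int(rng.integers(1, 4)), replace=False)
                for p in pos:
                    s[p] = rng.choice([b for b in BASES if b != s[p]])
                amp.counts[("".join(s), f"{SRC_SINGLETON}:{parent_id}")] += 1
    return amp


# ---------------------------------------------------------------------------
# run design and emission


@dataclass
class RunDesign:
    """A sequencing run: samples (replicates appear as distinct amplicon
    ids), dual 6 bp tag assignments, primers, platform and seed."""

    samples: list[str]
    tag_assignments: dict[str, tuple[str, str]]
    platform: str
    seed: int
    primers: tuple[str, str] = (PRIMER_FWD, PRIMER_REV)

    def __post_init__(self) -> None:
        pairs = list(self.tag_assignments.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("tag pairs must be unique per sample")
        for fwd, rev in pairs:
            if len(fwd) != TAG_LENGTH or len(rev) != TAG_LENGTH:
                raise ValueError(f"tags must be {TAG_LENGTH} bp")
        missing = set(self.samples) - set(self.tag_assignments)
        if missing:
            raise ValueError(f"samples without tags: {sorted(missing)}")


def make_run_design(
    samples: Sequence[str], platform: str, seed: int
) -> RunDesign:
    """Assign a unique 6 bp forward/reverse tag pair to every sample."""
    rng = np.random.default_rng(seed)
    tags: dict[str, tuple[str, str]] = {}
    used: set[tuple[str, str]] = set()
    for s in samples:
        while True:
            pair = (random_sequence(rng, TAG_LENGTH), random_sequence(rng, TAG_LENGTH))
            if pair not in used:
                used.add(pair)
                tags[s] = pair
                break
    return RunDesign(list(samples), tags, platform, seed)


def simulate_run(
    design: RunDesign,
    pool: AllelePool,
    genotypes: Mapping[str, frozenset[str] | set[str]],
    profile: ErrorProfile,
    coamplified_nonclassical: Iterable[str] | None = None,
) -> dict[str, SimulatedAmplicon]:
    """Simulate all amplicons of a run (repeatable MiSeq error sites are
    realised once from the design seed and shared across amplicons)."""
    if coamplified_nonclassical is None:
        coamplified_nonclassical = [a.id for a in pool.nonclassical]
    profile = profile.with_repeatable_sites(spawn_seed(design.seed, 0))
    out = {}
    for i, sample in enumerate(design.samples, start=1):
        out[sample] = simulate_amplicon(
            genotypes[sample],
            pool,
            profile,
            coamplified_nonclassical,
            seed=spawn_seed(design.seed, i),
            sample_id=sample,
        )
    return out


def _concretise_primer(primer: str, rng: np.random.Generator) -> str:
    from ._util import IUPAC

    return "".join(
        b if b in BASES else str(rng.choice(list(IUPAC[b]))) for b in primer
    )


def emit_run(
    design: RunDesign,
    amplicons: Mapping[str, SimulatedAmplicon],
    out_dir: str | Path,
    profile: ErrorProfile | None = None,
) -> dict[str, Path]:
    """Write a run to disk and return the emitted file paths.

    Each read becomes the full construct ``fwd_tag + fwd_primer + insert +
    revcomp(rev_primer) + revcomp(rev_tag)``.  454-like runs emit one FASTA
    with random per-read orientation; MiSeq-like runs emit paired 250 bp
    R1/R2 FASTQ with Phred+33 qualities (constant Q37 with a configurable
    fraction of low-quality reads).  Also writes a ground-truth table
    (sample -> allele ids that emitted at least one clean read), the tag
    table and the run config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile is None:
        profile = ErrorProfile.default(design.platform)
    rng = np.random.default_rng(spawn_seed(design.seed, 999_000))
    fwd_primer, rev_primer = design.primers

    paths: dict[str, Path] = {}
    records: list[tuple[str, str]] = []  # (read id, construct)
    qual_flags: list[bool] = []
    for sample in design.samples:
        fwd_tag, rev_tag = design.tag_assignments[sample]
        for i, (insert, _label) in enumerate(amplicons[sample].reads()):
            construct = (
                fwd_tag
                + _concretise_primer(fwd_primer, rng)
                + insert
                + revcomp(_concretise_primer(rev_primer, rng))
                + revcomp(rev_tag)
            )
            records.append((f"{sample}_{i:06d}", construct))
            qual_flags.append(rng.random() < profile.low_quality_fraction)

    if design.platform == "454":
        path = out_dir / "reads_454.fasta"
        with open(path, "w") as fh:
            for rid, construct in records:
                if rng.random() < 0.5:
                    construct = revcomp(construct)
                fh.write(f">{rid}\n{construct}\n")
        paths["reads"] = path
    else:
        r1_path = out_dir / "reads_R1.fastq"
        r2_path = out_dir / "reads_R2.fastq"
        q_hi = chr(profile.base_quality + 33)
        q_lo = chr(profile.low_quality_value + 33)
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for (rid, construct), low in zip(records, qual_flags):
                r1 = construct[:READ_LENGTH]
                r2 = revcomp(construct)[:READ_LENGTH]
                # low-quality pairs are low on both mates, so the merged
                # read's mean quality falls below the Q30 filter
                q1 = (q_lo if low else q_hi) * len(r1)
                q2 = (q_lo if low else q_hi) * len(r2)
                f1.write(f"@{rid}/1\n{r1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{q2}\n")
        paths["r1"], paths["r2"] = r1_path, r2_path

    truth_path = out_dir / "ground_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tallele_id\n")
        for sample in design.samples:
            ids = sorted(
                {
                    label.split(":", 1)[1]
                    for (_, label) in amplicons[sample].counts
                    if label.startswith(SRC_ALLELE + ":")
                }
            )
            for allele_id in ids:
                fh.write(f"{sample}\t{allele_id}\n")
    paths["ground_truth"] = truth_path

    tags_path = out_dir / "tags.tsv"
    with open(tags_path, "w") as fh:
        fh.write("sample_id\tfwd_tag\trev_tag\n")
        for sample in design.samples:
            fwd_tag, rev_tag = design.tag_assignments[sample]
            fh.write(f"{sample}\t{fwd_tag}\t{rev_tag}\n")
    paths["tags"] = tags_path

    config_path = out_dir / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "platform": design.platform,
                "seed": design.seed,
                "n_samples": len(design.samples),
                "primers": {"forward": fwd_primer, "reverse": rev_primer},
                "mean_depth": profile.mean_depth,
            },
            fh,
            sort_keys=False,
        )
    paths["config"] = config_path
    return paths
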