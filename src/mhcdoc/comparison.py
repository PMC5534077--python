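"""Quantitative and qualitative comparison of genotyping runs.

Quantitative: good/poor amplicon counts per platform, success rates by
allele count, a Fisher's exact test on the good/poor 2x2 table and
Mann-Whitney U tests on read depth of good vs poor amplicons.

Qualitative: genotype concordance within replicate pairs, across
platforms for shared samples (a genotype "match" is set equality of
called allele sequences), and pedigree consistency (every chick allele
present in at least one parent's called genotype).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import GenotypeCall
from .preprocess import VariantTable


@dataclass
class AmpliconOutcome:
    """One amplicon's outcome for success summaries: good/poor plus the
    allele-count bin it is tallied under (true A_i for simulations,
    called A_i for real data)."""

    sample_id: str
    good: bool
    a_i: Optional[int] = None
    replicate: bool = False


@dataclass
class SuccessSummary:
    n_good: int
    n_total: int
    by_a_i: pd.DataFrame  # index: a_i bin; columns: n_good, n_total, pct

    @property
    def pct(self) -> float:
        return 100.0 * self.n_good / self.n_total if self.n_total else float("nan")


def success_summary(
    outcomes: Iterable[AmpliconOutcome],
    exclude_replicates: bool = True,
    bins: Sequence[int] = range(3, 10),
    pool_high: Optional[int] = None,
) -> SuccessSummary:
    """Good/poor counts plus a success-by-allele-count table.

    Bins with no amplicons are reported with an undefined (NaN) rate
    rather than dropped.  With ``pool_high`` set (e.g. 7), all bins >= the
    value are pooled into one row, as is common when high-diversity
    amplicons are scarce.
    """
    outcomes = list(outcomes)
    if exclude_replicates:
        outcomes = [o for o in outcomes if not o.replicate]
    n_good = sum(o.good for o in outcomes)

    def bin_of(a_i: Optional[int]):
        if a_i is None:
            return None
        if pool_high is not None and a_i >= pool_high:
            return pool_high
        return a_i

    labels = sorted({bin_of(b) for b in bins} - {None})
    rows = []
    for b in labels:
        members = [o for o in outcomes if bin_of(o.a_i) == b]
        good = sum(o.good for o in members)
        pct = 100.0 * good / len(members) if members else float("nan")
        label = f"{b}+" if pool_high is not None and b == pool_high else str(b)
        rows.append({"a_i": label, "n_good": good, "n_total": len(members), "pct": pct})
    table = pd.DataFrame(rows).set_index("a_i")
    return SuccessSummary(n_good, len(outcomes), table)


# ---------------------------------------------------------------------------
# statistics


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact probability for a 2x2 count table: the sum
    of hypergeometric probabilities (margins fixed) of all tables whose
    point probability does not exceed the observed one.

    Degenerate margins (an all-zero row or column) carry no information;
    p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum() == 0 or 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("degenerate margins in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first group
    z: float  # tie-corrected normal approximation with continuity correction
    p: float  # two-sided

    def __iter__(self):
        return iter((self.u, self.z, self.p))


def mann_whitney(
    good_depths: Sequence[float], poor_depths: Sequence[float]
) -> MannWhitneyResult:
    """Mann-Whitney U test via rank sums with midranks for ties.

    Z uses the tie-corrected variance and a 0.5 continuity correction;
    two identical constant groups give Z = 0, p = 1.
    """
    x = np.asarray(good_depths, dtype=float)
    y = np.asarray(poor_depths, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return MannWhitneyResult(u1, 0.0, 1.0)
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(float(u1), float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# concordance


@dataclass
class ConcordanceResult:
    pct: Optional[float]  # None when no pair/sample qualifies
    n_compared: int
    mismatches: list = field(default_factory=list)


def replicate_concordance(
    calls: Mapping[str, GenotypeCall],
    pairs: Iterable[tuple[str, str]],
) -> ConcordanceResult:
    """Genotype repeatability across replicate amplicon pairs.

    The denominator is the number of pairs whose two members are both
    'good'; a match is identity of the called allele-sequence sets.
    """
    n_both_good = 0
    n_match = 0
    mismatches = []
    for a, b in pairs:
        ca, cb = calls.get(a), calls.get(b)
        if ca is None or cb is None or ca.quality != "good" or cb.quality != "good":
            continue
        n_both_good += 1
        if ca.allele_set == cb.allele_set:
            n_match += 1
        else:
            mismatches.append((a, b, ca.a_i, cb.a_i))
    pct = 100.0 * n_match / n_both_good if n_both_good else None
    return ConcordanceResult(pct, n_both_good, mismatches)


def cross_platform_concordance(
    calls_a: Mapping[str, GenotypeCall],
    calls_b: Mapping[str, GenotypeCall],
) -> ConcordanceResult:
    """Genotype agreement between two platforms over shared samples.

    The denominator is the samples called 'good' on both platforms; each
    mismatch is reported with both inferred allele counts.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    n_both_good = 0
    n_match = 0
    mismatches = []
    for sample in shared:
        ca, cb = calls_a[sample], calls_b[sample]
        if ca.quality != "good" or cb.quality != "good":
            continue
        n_both_good += 1
        if ca.allele_set == cb.allele_set:
            n_match += 1
        else:
            mismatches.append((sample, ca.a_i, cb.a_i))
    if n_both_good == 0:
        warnings.warn("no shared samples good on both platforms", stacklevel=2)
        return ConcordanceResult(None, 0, mismatches)
    return ConcordanceResult(100.0 * n_match / n_both_good, n_both_good, mismatches)


@dataclass
class PedigreeConsistency:
    fraction: Optional[float]  # chick alleles found in >= 1 parent
    n_alleles_checked: int
    n_chicks_checked: int
    violations: list = field(default_factory=list)  # (chick, allele sequence)


def pedigree_consistency(
    calls: Mapping[str, GenotypeCall],
    pedigree_rows: Iterable[tuple[str, str, str, str]],
) -> PedigreeConsistency:
    """Fraction of called chick alleles present in at least one parent's
    called genotype, over families where both parents and the chick are
    'good'.  Rows are (family, father, mother, chick)."""
    n_checked = n_found = n_chicks = 0
    violations = []
    for _family, father, mother, chick in pedigree_rows:
        cf, cm, cc = calls.get(father), calls.get(mother), calls.get(chick)
        if any(
            c is None or c.quality != "good" for c in (cf, cm, cc)
        ):
            continue
        parental = cf.allele_set | cm.allele_set
        n_chicks += 1
        for allele in sorted(cc.allele_set):
            n_checked += 1
            if allele in parental:
                n_found += 1
            else:
                violations.append((chick, allele))
    fraction = n_found / n_checked if n_checked else None
    return PedigreeConsistency(fraction, n_checked, n_chicks, violations)


# ---------------------------------------------------------------------------
# stage summary and report


def stage_summary(table: VariantTable) -> pd.DataFrame:
    """Mean +/- standard error of reads per amplicon at each recorded
    processing stage (se = sd/sqrt(n); a single amplicon reports se = 0
    and is flagged)."""
    rows = []
    for rec in table.log:
        depths = np.array(list(rec.depth_by_amplicon.values()), dtype=float)
        n = depths.size
        se = float(depths.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "stage": rec.stage,
                "n_amplicons": n,
                "mean_reads": float(depths.mean()) if n else float("nan"),
                "se_reads": se,
                "se_defined": n > 1,
                "removed": rec.removed,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Machine-readable summary of a two-platform comparison."""

    success_a: SuccessSummary
    success_b: SuccessSummary
    fisher_p: float
    mann_whitney_a: Optional[MannWhitneyResult]
    mann_whitney_b: Optional[MannWhitneyResult]
    replicate_a: Optional[ConcordanceResult]
    replicate_b: Optional[ConcordanceResult]
    cross_platform: Optional[ConcordanceResult]
    pedigree_a: Optional[PedigreeConsistency]
    pedigree_b: Optional[PedigreeConsistency]
    platform_a: str = "a"
    platform_b: str = "b"

    def to_dict(self) -> dict:
        def conc(c):
            return None if c is None else {
                "pct": c.pct,
                "n_compared": c.n_compared,
                "mismatches": [list(m) for m in c.mismatches],
            }

        def mw(m):
            return None if m is None else {"u": m.u, "z": m.z, "p": m.p}

        def ped(p):
            return None if p is None else {
                "fraction": p.fraction,
                "n_alleles_checked": p.n_alleles_checked,
                "n_chicks_checked": p.n_chicks_checked,
                "violations": [list(v) for v in p.violations],
            }

        return {
            "platforms": [self.platform_a, self.platform_b],
            "good_poor": {
                self.platform_a: [self.success_a.n_good,
                                  self.success_a.n_total - self.success_a.n_good],
                self.platform_b: [self.success_b.n_good,
                                  self.success_b.n_total - self.success_b.n_good],
            },
            "success_pct": {
                self.platform_a: self.success_a.pct,
                self.platform_b: self.success_b.pct,
            },
            "success_by_a_i": {
                self.platform_a: self.success_a.by_a_i.reset_index().to_dict("records"),
                self.platform_b: self.success_b.by_a_i.reset_index().to_dict("records"),
            },
            "fisher_p": self.fisher_p,
            "mann_whitney": {
                self.platform_a: mw(self.mann_whitney_a),
                self.platform_b: mw(self.mann_whitney_b),
            },
            "replicate_concordance": {
                self.platform_a: conc(self.replicate_a),
                self.platform_b: conc(self.replicate_b),
            },
            "cross_platform_concordance": conc(self.cross_platform),
            "pedigree_consistency": {
                self.platform_a: ped(self.pedigree_a),
                self.platform_b: ped(self.pedigree_b),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare_platforms(
    calls_a: Mapping[str, GenotypeCall],
    calls_b: Mapping[str, GenotypeCall],
    depths_a: Mapping[str, int] | None = None,
    depths_b: Mapping[str, int] | None = None,
    replicate_pairs: Sequence[tuple[str, str]] = (),
    pedigree_rows: Sequence[tuple[str, str, str, str]] = (),
    a_i_bins: Mapping[str, int] | None = None,
    platform_a: str = "a",
    platform_b: str = "b",
) -> ComparisonReport:
    """Assemble the full quantitative + qualitative comparison report."""
    replicate_ids = {s for pair in replicate_pairs for s in pair}

    def outcomes(calls: Mapping[str, GenotypeCall]) -> list[AmpliconOutcome]:
        out = []
        for sample, call in calls.items():
            a_i = None
            if a_i_bins is not None:
                a_i = a_i_bins.get(sample)
            elif call.a_i is not None:
                a_i = call.a_i
            out.append(
                AmpliconOutcome(sample, call.quality == "good", a_i,
                                sample in replicate_ids)
            )
        return out

    succ_a = success_summary(outcomes(calls_a))
    succ_b = success_summary(outcomes(calls_b))
    fisher_p = fisher_exact_2x2(
        [
            [succ_a.n_good, succ_a.n_total - succ_a.n_good],
            [succ_b.n_good, succ_b.n_total - succ_b.n_good],
        ]
    )

    def mw(calls, depths):
        if depths is None:
            return None
        good = [depths[s] for s, c in calls.items() if c.quality == "good" and s in depths]
        poor = [depths[s] for s, c in calls.items() if c.quality == "poor" and s in depths]
        if not good or not poor:
            return None
        return mann_whitney(good, poor)

    rep_a = replicate_concordance(calls_a, replicate_pairs) if replicate_pairs else None
    rep_b = replicate_concordance(calls_b, replicate_pairs) if replicate_pairs else None
    ped_a = pedigree_consistency(calls_a, pedigree_rows) if pedigree_rows else None
    ped_b = pedigree_consistency(calls_b, pedigree_rows) if pedigree_rows else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cross = cross_platform_concordance(calls_a, calls_b)
    return ComparisonReport(
        succ_a, succ_b, fisher_p,
        mw(calls_a, depths_a), mw(calls_b, depths_b),
        rep_a, rep_b, cross, ped_a, ped_b,
        platform_a, platform_b,
    )
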