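"""Error correction: distances, platform rules, conservation, recovery."""

import numpy as np
import pytest

import mhcdoc as m
from mhcdoc.correction import top_variants, variant_distance

from conftest import amplicon_study


def _rand_seq(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# brute-force alignment oracle: minimal unit-cost edit distance plus the set
# of (substitutions, indels) splits achievable by optimal alignments


def _oracle_alignments(a, b):
    la, lb = len(a), len(b)
    dist = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dist[i][0] = i
    for j in range(lb + 1):
        dist[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = dist[i - 1][j - 1] + (a[i - 1] != b[j - 1])
            dist[i][j] = min(sub, dist[i - 1][j] + 1, dist[i][j - 1] + 1)

    splits = [[set() for _ in range(lb + 1)] for _ in range(la + 1)]
    splits[0][0] = {(0, 0)}
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == j == 0:
                continue
            out = set()
            if i and j and dist[i][j] == dist[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
                extra = int(a[i - 1] != b[j - 1])
                out |= {(s + extra, d) for s, d in splits[i - 1][j - 1]}
            if i and dist[i][j] == dist[i - 1][j] + 1:
                out |= {(s, d + 1) for s, d in splits[i - 1][j]}
            if j and dist[i][j] == dist[i][j - 1] + 1:
                out |= {(s, d + 1) for s, d in splits[i][j - 1]}
            splits[i][j] = out
    return dist[la][lb], splits[la][lb]


class TestVariantDistance:
    def test_identical(self):
        rel = variant_distance("ACGTACGT", "ACGTACGT")
        assert (rel.substitutions, rel.indels, rel.homopolymer_indel) == (0, 0, False)

    def test_single_substitution(self):
        rel = variant_distance("ACGTACGT", "ACGAACGT")
        assert (rel.substitutions, rel.indels, rel.homopolymer_indel) == (1, 0, False)

    def test_homopolymer_deletion_in_run_of_three(self):
        a = "GGCAAAGTT"
        b = "GGCAAGTT"  # one A removed from the AAA run
        rel = variant_distance(a, b, run_min=3)
        assert (rel.substitutions, rel.indels, rel.homopolymer_indel) == (0, 1, True)
        dist, splits = _oracle_alignments(a, b)
        assert dist == 1 and (0, 1) in splits

    def test_non_homopolymer_single_indel(self):
        rel = variant_distance("ACGTAC", "ACGTC", run_min=3)
        assert rel.indels == 1 and not rel.homopolymer_indel

    def test_run_min_boundary(self):
        # run of length 2 in the longer sequence: below the default run_min
        assert not variant_distance("ACGGA", "ACGA", run_min=3).homopolymer_indel
        assert variant_distance("ACGGA", "ACGA", run_min=2).homopolymer_indel

    def test_counts_match_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            a = _rand_seq(int(rng.integers(3, 12)), rng)
            b = _rand_seq(int(rng.integers(3, 12)), rng)
            rel = variant_distance(a, b)
            dist, splits = _oracle_alignments(a, b)
            assert rel.substitutions + rel.indels == dist
            assert (rel.substitutions, rel.indels) in splits


class TestTopVariants:
    def test_truncates_to_k(self):
        entry = {f"{'A' * 10}{i:03d}": i + 1 for i in range(60)}
        assert len(top_variants(entry, 50)) == 50

    def test_short_entry_returned_whole(self):
        entry = {"AAA": 3, "CCC": 1, "GGG": 2}
        assert [s for s, _ in top_variants(entry)] == ["AAA", "GGG", "CCC"]

    def test_equal_depth_ties_lexicographic(self):
        entry = {"TTT": 5, "AAA": 5, "CCC": 5}
        assert [s for s, _ in top_variants(entry)] == ["AAA", "CCC", "TTT"]


@pytest.fixture
def parent_and_variant():
    rng = np.random.default_rng(23)
    parent = _rand_seq(240, rng)
    variant = _mutate(parent, 100, {"A": "C", "C": "G", "G": "T", "T": "A"}[parent[100]])
    other = _rand_seq(240, rng)  # unrelated deep variant
    return parent, variant, other


class TestRules454:
    def test_unique_artifact_deleted_reads_to_parent(self, parent_and_variant):
        parent, variant, _ = parent_and_variant
        table = m.VariantTable({"A1": {parent: 100, variant: 10}}, "454")
        corrected, decisions = m.correct_table(table)
        assert corrected.entries["A1"] == {parent: 110}
        (d,) = [d for d in decisions if d.verdict == "artefact"]
        assert d.parent == parent and d.rule == "ratio_454"

    def test_multi_amplicon_variant_is_true_allele(self, parent_and_variant):
        parent, variant, other = parent_and_variant
        table = m.VariantTable(
            {"A1": {parent: 100, variant: 10}, "A2": {other: 50, variant: 8}},
            "454",
        )
        corrected, decisions = m.correct_table(table)
        assert corrected.entries["A1"][variant] == 10
        assert any(d.verdict == "true_allele" for d in decisions)

    def test_ratio_at_or_above_half_untouched(self, parent_and_variant):
        parent, variant, _ = parent_and_variant
        for depth in (60, 50):  # "less than 50%" is strict
            table = m.VariantTable({"A1": {parent: 100, variant: depth}}, "454")
            corrected, decisions = m.correct_table(table)
            assert corrected.entries["A1"][variant] == depth


class TestRulesMiseq:
    def test_never_always_over_half_is_artefact_everywhere(self, parent_and_variant):
        """Over 50% in one amplicon but not all, never without the parent:
        deleted in every amplicon."""
        parent, variant, _ = parent_and_variant
        table = m.VariantTable(
            {
                "A1": {parent: 100, variant: 60},
                "A2": {parent: 100, variant: 30},
            },
            "miseq",
        )
        corrected, _ = m.correct_table(table)
        assert corrected.entries["A1"] == {parent: 160}
        assert corrected.entries["A2"] == {parent: 130}

    def test_present_without_parent_is_true_allele(self, parent_and_variant):
        parent, variant, other = parent_and_variant
        table = m.VariantTable(
            {
                "A1": {parent: 100, variant: 10},
                "A2": {other: 80, variant: 12},
            },
            "miseq",
        )
        corrected, _ = m.correct_table(table)
        assert corrected.entries["A1"][variant] == 10
        assert corrected.entries["A2"][variant] == 12

    def test_always_over_half_is_true_allele(self, parent_and_variant):
        parent, variant, _ = parent_and_variant
        table = m.VariantTable(
            {
                "A1": {parent: 100, variant: 60},
                "A2": {parent: 90, variant: 55},
            },
            "miseq",
        )
        corrected, _ = m.correct_table(table)
        assert corrected.entries["A1"][variant] == 60

    def test_exactly_half_fails_always_over_test(self, parent_and_variant):
        parent, variant, _ = parent_and_variant
        table = m.VariantTable({"A1": {parent: 100, variant: 50}}, "miseq")
        corrected, _ = m.correct_table(table)
        assert corrected.entries["A1"] == {parent: 150}


class TestHomopolymerRule:
    @pytest.fixture
    def homopolymer_pair(self):
        rng = np.random.default_rng(29)
        # parent of length 240 containing an AAA run; variant deletes one A
        parent = _rand_seq(117, rng) + "CAAAG" + _rand_seq(118, rng)
        variant = parent[:118] + parent[119:]
        assert len(parent) == 240 and len(variant) == 239
        return parent, variant

    def test_lower_depth_never_without_parent_deleted(self, homopolymer_pair):
        parent, variant = homopolymer_pair
        for platform in ("454", "miseq"):
            table = m.VariantTable(
                {"A1": {parent: 80, variant: 20}, "A2": {parent: 60, variant: 15}},
                platform,
            )
            corrected, decisions = m.correct_table(table)
            assert corrected.entries["A1"] == {parent: 100}
            assert all(
                d.rule == "homopolymer" for d in decisions if d.verdict == "artefact"
            )

    def test_occurs_without_parent_kept(self, homopolymer_pair):
        parent, variant = homopolymer_pair
        rng = np.random.default_rng(31)
        other = _rand_seq(240, rng)
        table = m.VariantTable(
            {"A1": {parent: 80, variant: 20}, "A2": {other: 60, variant: 15}},
            "454",
        )
        corrected, _ = m.correct_table(table)
        assert corrected.entries["A1"][variant] == 20


class TestCorrectTable:
    def test_no_qualifying_pairs_identity(self):
        rng = np.random.default_rng(37)
        a, b = _rand_seq(240, rng), _rand_seq(240, rng)
        table = m.VariantTable({"A1": {a: 50, b: 30}}, "454")
        corrected, decisions = m.correct_table(table)
        assert corrected.entries == table.entries
        assert not [d for d in decisions if d.verdict == "artefact"]

    def test_private_variant_not_deleted_for_privacy_alone(self):
        rng = np.random.default_rng(41)
        a = _rand_seq(240, rng)
        b = _rand_seq(240, rng)  # unrelated, private, shallow
        table = m.VariantTable(
            {"A1": {a: 500, b: 2}, "A2": {a: 400}},
            "miseq",
        )
        corrected, _ = m.correct_table(table)
        assert corrected.entries["A1"][b] == 2

    def test_read_conservation_on_simulated_amplicons(self, pool):
        """Correction moves reads between variants but never destroys
        them: per-amplicon totals are invariant (200 amplicons)."""
        genotypes = m.sample_genotypes(pool, 200, (3, 6), seed=43)
        profile = m.ErrorProfile.default("miseq", mean_depth=500.0)
        _, table, corrected, _, _ = amplicon_study(
            pool, genotypes, "miseq", 44, profile
        )
        for amplicon in table.entries:
            assert corrected.total_depth(amplicon) == table.total_depth(amplicon)

    def test_parent_cluster_depth_conserved(self, parent_and_variant):
        parent, variant, _ = parent_and_variant
        table = m.VariantTable({"A1": {parent: 100, variant: 10}}, "454")
        corrected, decisions = m.correct_table(table)
        moved = sum(
            10 for d in decisions if d.verdict == "artefact" and d.parent == parent
        )
        assert corrected.entries["A1"][parent] == 100 + moved

    def test_artifact_reads_reassigned_to_true_parents(self, pool, nonclassical_ids):
        """On MiSeq-like simulations, at least 95% of substitution-artefact
        reads that survive the singleton filter end up folded into the
        allele they actually arose from."""
        genotypes = m.sample_genotypes(pool, 20, (3, 6), seed=7)
        profile = m.ErrorProfile.default("miseq")
        amplicons, table, corrected, decisions, _ = amplicon_study(
            pool, genotypes, "miseq", 13, profile
        )
        decision_map = {(d.amplicon, d.variant): d for d in decisions}
        total = reassigned = 0
        for sample in genotypes:
            for (seq, label), n in amplicons[sample].counts.items():
                if not label.startswith("substitution:"):
                    continue
                if seq not in table.entries[sample]:
                    continue  # removed as a singleton upstream of correction
                total += n
                true_parent_seq = pool[label.split(":")[1]].sequence
                d = decision_map.get((sample, seq))
                if d is not None and d.verdict == "artefact" and d.parent == true_parent_seq:
                    reassigned += n
        assert total > 100
        assert reassigned / total >= 0.95

    def test_processing_order_rarely_matters(self, pool):
        """Genotypes from amplicon-id order vs reversed order agree on at
        least 99% of amplicons."""
        genotypes = m.sample_genotypes(pool, 50, (3, 6), seed=47)
        profile = m.ErrorProfile.default("miseq", mean_depth=800.0)
        design = m.make_run_design(sorted(genotypes), "miseq", 48)
        amplicons = m.simulate_run(design, pool, genotypes, profile)
        from mhcdoc.preprocess import drop_singletons, length_filter

        table = m.length_filter(
            m.drop_singletons(m.table_from_simulated(amplicons, "miseq"))
        )
        fwd, _ = m.correct_table(table)
        rev, _ = m.correct_table(table, amplicon_order=sorted(table.entries, reverse=True))
        same = sum(fwd.entries[a] == rev.entries[a] for a in table.entries)
        assert same / len(table.entries) >= 0.99

    def test_no_self_parenting(self, pool):
        genotypes = m.sample_genotypes(pool, 10, (3, 6), seed=53)
        _, _, _, decisions, _ = amplicon_study(pool, genotypes, "miseq", 54)
        for d in decisions:
            if d.verdict == "artefact":
                assert d.parent is not None and d.parent != d.variant
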