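"""Simulator: allele pools, pedigrees, amplicon reads, run emission."""

import itertools
from collections import Counter

import numpy as np
import pytest

import mhcdoc as m
from mhcdoc._util import hamming, revcomp
from mhcdoc.simdata import (
    CLASSICAL_LENGTH_RANGE,
    NONCLASSICAL_LENGTH,
    PRIMER_FWD,
    PRIMER_REV,
)

from conftest import truth_sequences


class TestAllelePool:
    def test_single_allele(self):
        pool = m.make_allele_pool(1, 0, 3, seed=7)
        (allele,) = pool.alleles
        lo, hi = CLASSICAL_LENGTH_RANGE
        assert lo <= len(allele.sequence) <= hi
        assert allele.is_classical

    def test_study_scale_pool(self, pool):
        assert len(pool.classical) == 21
        assert len(pool.nonclassical) == 4
        assert all(
            len(a.sequence) == NONCLASSICAL_LENGTH for a in pool.nonclassical
        )
        assert len({a.id for a in pool.alleles}) == 25

    def test_minimum_pairwise_distance_bruteforce(self):
        pool = m.make_allele_pool(10, 0, min_pairwise_substitutions=4, seed=3)
        for a, b in itertools.combinations(pool.classical, 2):
            if len(a.sequence) == len(b.sequence):
                assert hamming(a.sequence, b.sequence) >= 4

    def test_deterministic_given_seed(self):
        p1 = m.make_allele_pool(6, 2, 3, seed=11)
        p2 = m.make_allele_pool(6, 2, 3, seed=11)
        assert [(a.id, a.sequence) for a in p1.alleles] == [
            (a.id, a.sequence) for a in p2.alleles
        ]

    def test_impossible_divergence_constraint_raises(self):
        # two mutants 2 substitutions off a common ancestor are at most 4
        # apart, so a minimum distance of 5 is unsatisfiable once a length
        # class holds two alleles (5 alleles across 4 length classes)
        with pytest.raises(ValueError, match="min_pairwise_substitutions"):
            m.make_allele_pool(5, 0, min_pairwise_substitutions=5, seed=0,
                               divergence=2)


class TestPedigree:
    def test_mendelian_closure_and_allele_range(self, pool):
        ped = m.make_pedigree(
            11, (3, 6), pool, haplotype_size_range=(2, 5), a_i_range=(3, 9),
            seed=5,
        )
        assert len(ped.families) == 11
        for fam in ped.families:
            parents = ped.genotype(fam.father_id) | ped.genotype(fam.mother_id)
            for chick in fam.chick_ids:
                h1, h2 = ped.haplotypes[chick]
                assert h1 in ped.haplotypes[fam.father_id]
                assert h2 in ped.haplotypes[fam.mother_id]
                assert ped.genotype(chick) <= parents
        for ind in ped.individuals:
            assert 3 <= len(ped.genotype(ind)) <= 9

    def test_chick_union_sizes_bounded_by_haplotypes(self, pool):
        ped = m.make_pedigree(
            2, (4, 4), pool, haplotype_size_range=(2, 2), a_i_range=(2, 4),
            seed=9,
        )
        for fam in ped.families:
            for chick in fam.chick_ids:
                assert 2 <= len(ped.genotype(chick)) <= 4

    def test_unsatisfiable_allele_range_raises(self, pool):
        with pytest.raises(ValueError, match="cannot satisfy"):
            m.make_pedigree(
                1, (3, 3), pool, haplotype_size_range=(2, 2),
                a_i_range=(9, 9), seed=0,
            )


class TestSimulateAmplicon:
    def test_noise_free_reads_are_exact_allele_copies(self, pool, nonclassical_ids):
        profile = m.ErrorProfile.default("miseq", mean_depth=100.0).noise_free()
        genotype = {a.id for a in pool.classical[:4]}
        amp = m.simulate_amplicon(genotype, pool, profile, nonclassical_ids, seed=2)
        allowed = truth_sequences(pool, genotype) | truth_sequences(
            pool, nonclassical_ids
        )
        for (seq, label), _n in amp.counts.items():
            assert label.startswith("allele:")
            assert seq in allowed

    def test_miseq_depth_calibration(self, pool, nonclassical_ids):
        profile = m.ErrorProfile.default("miseq")
        genotype = {a.id for a in pool.classical[:5]}
        depths = np.array(
            [
                m.simulate_amplicon(
                    genotype, pool, profile, nonclassical_ids, seed=100 + i
                ).total_reads
                for i in range(50)
            ],
            dtype=float,
        )
        se = depths.std(ddof=1) / np.sqrt(depths.size)
        assert abs(depths.mean() - 2818.0) < 3 * se

    def test_artefact_fraction_binomial_calibration(self, pool):
        """Realized substitution-artefact read fraction converges to the
        configured per-read rate (99% binomial interval)."""
        profile = m.ErrorProfile.default(
            "miseq",
            mean_depth=1000.0,
            substitution_artefact_rate=0.1,
            homopolymer_indel_rate=0.0,
            chimera_rate=0.0,
            contamination_rate=0.0,
            singleton_rate=0.0,
        )
        genotype = {a.id for a in pool.classical[:4]}
        total = artefact = 0
        for i in range(200):
            amp = m.simulate_amplicon(genotype, pool, profile, (), seed=i)
            by_source = amp.depth_by_source()
            total += amp.total_reads
            artefact += by_source.get("substitution", 0)
        half_width = 2.576 * np.sqrt(0.1 * 0.9 / total)
        assert abs(artefact / total - 0.1) < half_width

    def test_source_label_conservation(self, pool, nonclassical_ids):
        amp = m.simulate_amplicon(
            {a.id for a in pool.classical[:6]},
            pool,
            m.ErrorProfile.default("454"),
            nonclassical_ids,
            seed=4,
        )
        assert sum(amp.depth_by_source().values()) == amp.total_reads

    def test_deterministic_and_seed_sensitive(self, pool, nonclassical_ids):
        genotype = {a.id for a in pool.classical[:3]}
        profile = m.ErrorProfile.default("454")
        a = m.simulate_amplicon(genotype, pool, profile, nonclassical_ids, seed=8)
        b = m.simulate_amplicon(genotype, pool, profile, nonclassical_ids, seed=8)
        c = m.simulate_amplicon(genotype, pool, profile, nonclassical_ids, seed=9)
        assert a.counts == b.counts
        assert a.counts != c.counts

    def test_empty_genotype_rejected(self, pool):
        with pytest.raises(ValueError):
            m.simulate_amplicon(set(), pool, m.ErrorProfile.default("454"), ())


class TestEmitRun:
    def test_454_construct_layout(self, pool, tmp_path):
        genotype = {pool.classical[0].id}
        profile = m.ErrorProfile.default("454", mean_depth=2.0).noise_free()
        design = m.make_run_design(["S01"], "454", seed=3)
        amplicons = {
            "S01": m.simulate_amplicon(genotype, pool, profile, (), seed=1)
        }
        paths = m.emit_run(design, amplicons, tmp_path, profile)
        fwd_tag, rev_tag = design.tag_assignments["S01"]
        records = [
            line.strip()
            for line in paths["reads"].read_text().splitlines()
            if not line.startswith(">")
        ]
        assert records
        for seq in records:
            oriented = seq if seq.startswith(fwd_tag) else revcomp(seq)
            assert oriented.startswith(fwd_tag)
            assert oriented.endswith(revcomp(rev_tag))
            assert oriented[6 : 6 + len(PRIMER_FWD)] == PRIMER_FWD

    def test_miseq_pairs_overlap_at_least_100(self, pool, tmp_path):
        # insert <= 242 bp means the 250 bp mates overlap by >= 206 bp
        genotype = {a.id for a in pool.classical[:3]}
        profile = m.ErrorProfile.default("miseq", mean_depth=30.0).noise_free()
        design = m.make_run_design(["S01"], "miseq", seed=5)
        amplicons = {
            "S01": m.simulate_amplicon(genotype, pool, profile, (), seed=1)
        }
        paths = m.emit_run(design, amplicons, tmp_path, profile)
        from mhcdoc.preprocess import read_fastq

        for r1, r2 in zip(read_fastq(paths["r1"]), read_fastq(paths["r2"])):
            construct_len = None
            merged = m.merge_pairs(r1, r2, min_overlap=100)
            assert merged is not None
            construct_len = len(merged.sequence)
            assert 500 - construct_len >= 100

    @pytest.mark.parametrize("platform", ["454", "miseq"])
    def test_round_trip_noise_free(self, pool, nonclassical_ids, tmp_path, platform):
        """Emitting a noise-free run and preprocessing it recovers exactly
        the emitted allele sequences in every amplicon."""
        profile = m.ErrorProfile.default(platform, mean_depth=120.0).noise_free()
        genotypes = m.sample_genotypes(pool, 3, (3, 5), seed=21)
        design = m.make_run_design(sorted(genotypes), platform, seed=22)
        amplicons = m.simulate_run(design, pool, genotypes, profile)
        paths = m.emit_run(design, amplicons, tmp_path / platform, profile)
        reads = paths.get("reads") or (paths["r1"], paths["r2"])
        table = m.preprocess_run(platform, reads, paths["tags"])
        for sample, genotype in genotypes.items():
            emitted = {
                seq
                for (seq, label) in amplicons[sample].counts
                if label.startswith("allele:") and len(seq) >= 239
            }
            assert set(table.entries[sample]) == emitted
            # classical alleles all present (depth 120 leaves no singletons)
            assert truth_sequences(pool, genotype) <= emitted

    def test_emission_deterministic(self, pool, tmp_path):
        genotypes = m.sample_genotypes(pool, 2, (3, 4), seed=1)
        design = m.make_run_design(sorted(genotypes), "454", seed=2)
        profile = m.ErrorProfile.default("454")
        outs = []
        for sub in ("a", "b"):
            amplicons = m.simulate_run(design, pool, genotypes, profile)
            paths = m.emit_run(design, amplicons, tmp_path / sub, profile)
            outs.append(paths["reads"].read_bytes())
        assert outs[0] == outs[1]

    def test_ground_truth_table_lists_sample_alleles(self, pool, tmp_path):
        genotypes = m.sample_genotypes(pool, 2, (3, 4), seed=6)
        design = m.make_run_design(sorted(genotypes), "454", seed=7)
        profile = m.ErrorProfile.default("454", mean_depth=200.0).noise_free()
        amplicons = m.simulate_run(design, pool, genotypes, profile)
        paths = m.emit_run(design, amplicons, tmp_path, profile)
        rows = paths["ground_truth"].read_text().splitlines()[1:]
        listed = Counter(row.split("\t")[0] for row in rows)
        for sample, genotype in genotypes.items():
            # with nonclassical co-amplification, >= the classical alleles
            assert listed[sample] >= len(genotype)


def test_duplicate_tag_pairs_rejected():
    with pytest.raises(ValueError, match="unique"):
        m.RunDesign(
            ["S01", "S02"],
            {"S01": ("AAAAAA", "CCCCCC"), "S02": ("AAAAAA", "CCCCCC")},
            "454",
            seed=0,
        )
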