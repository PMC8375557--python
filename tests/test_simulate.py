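"""Synthetic population generator: determinism, truth consistency, read model."""

import math
import re

import numpy as np
import pytest

from twobrad.digest import BSAXI, iupac_regex, revcomp
from twobrad.simulate import (
    SimConfig,
    simulate_individuals,
    simulate_population,
    simulate_reads,
    simulate_reference,
    write_fasta,
)

SMALL = dict(genome_length=25_000, n_autosomal_tags=50, n_gametolog_snps=5,
             n_autosomal_snps=10)


class TestConfig:
    def test_rejects_invalid_values(self):
        with pytest.raises(ValueError):
            SimConfig(error_rate=0.5)
        with pytest.raises(ValueError):
            SimConfig(n_females=-1)
        with pytest.raises(ValueError):
            SimConfig(system="WZ")
        with pytest.raises(ValueError):
            SimConfig(genome_length=1_000)  # cannot host 200 tags

    def test_none_system_cannot_carry_sex_limited_tags(self):
        with pytest.raises(ValueError):
            SimConfig(system="NONE", n_sex_limited_tags=3)


class TestReference:
    def test_null_system_has_no_sex_limited_contig(self):
        cfg = SimConfig(**{**SMALL, "seed": 1, "system": "NONE",
                           "n_sex_limited_tags": 0, "n_gametolog_snps": 0})
        ref, truth = simulate_reference(cfg)
        assert set(ref) == {"chr1"}
        assert truth.sex_limited_tag_ids == set()
        assert truth.gametolog_snp_ids == set()

    def test_fixed_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = SimConfig(seed=1, **SMALL)
        for run in ("a", "b"):
            ref, _ = simulate_reference(cfg)
            write_fasta(ref, tmp_path / f"{run}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_planted_motifs_equal_independent_regex_scan(self):
        cfg = SimConfig(seed=2, genome_length=100_000, n_autosomal_snps=50)
        ref, truth = simulate_reference(cfg)
        pat = re.compile(f"(?=({iupac_regex(BSAXI.motif)}))")
        n_found = 0
        for seq in ref.values():
            n_found += sum(1 for _ in pat.finditer(seq))
            n_found += sum(1 for _ in pat.finditer(revcomp(seq)))
        assert n_found == len(truth.planted_site_coordinates)

    def test_truth_coordinates_extract_motif_matching_cores(self):
        cfg = SimConfig(seed=4, **SMALL)
        ref, truth = simulate_reference(cfg)
        pat = re.compile(iupac_regex(BSAXI.motif))
        for contig, start, _strand in truth.planted_site_coordinates:
            core = ref[contig][start:start + 27]
            assert pat.match(core[9:]), core

    def test_capacity_error_when_tags_cannot_be_placed(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, genome_length=2_000, n_autosomal_tags=200)


class TestIndividuals:
    @pytest.mark.parametrize("system,het_sex,hom_sex", [("ZW", "F", "M"), ("XY", "M", "F")])
    def test_gametolog_snps_heterozygous_only_in_heterogametic_sex(
        self, system, het_sex, hom_sex
    ):
        cfg = SimConfig(seed=5, system=system, **SMALL)
        ref, truth = simulate_reference(cfg)
        genomes = simulate_individuals(cfg, ref, truth)
        for snp in truth.gametolog_snps.values():
            for ind, sex in truth.sex_by_individual.items():
                alleles = set(genomes[ind][snp.tag_id])
                if sex == het_sex:
                    assert len(alleles) == 2
                else:
                    assert len(alleles) == 1

    def test_sex_limited_tags_present_only_in_heterogametic_sex(self):
        cfg = SimConfig(seed=5, **SMALL)
        ref, truth = simulate_reference(cfg)
        genomes = simulate_individuals(cfg, ref, truth)
        for tag_id in truth.sex_limited_tag_ids:
            for ind, sex in truth.sex_by_individual.items():
                assert (tag_id in genomes[ind]) == (sex == "F")

    def test_autosomal_heterozygote_fraction_matches_hardy_weinberg(self):
        # 20 individuals x 500 SNP-bearing tags = 10,000 genotypes at p=0.5
        cfg = SimConfig(seed=6, genome_length=25_000, n_autosomal_tags=520,
                        n_gametolog_snps=0, n_autosomal_snps=500,
                        n_sex_limited_tags=0, system="NONE", allele_freq=0.5)
        ref, truth = simulate_reference(cfg)
        genomes = simulate_individuals(cfg, ref, truth)
        n = n_het = 0
        for snp in truth.autosomal_snps.values():
            for ind in truth.sex_by_individual:
                a = genomes[ind][snp.tag_id]
                n += 1
                n_het += len(set(a)) == 2
        se = math.sqrt(0.5 * 0.5 / n)
        assert abs(n_het / n - 0.5) < 3 * se


class TestReads:
    def test_error_free_homozygous_tag_yields_identical_reads(self):
        cfg = SimConfig(seed=7, error_rate=0.0, coverage_mean=30.0, **SMALL)
        ref, truth = simulate_reference(cfg)
        genomes = simulate_individuals(cfg, ref, truth)
        reads = simulate_reads(cfg, genomes, truth)
        # pick a tag with no planted SNP; collect its reads via the window
        snp_tags = {s.tag_id for s in truth.snp_by_tag().values()}
        tag_id = next(t for t in sorted(truth.tag_core)
                      if t not in snp_tags and t not in truth.sex_limited_tag_ids)
        window = truth.tag_window[tag_id]
        for ind in list(reads)[:2]:
            matching = [r for r, _ in reads[ind] if r in (window, revcomp(window))]
            assert len(matching) > 0
            assert all(r in (window, revcomp(window)) for r in matching)

    def test_total_reads_close_to_poisson_expectation(self):
        cfg = SimConfig(seed=8, error_rate=0.0, coverage_mean=20.0, **SMALL)
        ref, truth = simulate_reference(cfg)
        genomes = simulate_individuals(cfg, ref, truth)
        reads = simulate_reads(cfg, genomes, truth)
        for ind, rr in reads.items():
            n_copies = sum(len(v) for v in genomes[ind].values())
            lam = n_copies * cfg.coverage_mean
            assert abs(len(rr) - lam) < 4 * math.sqrt(lam)

    def test_observed_mismatch_rate_matches_error_rate(self):
        cfg = SimConfig(seed=9, error_rate=0.01, coverage_mean=30.0, **SMALL)
        ref, truth = simulate_reference(cfg)
        genomes = simulate_individuals(cfg, ref, truth)
        reads = simulate_reads(cfg, genomes, truth)
        # non-SNP autosomal tags: expected read is the reference window
        snp_tags = {s.tag_id for s in truth.snp_by_tag().values()}
        windows = {}
        for t, w in truth.tag_window.items():
            if t not in snp_tags and t not in truth.sex_limited_tag_ids:
                windows[w] = w
                windows[revcomp(w)] = w
        n_bases = n_mismatch = 0
        for ind in list(reads)[:2]:
            for r, _ in reads[ind]:
                best = min(windows, key=lambda w: sum(a != b for a, b in zip(r, w)),
                           default=None)
                d = sum(a != b for a, b in zip(r, best))
                if d <= 4:  # reads from these tags only
                    n_bases += len(r)
                    n_mismatch += d
        rate = n_mismatch / n_bases
        se = math.sqrt(0.01 * 0.99 / n_bases)
        assert abs(rate - 0.01) < 3 * se

    def test_reads_deterministic_per_seed(self):
        cfg = SimConfig(seed=10, **SMALL)
        r1 = simulate_population(cfg)[3]
        r2 = simulate_population(cfg)[3]
        assert r1 == r2
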