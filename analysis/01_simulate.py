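"""Simulate the 2b-RAD study population.

Generates the default ZW design — 10 females + 10 males, a 100 kb
genome hosting 200 autosomal tag loci, a W contig with 3 female-limited
tags, 10 gametolog SNPs, 50 autosomal SNPs, 30x coverage, 1% per-base
error — and writes the reference, reads and truth tables. Bulky
sequence files go to scratch/, small tables to results/.
"""

from pathlib import Path

from twobrad.simulate import (
    SimConfig,
    simulate_population,
    write_fasta,
    write_fastq,
    write_planted_bed,
    write_sample_sheet,
    write_truth_tables,
)

SEED = 42

def main():
    cfg = SimConfig(seed=SEED, coverage_mean=30.0, error_rate=0.01)
    reference, truth, genomes, reads = simulate_population(cfg)

    scratch = Path("scratch/sim")
    results = Path("results/sim")
    (scratch / "fastq").mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)

    write_fasta(reference, scratch / "reference.fa")
    for ind, rr in reads.items():
        write_fastq(rr, ind, scratch / "fastq" / f"{ind}.fastq")
    write_sample_sheet(truth, results / "samples.tsv")
    write_planted_bed(truth, results / "planted_sites.bed")
    write_truth_tables(truth, results)

    n_reads = sum(len(r) for r in reads.values())
    print(f"simulated {len(truth.sex_by_individual)} individuals "
          f"({sum(s == 'F' for s in truth.sex_by_individual.values())} F / "
          f"{sum(s == 'M' for s in truth.sex_by_individual.values())} M)")
    print(f"planted {len(truth.tag_core)} tag loci "
          f"({len(truth.sex_limited_tag_ids)} W-limited), "
          f"{len(truth.gametolog_snps)} gametolog + "
          f"{len(truth.autosomal_snps)} autosomal SNPs")
    print(f"emitted {n_reads:,} reads -> {scratch}")

if __name__ == "__main__":
    main()
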