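"""Synthetic 2b-RAD populations with known truth.

Generates a small diploid population under a chosen sex-determination
system (ZW, XY, or NONE), a reference carrying planted BsaXI tag loci,
and per-individual 33-nt reads, together with complete truth tables so
every downstream stage (digestion, QC, genotyping, screening) can be
validated without any external download.

The simulated design mirrors a 2b-RAD sex-marker study: a homogametic
pair of "autosomes" (one contig standing in for the autosomes plus the
shared Z), a sex-limited contig (W for ZW, Y for XY) carrying extra
tags present only in the heterogametic sex, gametolog SNPs at which the
heterogametic sex is constitutively heterozygous (diverged Z/W copies),
autosomal SNPs segregating under Hardy-Weinberg, Poisson per-tag-copy
coverage and iid per-base substitution errors. Reads are 33 nt: 3-nt
terminal pad + 27-nt core + 3-nt pad, emitted from a random strand.

Additionally provides genome-survey style whole-genome shotgun reads
(uniform coverage, optional diploid heterozygosity) for the k-mer
survey stage, emulating the separate short-read sequencing such studies
perform because RAD tags alone cannot support a genome-size estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .digest import BSAXI, RecognitionSpec, revcomp, scan_motif

BASES = "ACGT"
_TAG_SPACING = 40  # min distance between planted core starts
_EDGE_PAD = 10


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic 2b-RAD study.

    Defaults follow the emulated study design: 10 females + 10 males,
    ~37x mean tag depth, 33-nt reads with a 27-nt core, a 100 kb genome
    hosting ~200 tag loci.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_females: int = 10
    n_males: int = 10
    system: str = "ZW"  # ZW | XY | NONE
    n_sex_limited_tags: int = 3
    n_gametolog_snps: int = 10
    n_autosomal_tags: int = 200
    n_autosomal_snps: int = 50
    allele_freq: float = 0.5
    coverage_mean: float = 37.0
    error_rate: float = 0.001
    read_length: int = 33
    core_length: int = 27

    def __post_init__(self) -> None:
        counts = (
            self.n_females, self.n_males, self.n_sex_limited_tags,
            self.n_gametolog_snps, self.n_autosomal_tags, self.n_autosomal_snps,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must be in (0, 1)")
        if self.core_length > self.read_length:
            raise ValueError("core_length must not exceed read_length")
        if self.system not in ("ZW", "XY", "NONE"):
            raise ValueError("system must be ZW, XY or NONE")
        if self.n_gametolog_snps + self.n_autosomal_snps > self.n_autosomal_tags:
            raise ValueError("not enough autosomal tags to host requested SNPs")
        needed = _EDGE_PAD * 2 + self.n_autosomal_tags * _TAG_SPACING + 33
        if self.genome_length < needed:
            raise ValueError(
                f"genome_length={self.genome_length} too small for "
                f"{self.n_autosomal_tags} tags (need >= {needed})"
            )
        if self.system == "NONE" and self.n_sex_limited_tags:
            raise ValueError("system=NONE cannot carry sex-limited tags")


@dataclass(frozen=True)
class PlantedSnp:
    snp_id: str
    tag_id: str
    core_offset: int  # 0-based within the 27-nt core
    ref_base: str
    alt_base: str
    het_sex: str | None  # 'F'/'M' for gametologs, None for autosomal


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    sex_by_individual: dict[str, str] = field(default_factory=dict)
    sex_limited_tag_ids: set[str] = field(default_factory=set)
    gametolog_snps: dict[str, PlantedSnp] = field(default_factory=dict)
    autosomal_snps: dict[str, PlantedSnp] = field(default_factory=dict)
    planted_site_coordinates: list[tuple[str, int, str]] = field(default_factory=list)
    # internal bookkeeping used by the read simulator
    tag_core: dict[str, str] = field(default_factory=dict)
    tag_window: dict[str, str] = field(default_factory=dict)  # 33-nt read window
    tag_contig: dict[str, tuple[str, int]] = field(default_factory=dict)

    @property
    def gametolog_snp_ids(self) -> set[str]:
        return set(self.gametolog_snps)

    @property
    def autosomal_snp_ids(self) -> set[str]:
        return set(self.autosomal_snps)

    def snp_by_tag(self) -> dict[str, PlantedSnp]:
        out = {}
        for s in list(self.gametolog_snps.values()) + list(self.autosomal_snps.values()):
            out[s.tag_id] = s
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _motif_positions(seq: str, spec: RecognitionSpec) -> list[tuple[int, str]]:
    """All motif occurrences (motif_start, strand), core-fit not required."""
    import re

    from .digest import iupac_regex

    fwd = re.compile(f"(?=({iupac_regex(spec.motif)}))")
    hits = [(m.start(), "+") for m in fwd.finditer(seq)]
    rc = revcomp(seq)
    L, mlen = len(seq), len(spec.motif)
    hits += [(L - (m.start() + mlen), "-") for m in fwd.finditer(rc)]
    return hits


def random_motif_free_sequence(
    length: int, rng: np.random.Generator, spec: RecognitionSpec = BSAXI
) -> str:
    """Random ACGT sequence with every motif occurrence scrubbed out."""
    seq = list(_random_seq(rng, length))
    for _ in range(100):
        hits = _motif_positions("".join(seq), spec)
        if not hits:
            return "".join(seq)
        for p, strand in hits:
            # motif span in forward coordinates
            start = p if strand == "+" else p
            j = int(start + rng.integers(0, len(spec.motif)))
            seq[j] = BASES[int(rng.integers(0, 4))]
    raise RuntimeError("failed to scrub motifs from random sequence")


def _random_core(rng: np.random.Generator, spec: RecognitionSpec) -> str:
    """Random core carrying the motif's fixed bases: N9 + AC + N5 + CTCC + N7."""
    motif = "".join(
        ch if ch in "ACGT" else BASES[int(rng.integers(0, 4))] for ch in spec.motif
    )
    return (
        _random_seq(rng, spec.left_core) + motif + _random_seq(rng, spec.right_core)
    )


def _plant_tags(
    rng: np.random.Generator,
    length: int,
    n_tags: int,
    spec: RecognitionSpec,
) -> tuple[str, list[int]]:
    """Motif-free background with *n_tags* non-overlapping planted cores.

    Returns the contig sequence and the sorted core start positions. The
    only motif occurrences in the result are the planted ones; accidental
    matches (junction artifacts, matches arising inside a core's random
    positions, minus-strand matches) are scrubbed or re-drawn.
    """
    core_len = spec.core_length
    usable = length - 2 * _EDGE_PAD - core_len
    if n_tags and usable < (n_tags - 1) * _TAG_SPACING:
        raise ValueError("cannot place requested tags without overlap")
    seq = list(random_motif_free_sequence(length, rng, spec))
    if n_tags == 0:
        return "".join(seq), []
    # sample sorted starts with a minimum gap via the spacing transform
    slack = usable - (n_tags - 1) * _TAG_SPACING
    offsets = np.sort(rng.choice(slack + 1, size=n_tags, replace=True))
    starts = [
        int(_EDGE_PAD + off + i * _TAG_SPACING) for i, off in enumerate(offsets)
    ]
    core_spans = []
    for s in starts:
        seq[s : s + core_len] = _random_core(rng, spec)
        core_spans.append((s, s + core_len))
    expected = {(s + spec.left_core, "+") for s in starts}

    def in_core(pos: int) -> int | None:
        for i, (a, b) in enumerate(core_spans):
            if a <= pos < b:
                return i
        return None

    for _ in range(200):
        hits = set(_motif_positions("".join(seq), spec))
        stray = hits - expected
        if not stray:
            return "".join(seq), starts
        for p, strand in stray:
            span = range(p, p + len(spec.motif))
            core_idx = next((in_core(j) for j in span if in_core(j) is not None), None)
            if core_idx is not None:
                a, _b = core_spans[core_idx]
                seq[a : a + core_len] = _random_core(rng, spec)
            else:
                free = [j for j in span if in_core(j) is None and 0 <= j < length]
                j = int(rng.choice(free))
                seq[j] = BASES[int(rng.integers(0, 4))]
    raise RuntimeError("failed to converge on a clean planted reference")


def simulate_reference(
    config: SimConfig, spec: RecognitionSpec = BSAXI
) -> tuple[dict[str, str], SimTruth]:
    """Build the reference contigs and the truth skeleton.

    Returns ({contig: sequence}, truth). The autosome/Z stand-in contig
    is ``chr1``; the sex-limited contig (``W`` or ``Y``) exists only in
    heterogametic-sex individuals and is empty under system=NONE.
    Deterministic for a fixed config.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_ref, _, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    truth = SimTruth()
    for i in range(config.n_females):
        truth.sex_by_individual[f"F{i + 1:02d}"] = "F"
    for i in range(config.n_males):
        truth.sex_by_individual[f"M{i + 1:02d}"] = "M"

    chr1, starts = _plant_tags(rng_ref, config.genome_length, config.n_autosomal_tags, spec)
    contigs = {"chr1": chr1}

    auto_ids = []
    for i, s in enumerate(starts):
        tag_id = f"chr1_tag_{i:04d}"
        auto_ids.append(tag_id)
        truth.planted_site_coordinates.append(("chr1", s, "+"))
        truth.tag_core[tag_id] = chr1[s : s + spec.core_length]
        truth.tag_window[tag_id] = chr1[s - spec.left_read : s + spec.core_length + spec.right_read]
        truth.tag_contig[tag_id] = ("chr1", s)

    if config.system != "NONE":
        sex_contig = "W" if config.system == "ZW" else "Y"
        w_len = max(2_000, _EDGE_PAD * 2 + config.n_sex_limited_tags * _TAG_SPACING + 200)
        w_seq, w_starts = _plant_tags(rng_ref, w_len, config.n_sex_limited_tags, spec)
        contigs[sex_contig] = w_seq
        for i, s in enumerate(w_starts):
            tag_id = f"{sex_contig}_tag_{i:04d}"
            truth.sex_limited_tag_ids.add(tag_id)
            truth.planted_site_coordinates.append((sex_contig, s, "+"))
            truth.tag_core[tag_id] = w_seq[s : s + spec.core_length]
            truth.tag_window[tag_id] = w_seq[s - spec.left_read : s + spec.core_length + spec.right_read]
            truth.tag_contig[tag_id] = (sex_contig, s)

    # choose disjoint SNP-bearing tags among the autosomal/Z tags;
    # SNPs sit at degenerate core positions so both alleles keep the motif
    variable = [
        i for i, ch in enumerate(
            "N" * spec.left_core + spec.motif + "N" * spec.right_core
        ) if ch == "N"
    ]
    het_sex = {"ZW": "F", "XY": "M", "NONE": None}[config.system]
    n_gam = config.n_gametolog_snps if config.system != "NONE" else 0
    chosen = rng_ref.choice(
        len(auto_ids), size=n_gam + config.n_autosomal_snps, replace=False
    )
    for j, idx in enumerate(chosen):
        tag_id = auto_ids[int(idx)]
        off = int(rng_ref.choice(variable))
        ref_base = truth.tag_core[tag_id][off]
        alt_base = rng_ref.choice([b for b in BASES if b != ref_base])
        if j < n_gam:
            snp = PlantedSnp(f"gam_snp_{j:03d}", tag_id, off, ref_base, str(alt_base), het_sex)
            truth.gametolog_snps[snp.snp_id] = snp
        else:
            k = j - n_gam
            snp = PlantedSnp(f"auto_snp_{k:03d}", tag_id, off, ref_base, str(alt_base), None)
            truth.autosomal_snps[snp.snp_id] = snp
    return contigs, truth


def _apply_snp(core: str, off: int, base: str) -> str:
    return core[:off] + base + core[off + 1 :]


def simulate_individuals(
    config: SimConfig, reference: dict[str, str], truth: SimTruth
) -> dict[str, dict[str, tuple[str, ...]]]:
    """Diploid genotypes: individual -> {tag_id: per-copy core alleles}.

    Autosomal tags carry two copies; sex-limited tags one copy in the
    heterogametic sex and none in the homogametic sex. Heterogametic
    individuals are heterozygous ref/alt at every gametolog SNP;
    autosomal SNP genotypes are drawn under Hardy-Weinberg at the
    configured allele frequency.
    """
    ss = np.random.SeedSequence(config.seed)
    _, rng_ind, _ = [np.random.default_rng(s) for s in ss.spawn(3)]
    het_sex = {"ZW": "F", "XY": "M", "NONE": None}[config.system]
    snp_by_tag = truth.snp_by_tag()

    genomes: dict[str, dict[str, tuple[str, ...]]] = {}
    for ind in sorted(truth.sex_by_individual):
        sex = truth.sex_by_individual[ind]
        tags: dict[str, tuple[str, ...]] = {}
        for tag_id, core in truth.tag_core.items():
            if tag_id in truth.sex_limited_tag_ids:
                if sex == het_sex:
                    tags[tag_id] = (core,)
                continue
            snp = snp_by_tag.get(tag_id)
            if snp is None:
                tags[tag_id] = (core, core)
            elif snp.het_sex is not None:  # gametolog
                if sex == snp.het_sex:
                    tags[tag_id] = (core, _apply_snp(core, snp.core_offset, snp.alt_base))
                else:
                    tags[tag_id] = (core, core)
            else:  # autosomal SNP, HWE
                alleles = tuple(
                    _apply_snp(core, snp.core_offset, snp.alt_base)
                    if rng_ind.random() < config.allele_freq else core
                    for _ in range(2)
                )
                tags[tag_id] = alleles
        genomes[ind] = tags
    return genomes


def simulate_reads(
    config: SimConfig,
    genomes: dict[str, dict[str, tuple[str, ...]]],
    truth: SimTruth,
    spec: RecognitionSpec = BSAXI,
    no_motif_fraction: float = 0.0,
    low_quality_fraction: float = 0.0,
) -> dict[str, list[tuple[str, str]]]:
    """Per-individual reads as (sequence, quality) pairs.

    For each tag copy a Poisson(coverage_mean) number of 33-nt reads is
    emitted: the reference read window with the copy's core allele
    substituted, iid substitution errors at ``error_rate``, and a random
    emission strand. Qualities are constant 'I' (Phred+33 Q40).

    ``no_motif_fraction`` / ``low_quality_fraction`` replace that share
    of reads with motif-free sequence or all-'#' (Q2) qualities, to give
    the QC filters something to reject.
    """
    ss = np.random.SeedSequence(config.seed)
    _, _, rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    L = config.read_length
    qual_hi = "I" * L
    qual_lo = "#" * L
    reads_by_ind: dict[str, list[tuple[str, str]]] = {}
    for ind in sorted(genomes):
        out: list[tuple[str, str]] = []
        for tag_id in sorted(genomes[ind]):
            window = truth.tag_window[tag_id]
            for core_allele in genomes[ind][tag_id]:
                read_tmpl = (
                    window[: spec.left_read]
                    + core_allele
                    + window[spec.left_read + spec.core_length :]
                )
                n = int(rng.poisson(config.coverage_mean))
                for _ in range(n):
                    read = read_tmpl
                    if config.error_rate > 0:
                        nerr = int(rng.binomial(L, config.error_rate))
                        if nerr:
                            pos = rng.choice(L, size=nerr, replace=False)
                            b = list(read)
                            for p in pos:
                                b[int(p)] = BASES[
                                    (BASES.index(b[int(p)]) + int(rng.integers(1, 4))) % 4
                                ]
                            read = "".join(b)
                    if rng.random() < 0.5:
                        read = revcomp(read)
                    qual = qual_hi
                    if no_motif_fraction and rng.random() < no_motif_fraction:
                        read = random_motif_free_sequence(L, rng, spec)
                    if low_quality_fraction and rng.random() < low_quality_fraction:
                        qual = qual_lo
                    out.append((read, qual))
        reads_by_ind[ind] = out
    return reads_by_ind


def simulate_population(
    config: SimConfig,
    spec: RecognitionSpec = BSAXI,
    **read_kwargs,
):
    """Convenience wrapper: reference + genotypes + reads in one call."""
    reference, truth = simulate_reference(config, spec)
    genomes = simulate_individuals(config, reference, truth)
    reads = simulate_reads(config, genomes, truth, spec, **read_kwargs)
    return reference, truth, genomes, reads


# ---------------------------------------------------------------------------
# genome-survey style shotgun reads (for the k-mer survey stage)

def make_diploid_haplotypes(
    sequence: str, het_rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """A diploid pair: the input and a copy mutated at iid rate *het_rate*."""
    other = list(sequence)
    n = int(rng.binomial(len(sequence), het_rate))
    pos = rng.choice(len(sequence), size=n, replace=False)
    for p in pos:
        p = int(p)
        other[p] = BASES[(BASES.index(other[p]) + int(rng.integers(1, 4))) % 4]
    return sequence, "".join(other)


def simulate_survey_reads(
    haplotypes: list[str] | tuple[str, ...],
    coverage: float,
    rng: np.random.Generator,
    read_length: int = 100,
    error_rate: float = 0.0,
) -> list[str]:
    """Uniform-coverage WGS reads, *coverage* x over each haplotype."""
    reads: list[str] = []
    for hap in haplotypes:
        n_reads = int(round(coverage * len(hap) / read_length))
        starts = rng.integers(0, len(hap) - read_length + 1, size=n_reads)
        for s in starts:
            read = hap[int(s) : int(s) + read_length]
            if error_rate > 0:
                nerr = int(rng.binomial(read_length, error_rate))
                if nerr:
                    b = list(read)
                    for p in rng.choice(read_length, size=nerr, replace=False):
                        b[int(p)] = BASES[
                            (BASES.index(b[int(p)]) + int(rng.integers(1, 4))) % 4
                        ]
                    read = "".join(b)
            reads.append(read)
    return reads


# ---------------------------------------------------------------------------
# writers

def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[tuple[str, str]], ind: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            fh.write(f"@{ind}_read_{i}\n{seq}\n+\n{qual}\n")


def write_sample_sheet(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tsex\n")
        for ind in sorted(truth.sex_by_individual):
            fh.write(f"{ind}\t{truth.sex_by_individual[ind]}\n")


def write_planted_bed(truth: SimTruth, path: str | Path, core_length: int = 27) -> None:
    with open(path, "w") as fh:
        for contig, start, strand in truth.planted_site_coordinates:
            fh.write(f"{contig}\t{start}\t{start + core_length}\t"
                     f"{contig}:{start}\t0\t{strand}\n")


def write_truth_tables(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "truth_tags.tsv", "w") as fh:
        fh.write("tag_id\tcontig\tcore_start\tsex_limited\tcore_sequence\n")
        for tag_id in sorted(truth.tag_core):
            contig, start = truth.tag_contig[tag_id]
            fh.write(f"{tag_id}\t{contig}\t{start}\t"
                     f"{int(tag_id in truth.sex_limited_tag_ids)}\t"
                     f"{truth.tag_core[tag_id]}\n")
    with open(outdir / "truth_snps.tsv", "w") as fh:
        fh.write("snp_id\ttag_id\tcore_offset\tref\talt\thet_sex\n")
        for snps in (truth.gametolog_snps, truth.autosomal_snps):
            for snp_id in sorted(snps):
                s = snps[snp_id]
                fh.write(f"{s.snp_id}\t{s.tag_id}\t{s.core_offset}\t"
                         f"{s.ref_base}\t{s.alt_base}\t{s.het_sex or '.'}\n")


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**data)
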