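"""Locus clustering and depth-threshold genotyping of 2b-RAD tags.

Clean canonical 27-nt cores from all individuals are clustered into tag
loci: identical sequences collapse first, then each remaining sequence
joins the most abundant existing locus whose consensus is within
``max_mismatch`` substitutions (descending-abundance, lexicographic
tie-break — deterministic and permutation-invariant). Genotypes are
called by depth thresholds rather than a likelihood model, which is
adequate at typical 2b-RAD depths (~37x) and fully deterministic: a
locus with fewer than ``min_locus_depth`` reads in an individual is
absent (the published rule precludes sequences with fewer than three
reads); a second allele is called only with >= ``min_allele_depth``
reads and a minor fraction above ``max_hom_minor_fraction``.

SNP positions are reported 1-based in emitted tables (matching the
field's convention for the 27-nt tag), 0-based internally.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class TagLocus:
    locus_id: str
    consensus: str
    alleles: list[str] = field(default_factory=list)
    depth_by_individual_allele: dict[str, Counter] = field(default_factory=dict)
    multi_allelic: bool = False

    def total_depth(self, individual: str) -> int:
        return sum(self.depth_by_individual_allele.get(individual, Counter()).values())

    def allele_totals(self) -> Counter:
        tot: Counter = Counter()
        for c in self.depth_by_individual_allele.values():
            tot.update(c)
        return tot


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    individual: str
    call: str  # 'absent' | 'hom' | 'het'
    alleles: tuple[str, ...]  # () for absent, (a,) for hom, (a, b) for het
    total_depth: int
    allele_depths: tuple[int, ...]

    def genotype_string(self, snp_offset: int) -> str:
        """Render as base/base at a core offset, e.g. 'A/G'."""
        if self.call == "absent":
            return "./."
        if self.call == "hom":
            b = self.alleles[0][snp_offset]
            return f"{b}/{b}"
        a, b = (al[snp_offset] for al in self.alleles)
        return f"{a}/{b}"


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_catalog(
    cores_by_individual: dict[str, Counter],
    max_mismatch: int = 2,
) -> list[TagLocus]:
    """Cluster canonical cores across individuals into tag loci.

    Sequences are processed in descending total-abundance order
    (lexicographic tie-break). A sequence joins the first existing locus
    (in the same order) whose consensus is within ``max_mismatch`` in
    either orientation — a single substitution can flip which strand of
    a tag is lexicographically minimal, so allelic variants of one locus
    may arrive in opposite canonical orientations; such alleles are
    stored re-oriented to the consensus frame. A sequence matching no
    locus founds a new one. Every read is attributed to exactly one
    locus.
    """
    from .digest import revcomp

    totals: Counter = Counter()
    for counter in cores_by_individual.values():
        totals.update(counter)
    ordered = sorted(totals, key=lambda s: (-totals[s], s))

    loci: list[TagLocus] = []
    assignment: dict[str, tuple[TagLocus, str]] = {}
    for seq in ordered:
        home = None
        oriented = seq
        rc = revcomp(seq)
        for locus in loci:
            if hamming(seq, locus.consensus) <= max_mismatch:
                home, oriented = locus, seq
                break
            if hamming(rc, locus.consensus) <= max_mismatch:
                home, oriented = locus, rc
                break
        if home is None:
            home = TagLocus(locus_id="", consensus=seq)
            loci.append(home)
        if oriented not in home.alleles:
            home.alleles.append(oriented)
        assignment[seq] = (home, oriented)
    for i, locus in enumerate(loci):
        locus.locus_id = f"locus_{i:06d}"
    for ind, counter in sorted(cores_by_individual.items()):
        for seq, depth in counter.items():
            locus, oriented = assignment[seq]
            locus.depth_by_individual_allele.setdefault(ind, Counter())[oriented] += depth
    return loci


def genotype(
    locus: TagLocus,
    individual: str,
    min_locus_depth: int = 3,
    min_allele_depth: int = 2,
    max_hom_minor_fraction: float = 0.1,
) -> GenotypeCall:
    """Depth-threshold genotype call for one individual at one locus."""
    depths = locus.depth_by_individual_allele.get(individual, Counter())
    total = sum(depths.values())
    if total < min_locus_depth:
        return GenotypeCall(locus.locus_id, individual, "absent", (), total, ())
    ranked = sorted(depths.items(), key=lambda kv: (-kv[1], kv[0]))
    major, d_major = ranked[0]
    if len(ranked) > 1:
        minor, d_minor = ranked[1]
        if d_minor >= min_allele_depth and d_minor / total > max_hom_minor_fraction:
            return GenotypeCall(
                locus.locus_id, individual, "het",
                (major, minor), total, (d_major, d_minor),
            )
    return GenotypeCall(locus.locus_id, individual, "hom", (major,), total, (d_major,))


def genotype_all(
    catalog: list[TagLocus],
    individuals: list[str],
    min_locus_depth: int = 3,
    min_allele_depth: int = 2,
    max_hom_minor_fraction: float = 0.1,
) -> dict[str, dict[str, GenotypeCall]]:
    """locus_id -> individual -> GenotypeCall for every pair."""
    calls: dict[str, dict[str, GenotypeCall]] = {}
    for locus in catalog:
        calls[locus.locus_id] = {
            ind: genotype(locus, ind, min_locus_depth, min_allele_depth,
                          max_hom_minor_fraction)
            for ind in individuals
        }
    return calls


def _differing_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def call_snps(
    catalog: list[TagLocus],
    calls: dict[str, dict[str, GenotypeCall]],
) -> pd.DataFrame:
    """Biallelic SNP table from genotype calls.

    Only alleles supported by at least one genotype call (hom or het)
    define the SNP; unsupported sequencing-error alleles are ignored.
    Loci whose called alleles number more than two are flagged
    multi-allelic and excluded. The reference base is the major (highest
    total depth) allele's base; emitted positions are 1-based.
    """
    rows = []
    for locus in catalog:
        locus_calls = calls.get(locus.locus_id, {})
        called_alleles: set[str] = set()
        for c in locus_calls.values():
            called_alleles.update(c.alleles)
        if len(called_alleles) < 2:
            continue
        if len(called_alleles) > 2:
            locus.multi_allelic = True
            continue
        totals = locus.allele_totals()
        ref, alt = sorted(called_alleles, key=lambda s: (-totals[s], s))
        diff = _differing_positions(ref, alt)
        for off in diff:
            row = {
                "ref_id": locus.locus_id,
                "snp_position": off + 1,
                "ref_base": ref[off],
                "alt_base": alt[off],
            }
            for ind, c in sorted(locus_calls.items()):
                row[ind] = c.genotype_string(off)
            rows.append(row)
    cols = ["ref_id", "snp_position", "ref_base", "alt_base"]
    if rows:
        inds = [k for k in rows[0] if k not in cols]
        return pd.DataFrame(rows, columns=cols + inds)
    return pd.DataFrame(columns=cols)


def write_catalog_tsv(catalog: list[TagLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tconsensus\tn_alleles\ttotal_depth\tmulti_allelic\n")
        for locus in catalog:
            fh.write(
                f"{locus.locus_id}\t{locus.consensus}\t{len(locus.alleles)}\t"
                f"{sum(locus.allele_totals().values())}\t{int(locus.multi_allelic)}\n"
            )


def depth_matrix(catalog: list[TagLocus], individuals: list[str]) -> pd.DataFrame:
    """Loci x individuals total-depth table."""
    data = {
        ind: [locus.total_depth(ind) for locus in catalog] for ind in individuals
    }
    return pd.DataFrame(data, index=[locus.locus_id for locus in catalog])


def parse_genotype(s: str) -> tuple[str, str] | None:
    """Parse 'A/G' -> ('A', 'G'); './.' -> None."""
    a, _, b = s.partition("/")
    if a in (".", "") or b in (".", ""):
        return None
    if a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"malformed genotype string: {s!r}")
    return a, b
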