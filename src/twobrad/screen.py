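"""Sex-specific tag detection, SNP-sex association and heterogamety calls.

The central inference of a 2b-RAD sex-marker screen:

* **Sex-specific tags** — a tag locus present (depth >= 3) in all
  individuals of one sex and absent from every individual of the other
  is a candidate sex-limited (W- or Y-linked) marker. Each tag carries a
  two-sided Fisher exact p-value from its presence 2x2 table; at 10 vs
  10 the perfect split gives p = 2/184756 ~ 1.08e-5.
* **SNP-sex association** — each biallelic SNP is tested for
  heterozygote excess in one sex (het/hom x female/male Fisher exact),
  because gametolog SNPs on diverged Z/W (or X/Y) copies make the
  heterogametic sex constitutively heterozygous. Candidates are ranked
  by ascending p, as a screen, with Bonferroni and Benjamini-Hochberg
  columns reported alongside.
* **Heterogamety call** — ZW when female-side evidence (female-specific
  tags, female-het SNP patterns) strictly dominates, XY for the mirror,
  otherwise undetermined.

The Fisher exact test is computed with exact rational arithmetic (the
two-sided p sums hypergeometric probabilities <= the observed table's),
so candidate ranking is reproducible to the last bit at these sample
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import parse_genotype

PATTERNS = (
    "female_specific", "male_specific", "female_heterogametic",
    "male_heterogametic", "fixed_difference", "uninformative",
)


@dataclass
class PresenceMatrix:
    """Loci x individuals depth table with sex labels.

    Presence is a pure function of depth: depth >= min_locus_depth.
    """

    depth: pd.DataFrame  # rows: loci, columns: individuals
    sexes: dict[str, str]
    min_locus_depth: int = 3

    def __post_init__(self) -> None:
        missing = set(self.depth.columns) - set(self.sexes)
        if missing:
            raise ValueError(f"individuals without sex label: {sorted(missing)}")

    @property
    def presence(self) -> pd.DataFrame:
        return self.depth >= self.min_locus_depth

    def individuals(self, sex: str) -> list[str]:
        return [i for i in self.depth.columns if self.sexes[i] == sex]


@dataclass(frozen=True)
class SexAssociationResult:
    marker_id: str
    marker_type: str  # 'tag' | 'snp'
    p_value: float
    pattern: str
    counts: tuple[int, int, int, int]  # 2x2 table row-major
    candidate: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass(frozen=True)
class SystemInference:
    call: str  # 'ZW' | 'XY' | 'undetermined'
    evidence: dict = field(default_factory=dict)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities that are <= the observed table's probability (the
    standard two-sided definition). Computed with exact Fractions, so
    there is no floating-point ambiguity in the <= comparison.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum((p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs), Fraction(0))
    return float(min(total, Fraction(1)))


def find_sex_specific_tags(
    matrix: PresenceMatrix,
    min_present_fraction: float = 1.0,
    max_absent_sex_presence: int = 0,
) -> list[SexAssociationResult]:
    """Screen every tag locus for sex-limited presence.

    Strict default: present in all individuals of one sex, absent from
    every individual of the other (loosen ``min_present_fraction`` /
    ``max_absent_sex_presence`` to tolerate missing data). Results for
    all loci are returned sorted by (p, marker_id); candidates carry
    pattern female_specific / male_specific.
    """
    females = matrix.individuals("F")
    males = matrix.individuals("M")
    if not females or not males:
        raise ValueError("both sexes must be present in the sample sheet")
    pres = matrix.presence
    nf, nm = len(females), len(males)
    results = []
    for locus_id, row in pres.iterrows():
        f_pres = int(row[females].sum())
        m_pres = int(row[males].sum())
        pattern = "uninformative"
        if f_pres >= min_present_fraction * nf and m_pres <= max_absent_sex_presence:
            pattern = "female_specific"
        elif m_pres >= min_present_fraction * nm and f_pres <= max_absent_sex_presence:
            pattern = "male_specific"
        table = ((f_pres, nf - f_pres), (m_pres, nm - m_pres))
        p = fisher_exact_2x2(table)
        results.append(
            SexAssociationResult(
                marker_id=str(locus_id), marker_type="tag", p_value=p,
                pattern=pattern, counts=(f_pres, nf - f_pres, m_pres, nm - m_pres),
                candidate=pattern != "uninformative",
            )
        )
    results.sort(key=lambda r: (r.p_value, r.marker_id))
    return results


def classify_pattern(
    female_genotypes: list[tuple[str, str] | None],
    male_genotypes: list[tuple[str, str] | None],
) -> str:
    """Classify per-sex genotype configurations at a biallelic site.

    ``female_heterogametic``: every non-absent female heterozygous and
    every non-absent male homozygous for one shared allele (the Z/W
    gametolog signature); ``male_heterogametic`` is the mirror;
    ``fixed_difference``: both sexes homozygous, for different alleles.
    Anything else is uninformative. Absent calls (None) are dropped.
    """
    fem = [g for g in female_genotypes if g is not None]
    mal = [g for g in male_genotypes if g is not None]
    if not fem or not mal:
        return "uninformative"

    def all_het(gs):
        return all(a != b for a, b in gs)

    def hom_allele(gs):
        alleles = {a for g in gs for a in g}
        if len(alleles) == 1 and all(a == b for a, b in gs):
            return alleles.pop()
        return None

    f_hom = hom_allele(fem)
    m_hom = hom_allele(mal)
    if all_het(fem) and m_hom is not None:
        return "female_heterogametic"
    if all_het(mal) and f_hom is not None:
        return "male_heterogametic"
    if f_hom is not None and m_hom is not None and f_hom != m_hom:
        return "fixed_difference"
    return "uninformative"


def snp_sex_association(
    snp_table: pd.DataFrame,
    sexes: dict[str, str],
    model: str = "genotype_het_vs_hom",
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank SNPs by sex association.

    ``snp_table`` is the genotyper's output (ref_id, snp_position,
    ref_base, alt_base, one genotype column per individual). The default
    model tabulates het vs hom against sex; the ``allele_count`` model
    tabulates ref vs alt allele copies. Absent calls are dropped per
    marker; a monomorphic marker gets p = 1 and pattern uninformative.
    Output is sorted by (p, marker_id) with Bonferroni and BH columns.
    """
    if model not in ("genotype_het_vs_hom", "allele_count"):
        raise ValueError(f"unknown model {model!r}")
    inds = [c for c in snp_table.columns
            if c not in ("ref_id", "snp_position", "ref_base", "alt_base")]
    bad = [i for i in inds if i not in sexes]
    if bad:
        raise ValueError(f"individuals without sex label: {bad}")
    females = [i for i in inds if sexes[i] == "F"]
    males = [i for i in inds if sexes[i] == "M"]

    rows = []
    for _, rec in snp_table.iterrows():
        marker_id = f"{rec['ref_id']}:{rec['snp_position']}"
        fg = [parse_genotype(rec[i]) for i in females]
        mg = [parse_genotype(rec[i]) for i in males]
        fg_ok = [g for g in fg if g is not None]
        mg_ok = [g for g in mg if g is not None]
        observed = {a for g in fg_ok + mg_ok for a in g}
        if model == "genotype_het_vs_hom":
            f_het = sum(a != b for a, b in fg_ok)
            m_het = sum(a != b for a, b in mg_ok)
            table = ((f_het, len(fg_ok) - f_het), (m_het, len(mg_ok) - m_het))
        else:
            alt = str(rec["alt_base"])
            f_alt = sum((g.count(alt)) for g in fg_ok)
            m_alt = sum((g.count(alt)) for g in mg_ok)
            table = ((f_alt, 2 * len(fg_ok) - f_alt), (m_alt, 2 * len(mg_ok) - m_alt))
        if len(observed) < 2:
            p, pattern = 1.0, "uninformative"
        else:
            p = fisher_exact_2x2(table)
            pattern = classify_pattern(fg, mg)
        rows.append({
            "marker_id": marker_id,
            "ref_id": rec["ref_id"],
            "snp_position": rec["snp_position"],
            "p_value": p,
            "pattern": pattern,
            "n_female_het": table[0][0], "n_female_other": table[0][1],
            "n_male_het": table[1][0], "n_male_other": table[1][1],
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(["p_value", "marker_id"], kind="mergesort").reset_index(drop=True)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_value"] * m, 1.0)
    from statsmodels.stats.multitest import multipletests

    out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    if top_n is not None:
        out = out.head(top_n)
    return out


def infer_system(
    tag_results: list[SexAssociationResult],
    snp_results: pd.DataFrame,
    top_n: int = 10,
) -> SystemInference:
    """Call the sex-determination system from screening evidence.

    ZW requires female-specific tags to outnumber male-specific ones
    *and* female-heterogametic patterns to be at least as frequent as
    male-heterogametic among the top-N SNPs; XY is the mirror.
    """
    n_f_tags = sum(r.pattern == "female_specific" for r in tag_results)
    n_m_tags = sum(r.pattern == "male_specific" for r in tag_results)
    if snp_results is None or snp_results.empty:
        n_f_het = n_m_het = 0
    else:
        top = snp_results.head(top_n)
        n_f_het = int((top["pattern"] == "female_heterogametic").sum())
        n_m_het = int((top["pattern"] == "male_heterogametic").sum())
    evidence = {
        "female_specific_tags": n_f_tags,
        "male_specific_tags": n_m_tags,
        "female_het_snps": n_f_het,
        "male_het_snps": n_m_het,
    }
    if n_f_tags > n_m_tags and n_f_het >= n_m_het:
        call = "ZW"
    elif n_m_tags > n_f_tags and n_m_het >= n_f_het:
        call = "XY"
    else:
        call = "undetermined"
    return SystemInference(call=call, evidence=evidence)


def candidates_tsv(
    tag_results: list[SexAssociationResult],
    snp_results: pd.DataFrame,
    path: str | Path,
) -> None:
    """Combined candidates table: tags first, then ranked SNPs."""
    with open(path, "w") as fh:
        fh.write("marker_id\tmarker_type\tpattern\tp_value\tp_bonferroni\tp_bh\t"
                 "f_yes\tf_no\tm_yes\tm_no\n")
        cand = [r for r in tag_results if r.candidate]
        m = max(len(tag_results), 1)
        for r in cand:
            bonf = min(r.p_value * m, 1.0)
            fh.write(f"{r.marker_id}\ttag\t{r.pattern}\t{r.p_value:.6g}\t"
                     f"{bonf:.6g}\t.\t"
                     + "\t".join(str(x) for x in r.counts) + "\n")
        if snp_results is not None and not snp_results.empty:
            for _, rec in snp_results.iterrows():
                fh.write(
                    f"{rec['marker_id']}\tsnp\t{rec['pattern']}\t"
                    f"{rec['p_value']:.6g}\t{rec['p_bonferroni']:.6g}\t"
                    f"{rec['p_bh']:.6g}\t{rec['n_female_het']}\t{rec['n_female_other']}\t"
                    f"{rec['n_male_het']}\t{rec['n_male_other']}\n"
                )
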