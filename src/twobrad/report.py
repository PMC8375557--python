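"""Run summaries, published-table fixtures, marker assays and annotation.

Covers the bookkeeping around the screen: per-run sequencing summaries
(totals and per-sex subtotals with mean tag depth), loading of the
transcribed published tables (the 20-individual run table, the 13
candidate female-specific tags, the top-10 sex-associated SNPs), flank
extraction for marker assays, in-silico PCR concordance between genetic
and phenotypic sex, scaffold statistics (N50 etc.), and a 6-frame ORF
scan for marker-bearing scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .digest import BSAXI, RecognitionSpec, iupac_regex, revcomp
from .genotype import parse_genotype
from .screen import classify_pattern

STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# run-table summaries

def summarize_run_table(rows: pd.DataFrame) -> dict:
    """Totals and per-sex subtotals of a per-individual run table.

    Expects columns name, sex (F/M), raw_reads, raw_bases, clean_reads,
    tags, depth. Sums are exact integers; mean depth is returned
    unrounded plus a 2-dp rendering.
    """
    if rows.empty:
        raise ValueError("run table must have at least one row")
    for col in ("raw_reads", "raw_bases", "clean_reads", "tags"):
        if (rows[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    out: dict = {}
    for label, sub in (("total", rows),
                       ("female", rows[rows["sex"] == "F"]),
                       ("male", rows[rows["sex"] == "M"])):
        out[label] = {
            "raw_reads": int(sub["raw_reads"].sum()),
            "raw_bases": int(sub["raw_bases"].sum()),
            "clean_reads": int(sub["clean_reads"].sum()),
            "tags": int(sub["tags"].sum()),
            "mean_depth": float(sub["depth"].mean()) if len(sub) else float("nan"),
        }
    out["mean_depth_2dp"] = f"{out['total']['mean_depth']:.2f}"
    return out


# ---------------------------------------------------------------------------
# published-table fixtures (verbatim TSV transcriptions shipped as data)

def _fixture(name: str) -> Path:
    return resources.files("twobrad.data").joinpath(name)


def load_run_table(path: str | Path | None = None) -> pd.DataFrame:
    """The 20-individual 2b-RAD run table (10 F + 10 M)."""
    with resources.as_file(_fixture("table1.tsv")) if path is None else _noop(path) as p:
        df = pd.read_csv(p, sep="\t")
    expected = ["name", "sex", "raw_reads", "raw_bases", "clean_reads", "tags", "depth"]
    if list(df.columns) != expected:
        raise ValueError(f"run table columns must be {expected}")
    return df


class _noop:
    def __init__(self, p):
        self.p = p

    def __enter__(self):
        return self.p

    def __exit__(self, *a):
        return False


def load_candidate_tags(
    path: str | Path | None = None, spec: RecognitionSpec = BSAXI
) -> pd.DataFrame:
    """The 13 candidate female-specific 27-nt tags, validated.

    Each sequence must be 27 nt of pure ACGT and carry the recognition
    motif at the core offset (9 for BsaXI) on the forward strand.
    """
    import re

    with resources.as_file(_fixture("table3.tsv")) if path is None else _noop(path) as p:
        df = pd.read_csv(p, sep="\t")
    pat = re.compile(iupac_regex(spec.motif))
    for _, rec in df.iterrows():
        seq = rec["sequence"]
        if len(seq) != spec.core_length or any(ch not in "ACGT" for ch in seq):
            raise ValueError(f"invalid tag sequence for {rec['tag_name']}: {seq!r}")
        if not pat.match(seq[spec.left_core:]):
            raise ValueError(
                f"{rec['tag_name']}: motif absent at core offset {spec.left_core}"
            )
    return df


def load_candidate_snps(path: str | Path | None = None) -> pd.DataFrame:
    """The top-10 sex-associated SNP records, validated."""
    with resources.as_file(_fixture("table4.tsv")) if path is None else _noop(path) as p:
        df = pd.read_csv(p, sep="\t")
    for _, rec in df.iterrows():
        for col in ("female", "male"):
            if parse_genotype(rec[col]) is None:
                raise ValueError(f"unparseable genotype {rec[col]!r}")
        if not (1 <= int(rec["snp_position"]) <= 27):
            raise ValueError(f"SNP position out of range: {rec['snp_position']}")
    return df


def classify_snp_fixture(df: pd.DataFrame) -> pd.Series:
    """Apply the genotype-pattern classifier to per-sex consensus genotypes."""
    return df.apply(
        lambda rec: classify_pattern(
            [parse_genotype(rec["female"])], [parse_genotype(rec["male"])]
        ),
        axis=1,
    )


# ---------------------------------------------------------------------------
# marker assays and in-silico PCR

@dataclass(frozen=True)
class MarkerAssay:
    marker_id: str
    scaffold_id: str
    amplicon_start: int  # 0-based half-open
    amplicon_end: int
    expected_presence: dict  # sex -> 'band' | 'no_band'


def _find_tag_hits(scaffolds: dict[str, str], tag: str) -> list[tuple[str, int]]:
    hits = []
    targets = {tag, revcomp(tag)}
    for name, seq in scaffolds.items():
        for t in targets:
            start = seq.find(t)
            while start != -1:
                hits.append((name, start))
                start = seq.find(t, start + 1)
    return sorted(set(hits))


def extract_flanks(
    scaffolds: dict[str, str],
    tag_sequence: str,
    marker_id: str,
    amplicon_min: int = 100,
    amplicon_max: int = 1000,
    expected_presence: dict | None = None,
) -> MarkerAssay:
    """Design an amplicon window around a uniquely-mapping tag.

    The tag (exact 27-mer or its reverse complement) must occur exactly
    once across the scaffolds. The window of ``amplicon_max`` nt is
    centred on the tag and clipped to scaffold ends; if clipping leaves
    it shorter than ``amplicon_min`` the assay fails.
    """
    hits = _find_tag_hits(scaffolds, tag_sequence)
    if len(hits) != 1:
        raise ValueError(
            f"tag for {marker_id} has {len(hits)} hit(s); need exactly one"
        )
    scaffold_id, pos = hits[0]
    L = len(scaffolds[scaffold_id])
    center = pos + len(tag_sequence) // 2
    half = amplicon_max // 2
    start = max(0, center - half)
    end = min(L, center + half)
    if end - start < amplicon_min:
        raise ValueError(
            f"amplicon for {marker_id} is {end - start} bp < min {amplicon_min}"
        )
    return MarkerAssay(
        marker_id=marker_id,
        scaffold_id=scaffold_id,
        amplicon_start=start,
        amplicon_end=end,
        expected_presence=expected_presence or {},
    )


def insilico_pcr_concordance(
    assays: list[MarkerAssay],
    presence: pd.DataFrame,  # markers x individuals boolean
    sexes: dict[str, str],
    band_sex: str = "F",
) -> tuple[pd.DataFrame, dict]:
    """Band calls per individual vs phenotypic sex.

    For each assay the predicted band (tag present above the depth
    threshold) is compared with the sex expected to carry it
    (``band_sex``, the heterogametic sex). Returns the per-marker,
    per-individual call table and an overall summary with accuracy and
    the pooled confusion matrix.
    """
    rows = []
    confusion = {"band_expected_band": 0, "band_expected_no_band": 0,
                 "no_band_expected_band": 0, "no_band_expected_no_band": 0}
    for assay in assays:
        if assay.marker_id not in presence.index:
            raise ValueError(f"assay {assay.marker_id} missing from presence matrix")
        for ind in presence.columns:
            band = bool(presence.loc[assay.marker_id, ind])
            expected = sexes[ind] == band_sex
            rows.append({
                "marker_id": assay.marker_id, "individual": ind,
                "sex": sexes[ind], "band": band, "expected_band": expected,
                "concordant": band == expected,
            })
            key = (("band" if band else "no_band")
                   + "_expected_" + ("band" if expected else "no_band"))
            confusion[key] += 1
    table = pd.DataFrame(rows)
    n = len(table)
    summary = {
        "n_calls": n,
        "n_concordant": int(table["concordant"].sum()) if n else 0,
        "accuracy": float(table["concordant"].mean()) if n else float("nan"),
        "confusion": confusion,
    }
    return table, summary


# ---------------------------------------------------------------------------
# scaffold statistics

def scaffold_stats(lengths_or_seqs) -> dict:
    """count, max, total_length, N50 and count > 2 kb of a scaffold set.

    N50 is the length at which the cumulative sorted-descending total
    first reaches half the assembly length.
    """
    lengths = sorted(
        (len(s) if isinstance(s, str) else int(s)) for s in lengths_or_seqs
    )
    if not lengths:
        raise ValueError("need at least one scaffold")
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = lengths[-1]
    for L in reversed(lengths):
        acc += L
        if acc >= half:
            n50 = L
            break
    return {
        "count": len(lengths),
        "max": lengths[-1],
        "total_length": total,
        "n50": n50,
        "count_gt_2kb": sum(1 for L in lengths if L > 2000),
    }


# ---------------------------------------------------------------------------
# ORF scanning

def find_orfs(sequence: str, min_aa: int = 50) -> list[dict]:
    """ATG-to-stop ORFs of >= min_aa codons (excluding the stop), 6 frames.

    Every qualifying ATG is reported (overlapping/nested ORFs included).
    Coordinates are 0-based half-open on the forward strand; the span
    includes the stop codon.
    """
    seq = sequence.upper()
    L = len(seq)
    orfs: list[dict] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            starts = []
            stop_positions = []
            for i in range(frame, L - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in STOP_CODONS:
                    stop_positions.append(i)
            si = 0
            for atg in starts:
                while si < len(stop_positions) and stop_positions[si] < atg:
                    si += 1
                # nearest in-frame stop downstream of this ATG
                j = si
                if j >= len(stop_positions):
                    continue
                stop = stop_positions[j]
                n_codons = (stop - atg) // 3  # ATG..last codon before stop
                if n_codons < min_aa:
                    continue
                if strand == "+":
                    start, end = atg, stop + 3
                else:
                    start, end = L - (stop + 3), L - atg
                orfs.append({
                    "start": start, "end": end, "strand": strand,
                    "frame": frame, "aa_length": n_codons,
                })
    orfs.sort(key=lambda o: (o["start"], o["end"], o["strand"]))
    return orfs


def orfs_to_bed(orfs: list[dict], contig: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, o in enumerate(orfs):
            fh.write(f"{contig}\t{o['start']}\t{o['end']}\torf_{i}\t"
                     f"{o['aa_length']}\t{o['strand']}\n")
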