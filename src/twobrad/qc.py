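"""Raw-read filtering and trimming to the 27-nt tag core.

Filters follow the published 2b-RAD cleaning recipe: reads of the wrong
length, reads whose ambiguous-base (N) fraction exceeds 8%, poor-quality
reads, and reads without a restriction site are excluded; survivors are
trimmed to the 27-nt core with the recognition motif placed at its fixed
offset. Reads whose motif matches on the minus strand are rescued by
reverse complementation so all cores live in motif-forward orientation;
cores are then canonicalized for strand-independent identity.

The quality criterion (mean Phred >= 20 by default) is a documented
assumption: "poor-quality" has no published definition here.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .digest import BSAXI, RecognitionSpec, canonicalize, iupac_regex, revcomp

FAIL_REASONS = ("wrong_length", "n_excess", "low_quality", "no_motif", "wrong_structure")


@dataclass(frozen=True)
class QCParams:
    max_n_fraction: float = 0.08
    min_mean_quality: float = 20.0
    require_motif: bool = True
    read_length: int = 33
    core_length: int = 27

    def __post_init__(self) -> None:
        if not 0 <= self.max_n_fraction <= 1:
            raise ValueError("max_n_fraction must be in [0, 1]")
        if self.read_length < self.core_length:
            raise ValueError("read_length must be >= core_length")


@dataclass
class QCReport:
    """Per-individual accounting: raw = clean + sum(fail reasons)."""

    raw_reads: dict[str, int] = field(default_factory=dict)
    clean_reads: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, Counter] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return all(
            self.raw_reads[ind]
            == self.clean_reads.get(ind, 0) + sum(self.reasons.get(ind, Counter()).values())
            for ind in self.raw_reads
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("individual\traw_reads\tclean_reads\t" + "\t".join(FAIL_REASONS) + "\n")
            for ind in sorted(self.raw_reads):
                r = self.reasons.get(ind, Counter())
                fh.write(
                    f"{ind}\t{self.raw_reads[ind]}\t{self.clean_reads.get(ind, 0)}\t"
                    + "\t".join(str(r.get(k, 0)) for k in FAIL_REASONS) + "\n"
                )


def mean_phred(quality: str) -> float:
    if not quality:
        return 0.0
    return sum(ord(c) - 33 for c in quality) / len(quality)


def _motif_pattern(spec: RecognitionSpec) -> re.Pattern:
    return re.compile(f"(?=({iupac_regex(spec.motif)}))")


def filter_read(
    sequence: str,
    quality: str,
    params: QCParams = QCParams(),
    spec: RecognitionSpec = BSAXI,
) -> tuple[bool, str | None]:
    """Apply the QC filters in fixed order; (passed, fail_reason).

    Order: wrong_length -> n_excess (strict: fraction *exceeding* the
    threshold fails) -> low_quality (mean Phred below threshold) ->
    no_motif (no IUPAC motif match on either strand).
    """
    if len(quality) != len(sequence):
        raise ValueError("quality string length differs from sequence length")
    seq = sequence.upper()
    if len(seq) != params.read_length:
        return False, "wrong_length"
    if seq.count("N") / len(seq) > params.max_n_fraction:
        return False, "n_excess"
    if mean_phred(quality) < params.min_mean_quality:
        return False, "low_quality"
    if params.require_motif:
        pat = _motif_pattern(spec)
        if not pat.search(seq) and not pat.search(revcomp(seq)):
            return False, "no_motif"
    return True, None


def trim_to_core(
    sequence: str, spec: RecognitionSpec = BSAXI
) -> tuple[str | None, str | None]:
    """Extract the 27-nt core, motif-forward; (core, fail_reason).

    The motif must sit so that the full core window (left_core nt before
    it, right_core after) fits inside the read. A minus-strand match is
    reverse-complemented before extraction. Returns (None,
    "wrong_structure") when a motif exists but no compatible window, and
    (None, "no_motif") when no match at all.
    """
    seq = sequence.upper()
    pat = _motif_pattern(spec)
    found = False
    for oriented in (seq, revcomp(seq)):
        for m in pat.finditer(oriented):
            found = True
            start = m.start() - spec.left_core
            end = start + spec.core_length
            if start >= 0 and end <= len(oriented):
                core = oriented[start:end]
                if all(ch in "ACGT" for ch in core):
                    return core, None
    return None, ("wrong_structure" if found else "no_motif")


def run_qc(
    reads_by_individual: dict[str, list[tuple[str, str]]],
    sexes: dict[str, str],
    params: QCParams = QCParams(),
    spec: RecognitionSpec = BSAXI,
) -> tuple[dict[str, Counter], QCReport]:
    """Filter + trim every individual's reads to canonical core multisets.

    ``reads_by_individual`` maps individual -> [(sequence, quality)].
    Every individual must appear in the sample sheet (``sexes``).
    """
    missing = set(reads_by_individual) - set(sexes)
    if missing:
        raise ValueError(f"individuals absent from sample sheet: {sorted(missing)}")
    cores: dict[str, Counter] = {}
    report = QCReport()
    for ind, reads in reads_by_individual.items():
        counter: Counter = Counter()
        reasons: Counter = Counter()
        n_clean = 0
        for seq, qual in reads:
            ok, reason = filter_read(seq, qual, params, spec)
            if not ok:
                reasons[reason] += 1
                continue
            core, trim_fail = trim_to_core(seq, spec)
            if core is None:
                reasons[trim_fail] += 1
                continue
            counter[canonicalize(core)] += 1
            n_clean += 1
        cores[ind] = counter
        report.raw_reads[ind] = len(reads)
        report.clean_reads[ind] = n_clean
        report.reasons[ind] = reasons
    return cores, report


def load_fastq_dir(
    fastq_by_individual: dict[str, str | Path]
) -> dict[str, list[tuple[str, str]]]:
    """Read per-individual FASTQ files into (sequence, quality) lists."""
    out: dict[str, list[tuple[str, str]]] = {}
    for ind, path in fastq_by_individual.items():
        reads = []
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append((str(rec.seq).upper(), qual))
        out[ind] = reads
    return out


def load_sample_sheet(path: str | Path) -> dict[str, str]:
    sexes: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["individual_id", "sex"]:
            raise ValueError("sample sheet must have columns individual_id, sex")
        for line in fh:
            if not line.strip():
                continue
            ind, sex = line.rstrip("\n").split("\t")[:2]
            if sex not in ("F", "M"):
                raise ValueError(f"invalid sex {sex!r} for {ind}")
            sexes[ind] = sex
    return sexes


def write_core_fasta(cores: Counter, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (core, depth) in enumerate(sorted(cores.items())):
            fh.write(f">core_{i}_depth_{depth}\n{core}\n")
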