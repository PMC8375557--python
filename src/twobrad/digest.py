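"""In-silico type IIB restriction digestion.

Type IIB enzymes such as BsaXI cut on *both* sides of their recognition
site, excising a uniform short fragment ("tag") genome-wide. 2b-RAD
libraries are made of exactly these fragments, so the computational
equivalent of the digestion step is: scan a genome for the degenerate
recognition motif on both strands and extract the fixed-offset core
around every match.

The BsaXI tag is modelled as a 27-nt core:

    5'-[9 nt][AC][NNNNN][CTCC][7 nt]-3'

i.e. the degenerate recognition motif ``ACNNNNNCTCC`` flanked by 9 nt on
the 5' side and 7 nt on the 3' side. The enzyme's physical cut offsets
additionally leave ~3 nt of terminal sequence on each side of the core in
a sequenced 33-nt read; those terminal bases are handled by the read-QC
stage, not here. The 9+11+7 core structure is inferred from the published
female-specific tag sequences, which all carry the motif at offset 9 —
the motif and offsets are not stated anywhere as such and are documented
as an inference.

All coordinates are 0-based, half-open, BED-compatible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> str:
    """Expand an IUPAC motif into a plain regex over ACGT.

    Subject-side ``N`` never matches: every motif letter expands to a
    character class over ACGT only, so ambiguous bases in the scanned
    sequence cannot satisfy the motif.
    """
    parts = []
    for ch in motif:
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code in motif: {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class RecognitionSpec:
    """Geometry of a type IIB enzyme's recognition site and excised tag.

    ``left_core`` nt are retained 5' of the motif and ``right_core`` nt
    3' of it, so the core length is ``left_core + len(motif) +
    right_core`` (9 + 11 + 7 = 27 for BsaXI). ``left_read``/``right_read``
    are the extra terminal bases present in a raw read on each side of
    the core (3 + 27 + 3 = 33 nt reads).
    """

    enzyme_name: str = "BsaXI"
    motif: str = "ACNNNNNCTCC"
    left_core: int = 9
    right_core: int = 7
    left_read: int = 3
    right_read: int = 3

    def __post_init__(self) -> None:
        for ch in self.motif:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code in motif: {ch!r}")
        if min(self.left_core, self.right_core, self.left_read, self.right_read) < 0:
            raise ValueError("core/read offsets must be non-negative")

    @property
    def core_length(self) -> int:
        return self.left_core + len(self.motif) + self.right_core

    @property
    def read_length(self) -> int:
        return self.left_read + self.core_length + self.right_read


BSAXI = RecognitionSpec()


@dataclass(frozen=True)
class IIBSite:
    """A located type IIB tag: motif position, strand and 27-nt core."""

    contig: str
    motif_start: int
    strand: str
    core_start: int
    core_end: int
    core_sequence: str
    canonical_sequence: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not self.canonical_sequence:
            object.__setattr__(
                self, "canonical_sequence", canonicalize(self.core_sequence)
            )


def canonicalize(core_sequence: str) -> str:
    """Strand-independent tag identity: min(seq, revcomp(seq)).

    The same physical tag is sequenced from either strand; taking the
    lexicographic minimum of a core and its reverse complement gives a
    single canonical representative. Idempotent, and invariant under
    reverse complement of the input.
    """
    if len(core_sequence) != 27:
        raise ValueError(f"core must be 27 nt, got {len(core_sequence)}")
    if any(ch not in "ACGT" for ch in core_sequence):
        raise ValueError("core must contain only A/C/G/T")
    rc = revcomp(core_sequence)
    return core_sequence if core_sequence <= rc else rc


def scan_motif(
    sequence: str,
    spec: RecognitionSpec = BSAXI,
    contig: str = "seq",
) -> list[IIBSite]:
    """Locate every recognition site on both strands of *sequence*.

    A site is reported when the IUPAC motif matches and the full core
    window fits inside the sequence. Overlapping matches are all
    reported (independent enzyme sites, no greedy consumption). Cores
    containing N are skipped. If the motif-plus-flank context is
    palindromic the plus and minus strand yield the same core interval
    with identical canonical sequence; such duplicates are collapsed to
    the plus-strand site.

    Returns sites sorted by (core_start, strand).
    """
    seq = sequence.upper()
    if any(ch not in IUPAC for ch in seq):
        bad = sorted({ch for ch in seq if ch not in IUPAC})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    pat = re.compile(f"(?=({iupac_regex(spec.motif)}))")
    L = len(seq)
    mlen = len(spec.motif)
    sites: list[IIBSite] = []
    skipped_n = 0

    for m in pat.finditer(seq):
        p = m.start()
        core_start = p - spec.left_core
        core_end = core_start + spec.core_length
        if core_start < 0 or core_end > L:
            continue
        core = seq[core_start:core_end]
        if "N" in core or any(ch not in "ACGT" for ch in core):
            skipped_n += 1
            continue
        sites.append(IIBSite(contig, p, "+", core_start, core_end, core))

    rc_seq = revcomp(seq)
    for m in pat.finditer(rc_seq):
        p = m.start()
        rc_core_start = p - spec.left_core
        rc_core_end = rc_core_start + spec.core_length
        if rc_core_start < 0 or rc_core_end > L:
            continue
        core = rc_seq[rc_core_start:rc_core_end]
        if "N" in core or any(ch not in "ACGT" for ch in core):
            skipped_n += 1
            continue
        core_start = L - rc_core_end
        core_end = L - rc_core_start
        motif_start = L - (p + mlen)
        sites.append(IIBSite(contig, motif_start, "-", core_start, core_end, core))

    # collapse palindromic double-hits: same core interval + same canonical
    seen: dict[tuple[int, int, str], IIBSite] = {}
    for s in sorted(sites, key=lambda s: (s.core_start, s.strand)):
        key = (s.core_start, s.core_end, s.canonical_sequence)
        seen.setdefault(key, s)
    out = sorted(seen.values(), key=lambda s: (s.core_start, s.strand))
    if skipped_n:
        import logging

        logging.getLogger(__name__).info(
            "scan_motif: skipped %d site(s) with N in core on %s", skipped_n, contig
        )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_tag_catalog(
    reference: str | Path | dict[str, str],
    spec: RecognitionSpec = BSAXI,
) -> list[IIBSite]:
    """Digest a whole reference: one IIBSite per located tag.

    *reference* may be a FASTA path or an in-memory {contig: seq} dict.
    An empty reference yields an empty catalog (warning, not an error).
    """
    if isinstance(reference, (str, Path)):
        contigs = read_fasta(reference)
    else:
        contigs = reference
    if not contigs:
        import warnings

        warnings.warn("empty reference: tag catalog is empty")
        return []
    catalog: list[IIBSite] = []
    for name, seq in contigs.items():
        catalog.extend(scan_motif(seq, spec, contig=name))
    catalog.sort(key=lambda s: (s.contig, s.core_start, s.strand))
    return catalog


def write_catalog_bed(catalog: Iterable[IIBSite], path: str | Path) -> None:
    """6-column BED (0-based half-open; strand in column 6) of core intervals."""
    with open(path, "w") as fh:
        for s in catalog:
            fh.write(
                f"{s.contig}\t{s.core_start}\t{s.core_end}\t"
                f"{s.contig}:{s.core_start}-{s.core_end}:{s.strand}\t0\t{s.strand}\n"
            )


def write_catalog_fasta(catalog: Iterable[IIBSite], path: str | Path) -> None:
    """FASTA of 27-nt cores; headers encode contig:start-end:strand."""
    with open(path, "w") as fh:
        for s in catalog:
            fh.write(f">{s.contig}:{s.core_start}-{s.core_end}:{s.strand}\n")
            fh.write(s.core_sequence + "\n")


def write_catalog_tsv(catalog: Iterable[IIBSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tcore_start\tcore_end\tstrand\tmotif_start\t"
                 "core_sequence\tcanonical_sequence\n")
        for s in catalog:
            fh.write(
                f"{s.contig}\t{s.core_start}\t{s.core_end}\t{s.strand}\t"
                f"{s.motif_start}\t{s.core_sequence}\t{s.canonical_sequence}\n"
            )


def iter_sites_brute_force(
    sequence: str, spec: RecognitionSpec = BSAXI
) -> Iterator[tuple[int, str]]:
    """Positions (motif_start, strand) by naive per-position IUPAC set test.

    Exists as a transparent cross-check for the regex scanner; O(L·m).
    """
    seq = sequence.upper()

    def matches(s: str, at: int) -> bool:
        for i, ch in enumerate(spec.motif):
            base = s[at + i]
            if base not in IUPAC[ch] or base not in "ACGT":
                return False
        return True

    L, mlen = len(seq), len(spec.motif)
    for p in range(L - mlen + 1):
        if matches(seq, p):
            yield p, "+"
    rc = revcomp(seq)
    for p in range(L - mlen + 1):
        if matches(rc, p):
            yield L - (p + mlen), "-"
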