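"""End-to-end orchestration: reads -> QC -> catalog -> screen -> call.

Thin glue over the stage modules so drivers, the CLI and tests run the
identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import genotype as gt
from . import qc as qcmod
from . import screen as sc
from .digest import BSAXI, RecognitionSpec
from .simulate import SimConfig, SimTruth, simulate_population


@dataclass
class ScreenResult:
    config: SimConfig
    truth: SimTruth
    qc_report: qcmod.QCReport
    catalog: list[gt.TagLocus]
    snp_table: pd.DataFrame
    tag_results: list[sc.SexAssociationResult]
    snp_results: pd.DataFrame
    inference: sc.SystemInference
    presence: sc.PresenceMatrix = field(repr=False, default=None)
    genomes: dict = field(repr=False, default=None)


def screen_from_reads(
    reads_by_individual: dict[str, list[tuple[str, str]]],
    sexes: dict[str, str],
    spec: RecognitionSpec = BSAXI,
    qc_params: qcmod.QCParams | None = None,
    max_mismatch: int = 2,
    min_locus_depth: int = 3,
    top_n: int = 10,
):
    """Run QC, cataloguing, genotyping and the sex screen on raw reads."""
    params = qc_params or qcmod.QCParams(read_length=spec.read_length,
                                         core_length=spec.core_length)
    cores, qc_report = qcmod.run_qc(reads_by_individual, sexes, params, spec)
    catalog = gt.build_catalog(cores, max_mismatch=max_mismatch)
    individuals = sorted(sexes)
    calls = gt.genotype_all(catalog, individuals, min_locus_depth=min_locus_depth)
    snp_table = gt.call_snps(catalog, calls)
    depth = gt.depth_matrix(catalog, individuals)
    matrix = sc.PresenceMatrix(depth=depth, sexes=sexes,
                               min_locus_depth=min_locus_depth)
    tag_results = sc.find_sex_specific_tags(matrix)
    snp_results = sc.snp_sex_association(snp_table, sexes)
    inference = sc.infer_system(tag_results, snp_results, top_n=top_n)
    return qc_report, catalog, snp_table, tag_results, snp_results, inference, matrix


def run_simulated_screen(config: SimConfig, top_n: int = 10, **read_kwargs) -> ScreenResult:
    """Simulate a population under *config* and screen it end to end."""
    _, truth, genomes, reads = simulate_population(config, **read_kwargs)
    (qc_report, catalog, snp_table, tag_results, snp_results,
     inference, matrix) = screen_from_reads(reads, truth.sex_by_individual, top_n=top_n)
    return ScreenResult(
        config=config, truth=truth, qc_report=qc_report, catalog=catalog,
        snp_table=snp_table, tag_results=tag_results, snp_results=snp_results,
        inference=inference, presence=matrix, genomes=genomes,
    )


def locus_for_core(catalog: list[gt.TagLocus], core_canonical: str) -> gt.TagLocus | None:
    """Find the catalog locus holding a given canonical core, if any.

    Alleles are stored in the consensus frame, which may be the reverse
    complement of the canonical frame, so comparison is canonical.
    """
    from .digest import canonicalize

    for locus in catalog:
        if core_canonical == locus.consensus:
            return locus
        if any(core_canonical == canonicalize(a) for a in locus.alleles):
            return locus
    return None


def truth_locus_map(result: ScreenResult) -> dict[str, gt.TagLocus | None]:
    """Map each planted tag id to the catalog locus carrying its core."""
    from .digest import canonicalize

    return {
        tag_id: locus_for_core(result.catalog, canonicalize(core))
        for tag_id, core in result.truth.tag_core.items()
    }


def genotype_accuracy(result: ScreenResult, min_locus_depth: int = 3) -> float:
    """Fraction of (planted locus, individual) genotype calls matching truth.

    The expected call at a locus is the canonical-core multiset of the
    individual's planted alleles; the observed call is the depth-threshold
    genotype at the catalog locus carrying that core. Individuals not
    carrying a sex-limited tag are expected absent (or the locus simply
    lacks their depth).
    """
    from .digest import canonicalize

    tag_to_locus = truth_locus_map(result)
    n_total = 0
    n_correct = 0
    for ind, tags in result.genomes.items():
        for tag_id, locus in tag_to_locus.items():
            expected = (
                frozenset(canonicalize(a) for a in tags[tag_id])
                if tag_id in tags else frozenset()
            )
            n_total += 1
            if locus is None:
                n_correct += not expected
                continue
            call = gt.genotype(locus, ind, min_locus_depth=min_locus_depth)
            observed = frozenset(canonicalize(a) for a in call.alleles)
            n_correct += observed == expected
    return n_correct / n_total if n_total else float("nan")
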