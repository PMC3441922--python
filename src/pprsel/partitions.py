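"""Structural-partition selection tests and truncation localisation.

Partitions (PPR repeats, helix A/B stretches, the C-terminal E/E+/DYW
domains) are codon ranges on the gene alignment.  Each partition's omega is
compared against the gene-wide mean by a likelihood-ratio test in which the
partition's omega is clamped to the gene value; helix A and helix B
concatenations are compared by clamping each helix's omega to the other's
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import CodonAlignment
from .errors import InsufficientDataError, ReferenceTaxonError
from .genetic_code import STOP_CODONS
from .io import AnalysisConfig, PartitionMap
from .models import CodonModel, CodonModelResults, lrt
from .trees import PhyloTree


@dataclass
class PartitionTestResult:
    partition_name: str
    omega_hat: float
    logL_free: float
    logL_at_gene_omega: float
    p_value: float
    direction: str  # below_gene_mean | above_gene_mean
    q_value: float | None = None  # BH-adjusted, when requested


@dataclass
class HelixComparisonResult:
    omega_A: float
    omega_B: float
    p_A_vs_B: float  # helix A data, omega clamped to helix B's estimate
    p_B_vs_A: float


@dataclass
class TruncationReport:
    taxon: str
    first_premature_stop_codon: int | None  # 1-based codon index
    domains_lost: list[str]
    reference_taxon: str


def extract_partition(
    aln: CodonAlignment, pmap: PartitionMap, name_or_class: str
) -> CodonAlignment:
    """Concatenate all codon ranges matching a partition name or class.

    Ranges are concatenated in ascending coordinate order; taxa are
    preserved.  Overlapping ranges under different names duplicate their
    shared columns, by construction.
    """
    entries = sorted(pmap.select(name_or_class), key=lambda e: e.start_codon)
    columns: list[int] = []
    for e in entries:
        columns.extend(e.columns())
    return aln.select_codons(columns)


def partition_omega_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    pmap: PartitionMap,
    partition_name: str,
    cfg: AnalysisConfig | None = None,
    gene_fit: CodonModelResults | None = None,
) -> PartitionTestResult:
    """Does a partition's omega differ from the gene-wide mean?

    The free model re-estimates omega on the partition's columns with kappa
    and the branch scaler fixed at their gene-wide estimates; the null
    clamps omega to the gene-wide value.  The two-sided p-value comes from a
    chi-square LRT with one degree of freedom.
    """
    cfg = cfg or AnalysisConfig()
    gene_model = CodonModel(aln, tree, config=cfg)
    if gene_fit is None:
        gene_fit = gene_model.fit()
    omega_gene = gene_fit.params.omega
    kappa, scaler = gene_fit.params.kappa, gene_fit.params.rate_scaler

    sub = extract_partition(aln, pmap, partition_name)
    model = CodonModel(sub, tree, config=cfg, pi=gene_model.pi)
    if model.n_informative_codons < 3:
        raise InsufficientDataError(
            f"partition {partition_name!r} has fewer than 3 informative codons"
        )
    free = model.fit(fix_kappa=kappa, fix_scaler=scaler)
    constrained = model.fit(fix_omega=omega_gene, fix_kappa=kappa, fix_scaler=scaler)
    test = lrt(free, constrained, df=1)
    return PartitionTestResult(
        partition_name=partition_name,
        omega_hat=free.params.omega,
        logL_free=free.llf,
        logL_at_gene_omega=constrained.llf,
        p_value=test.p_value,
        direction="below_gene_mean" if free.params.omega < omega_gene else "above_gene_mean",
    )


def all_partition_tests(
    aln: CodonAlignment,
    tree: PhyloTree,
    pmap: PartitionMap,
    cfg: AnalysisConfig | None = None,
    adjust: str | None = None,
) -> list[PartitionTestResult]:
    """partition_omega_test for every named partition, sharing one gene fit.

    Raw per-partition p-values are reported by default; ``adjust="bh"``
    additionally fills ``q_value`` with Benjamini–Hochberg adjusted values.
    """
    cfg = cfg or AnalysisConfig()
    gene_fit = CodonModel(aln, tree, config=cfg).fit()
    results = [
        partition_omega_test(aln, tree, pmap, name, cfg=cfg, gene_fit=gene_fit)
        for name in pmap.names
    ]
    if adjust == "bh":
        from scipy.stats import false_discovery_control

        qs = false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, qs):
            r.q_value = float(q)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def helix_comparison_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    pmap: PartitionMap,
    cfg: AnalysisConfig | None = None,
) -> HelixComparisonResult:
    """Compare selective pressure on concatenated helix A vs helix B.

    Each concatenation gets its own full M0 fit (the concatenations are long
    enough to identify omega, kappa and the scaler).  p_A_vs_B is the LRT
    p-value on the helix A data with omega clamped to helix B's estimate,
    and symmetrically for p_B_vs_A.
    """
    cfg = cfg or AnalysisConfig()
    aln_A = extract_partition(aln, pmap, "helixA")
    aln_B = extract_partition(aln, pmap, "helixB")
    model_A = CodonModel(aln_A, tree, config=cfg)
    model_B = CodonModel(aln_B, tree, config=cfg)
    fit_A = model_A.fit()
    fit_B = model_B.fit()
    con_A = model_A.fit(fix_omega=fit_B.params.omega)
    con_B = model_B.fit(fix_omega=fit_A.params.omega)
    return HelixComparisonResult(
        omega_A=fit_A.params.omega,
        omega_B=fit_B.params.omega,
        p_A_vs_B=lrt(fit_A, con_A, df=1).p_value,
        p_B_vs_A=lrt(fit_B, con_B, df=1).p_value,
    )


def locate_truncation(
    aln: CodonAlignment,
    pmap: PartitionMap,
    taxon: str,
    reference: str,
) -> TruncationReport:
    """First premature stop codon in ``taxon`` and the domains beyond it.

    The alignment must have been read with ``allow_stop_codons=True``.  The
    reference taxon must be stop-free; a partition counts as lost when it
    starts strictly after the stop codon.
    """
    for t in (taxon, reference):
        if t not in aln.sequences:
            raise KeyError(f"taxon {t!r} not in alignment")
    if _first_stop(aln, reference) is not None:
        raise ReferenceTaxonError(f"reference taxon {reference!r} contains a premature stop")
    stop = _first_stop(aln, taxon)
    lost: list[str] = []
    if stop is not None:
        seen: dict[str, None] = {}
        for e in aln_entries_after(pmap, stop):
            seen.setdefault(e.name)
        lost = list(seen)
    return TruncationReport(
        taxon=taxon,
        first_premature_stop_codon=stop,
        domains_lost=lost,
        reference_taxon=reference,
    )


def aln_entries_after(pmap: PartitionMap, stop_codon_index: int):
    return [e for e in pmap.entries if e.start_codon > stop_codon_index]


def _first_stop(aln: CodonAlignment, taxon: str) -> int | None:
    """1-based index of the first fully resolved in-frame stop codon."""
    seq = aln.sequences[taxon]
    for k in range(aln.n_codons):
        if seq[3 * k : 3 * k + 3] in STOP_CODONS:
            return k + 1
    return None
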