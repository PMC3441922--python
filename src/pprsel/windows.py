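"""Sliding-window dN/dS profile along a gene.

Windows of ``window_codons`` codons advance by ``step_codons``; only full
windows are emitted.  Per window only omega is re-estimated — kappa, the
branch-length scaler and the codon frequencies are held at their gene-wide
values, since a 9-codon window cannot identify three parameters.  A window's
omega is reported as undefined (None) when the window has fewer than three
informative codons or shows no synonymous divergence (dS = 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .alignment import CodonAlignment
from .errors import EmptyScanError, PprselError
from .io import AnalysisConfig
from .models import CodonModel, CodonModelResults
from .ng86 import ng86_path_differences
from .genetic_code import CODON_INDEX
from .trees import PhyloTree


@dataclass
class Window:
    start_codon: int  # 1-based inclusive
    end_codon: int
    midpoint_nt: float  # 1-based nucleotide position of the window midpoint


@dataclass
class WindowResult:
    start_codon: int
    end_codon: int
    midpoint_nt: float
    omega: float | None
    logL: float | None
    n_informative_codons: int


def make_windows(n_codons: int, window_codons: int, step_codons: int) -> list[Window]:
    """Full windows over ``n_codons`` codons.

    Window count is floor((n_codons - window_codons)/step_codons) + 1.  The
    midpoint is the central nucleotide of the window: for an odd window size
    this is the second nucleotide of the central codon (e.g. nt 14 for
    codons 1-9).
    """
    if n_codons < window_codons:
        raise EmptyScanError(
            f"{n_codons} codons is shorter than one {window_codons}-codon window"
        )
    windows = []
    for start in itertools.count(1, step_codons):
        end = start + window_codons - 1
        if end > n_codons:
            break
        first_nt = 3 * (start - 1) + 1
        last_nt = 3 * end
        mid = (first_nt + last_nt) / 2.0
        windows.append(Window(start, end, mid if mid != int(mid) else int(mid)))
    return windows


def _has_synonymous_divergence(window_aln: CodonAlignment) -> tuple[bool, bool]:
    """(any_difference, any_synonymous_difference) across all taxon pairs."""
    any_diff = any_syn = False
    codes = [window_aln.sequences[t] for t in window_aln.taxa]
    n = window_aln.n_codons
    for i, s1 in enumerate(codes):
        for s2 in codes[i + 1 :]:
            for k in range(n):
                c1, c2 = s1[3 * k : 3 * k + 3], s2[3 * k : 3 * k + 3]
                if c1 not in CODON_INDEX or c2 not in CODON_INDEX or c1 == c2:
                    continue
                any_diff = True
                sd, _ = ng86_path_differences(c1, c2)
                if sd > 0:
                    return True, True
    return any_diff, any_syn


def scan_dnds(
    aln: CodonAlignment,
    tree: PhyloTree,
    cfg: AnalysisConfig | None = None,
    gene_fit: CodonModelResults | None = None,
) -> list[WindowResult]:
    """Sliding-window omega profile on a fixed phylogeny.

    ``gene_fit`` (an M0 fit of the whole alignment) supplies the fixed kappa
    and branch scaler; it is computed here when not given.  Windows where a
    fit fails are recorded with omega None and the scan continues.
    """
    cfg = cfg or AnalysisConfig()
    gene_model = CodonModel(aln, tree, config=cfg)
    if gene_fit is None:
        gene_fit = gene_model.fit()
    kappa = gene_fit.params.kappa
    scaler = gene_fit.params.rate_scaler
    pi = gene_model.pi

    results = []
    for w in make_windows(aln.n_codons, cfg.window_codons, cfg.step_codons):
        sub = aln.slice_codons(w.start_codon, w.end_codon)
        model = CodonModel(sub, tree, config=cfg, pi=pi)
        n_inf = model.n_informative_codons
        omega = logL = None
        if n_inf >= 3:
            try:
                _, any_syn = _has_synonymous_divergence(sub)
                fit = model.fit(fix_kappa=kappa, fix_scaler=scaler)
                logL = fit.llf
                # dS = 0 (no synonymous divergence): omega is inestimable,
                # reported as a gap rather than a capped value
                if any_syn:
                    omega = fit.params.omega
            except PprselError:
                pass
        results.append(
            WindowResult(
                start_codon=w.start_codon,
                end_codon=w.end_codon,
                midpoint_nt=w.midpoint_nt,
                omega=omega,
                logL=logL,
                n_informative_codons=n_inf,
            )
        )
    return results


def scan_to_frame(results: list[WindowResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start_codon": r.start_codon,
                "end_codon": r.end_codon,
                "midpoint_nt": r.midpoint_nt,
                "omega": r.omega if r.omega is not None else "",
                "logL": r.logL if r.logL is not None else "",
                "n_informative_codons": r.n_informative_codons,
            }
            for r in results
        ]
    )
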