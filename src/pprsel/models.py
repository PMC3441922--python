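"""Codon-model fitting: M0, fixed-omega, and two-ratio branch models.

The central objects follow the statsmodels convention: a :class:`CodonModel`
is built from data (alignment + tree) and ``fit()`` returns a
:class:`CodonModelResults` carrying estimates, log-likelihood and
diagnostics, with ``summary()`` and ``lrt()`` hanging off the results.

All fits keep the *relative* branch lengths of the input tree fixed and
optimise a single global rate scaler alongside omega and kappa; this keeps
short extracts (down to 9-codon windows) identifiable.  Optimisation is
bounded quasi-Newton in log-parameter space with deterministic multi-starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment
from .errors import ConvergenceError, OrderingError
from .io import AnalysisConfig
from .likelihood import TreeLikelihood
from .ng86 import PairwiseEstimate
from .ratematrix import (
    CodonModelParams,
    expected_substitution_fractions,
    f3x4_frequencies,
    site_fractions,
    uniform_frequencies,
)
from .trees import PhyloTree

_PENALTY = 1e12  # objective value standing in for log-likelihood -inf


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models.

    statistic = 2 (logL_free - logL_constrained), compared with a chi-square
    distribution on ``df`` degrees of freedom.
    """

    logL_free: float
    logL_constrained: float
    df: int
    statistic: float
    p_value: float


def lrt(free, constrained, df: int) -> LRTResult:
    """Likelihood-ratio test between a free and a nested constrained fit.

    Accepts :class:`CodonModelResults` or bare log-likelihood floats.
    Raises :class:`OrderingError` when the constrained model beats the free
    one by more than numerical tolerance (an optimiser failure).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    llf_free = free.llf if hasattr(free, "llf") else float(free)
    llf_con = constrained.llf if hasattr(constrained, "llf") else float(constrained)
    stat = 2.0 * (llf_free - llf_con)
    if math.isnan(stat):
        raise ValueError("log-likelihoods must be comparable (not NaN)")
    if stat < -1e-4:
        raise OrderingError(
            f"constrained logL {llf_con:.6f} exceeds free logL {llf_free:.6f}"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if math.isfinite(stat) else 0.0
    return LRTResult(
        logL_free=llf_free,
        logL_constrained=llf_con,
        df=df,
        statistic=stat,
        p_value=p,
    )


class CodonModelResults:
    """Fitted codon model: parameter estimates and diagnostics."""

    def __init__(self, model, params, llf, converged, n_starts_used, free_names):
        self.model = model
        self.params: CodonModelParams = params
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_starts_used = int(n_starts_used)
        self.free_names: tuple[str, ...] = tuple(free_names)

    # spec-facing aliases
    @property
    def logL(self) -> float:
        return self.llf

    @property
    def n_codons(self) -> int:
        return self.model.n_codons

    @property
    def df_model(self) -> int:
        return len(self.free_names)

    @property
    def omega(self) -> float:
        return self.params.omega

    @property
    def kappa(self) -> float:
        return self.params.kappa

    @property
    def rate_scaler(self) -> float:
        return self.params.rate_scaler

    @property
    def foreground_omega(self) -> float | None:
        return self.params.foreground_omega

    def lrt(self, constrained: "CodonModelResults", df: int | None = None) -> LRTResult:
        """LRT of this (free) fit against a nested constrained fit."""
        if df is None:
            df = self.df_model - constrained.df_model
        return lrt(self, constrained, df)

    def summary(self) -> str:
        lines = [
            "Codon substitution model fit",
            "=" * 44,
            f"{'codons':<22}{self.n_codons:>22}",
            f"{'log-likelihood':<22}{self.llf:>22.4f}",
            f"{'converged':<22}{str(self.converged):>22}",
            f"{'starts used':<22}{self.n_starts_used:>22}",
            "-" * 44,
            f"{'omega (dN/dS)':<22}{self.params.omega:>22.4f}",
            f"{'kappa (ts/tv)':<22}{self.params.kappa:>22.4f}",
            f"{'rate scaler':<22}{self.params.rate_scaler:>22.4f}",
        ]
        if self.params.foreground_omega is not None:
            lines.append(f"{'foreground omega':<22}{self.params.foreground_omega:>22.4f}")
        lines.append(
            f"{'free parameters':<22}{', '.join(self.free_names) or '(none)':>22}"
        )
        lines.append("=" * 44)
        return "\n".join(lines)

    def __repr__(self):
        w = self.params.omega
        return f"<CodonModelResults omega={w:.4g} logL={self.llf:.3f}>"


class CodonModel:
    """Codon substitution model bound to an alignment and tree.

    Parameters
    ----------
    alignment, tree
        The data.  Tree taxa must be a subset of alignment taxa.
    config
        :class:`~pprsel.io.AnalysisConfig`; supplies optimiser bounds,
        multi-start count and the frequency model.
    pi
        Explicit equilibrium codon frequencies; overrides the config's
        frequency model (used to share gene-wide frequencies with window
        and partition fits).
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        config: AnalysisConfig | None = None,
        pi: np.ndarray | None = None,
    ):
        self.alignment = alignment
        self.tree = tree
        self.config = config or AnalysisConfig()
        if pi is not None:
            self.pi = np.asarray(pi, dtype=float)
        elif self.config.frequency_model == "F3x4":
            self.pi = f3x4_frequencies(alignment)
        else:
            self.pi = uniform_frequencies()
        self.engine = TreeLikelihood(alignment, tree)

    @property
    def n_codons(self) -> int:
        return self.alignment.n_codons

    @property
    def n_informative_codons(self) -> int:
        return self.engine.n_informative_codons

    @classmethod
    def from_files(cls, alignment_path, tree_path, config=None) -> "CodonModel":
        from .io import read_codon_alignment
        from .trees import read_tree

        cfg = config or AnalysisConfig()
        return cls(
            read_codon_alignment(alignment_path),
            read_tree(tree_path, default_branch_length=cfg.default_branch_length),
            config=cfg,
        )

    # -- likelihood ----------------------------------------------------

    def loglike(
        self,
        omega: float,
        kappa: float,
        rate_scaler: float = 1.0,
        foreground_omega: float | None = None,
    ) -> float:
        params = CodonModelParams(
            omega=omega,
            kappa=kappa,
            pi=self.pi,
            rate_scaler=rate_scaler,
            foreground_omega=foreground_omega,
        )
        return self.engine.loglike(params)

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        fix_omega: float | None = None,
        fix_kappa: float | None = None,
        fix_scaler: float | None = None,
        two_ratio: bool = False,
        fix_foreground_omega: float | None = None,
    ) -> CodonModelResults:
        """Maximise the likelihood over the non-fixed parameters.

        With ``two_ratio=True`` the branches marked foreground on the tree
        get their own omega (free, or clamped to ``fix_foreground_omega``).
        """
        cfg = self.config
        if two_ratio and self.tree.foreground_edge_count() == 0:
            raise ValueError("two-ratio model requires >= 1 foreground branch")

        bounds_of = {
            "omega": cfg.omega_bounds,
            "kappa": cfg.kappa_bounds,
            "rate_scaler": cfg.scaler_bounds,
            "foreground_omega": cfg.omega_bounds,
        }
        fixed: dict[str, float] = {}
        free: list[str] = []
        for name, fix in (
            ("omega", fix_omega),
            ("kappa", fix_kappa),
            ("rate_scaler", fix_scaler),
        ):
            if fix is not None:
                fixed[name] = float(fix)
            else:
                free.append(name)
        if two_ratio:
            if fix_foreground_omega is not None:
                fixed["foreground_omega"] = float(fix_foreground_omega)
            else:
                free.append("foreground_omega")

        def build(values: dict[str, float]) -> CodonModelParams:
            return CodonModelParams(
                omega=values["omega"],
                kappa=values["kappa"],
                pi=self.pi,
                rate_scaler=values["rate_scaler"],
                foreground_omega=values.get("foreground_omega"),
            )

        def objective(x: np.ndarray) -> float:
            values = dict(fixed)
            for name, xi in zip(free, x):
                values[name] = math.exp(xi)
            ll = self.engine.loglike(build(values))
            return _PENALTY if not math.isfinite(ll) else -ll

        if not free:  # pure evaluation, nothing to optimise
            ll = self.engine.loglike(build(fixed))
            return CodonModelResults(self, build(fixed), ll, math.isfinite(ll), 0, ())

        starts = self._starts(free, fixed)
        best_x, best_obj, n_used, ok = None, np.inf, 0, False
        for x0 in starts:
            n_used += 1
            if len(free) == 1:
                lo, hi = (math.log(b) for b in bounds_of[free[0]])
                res = optimize.minimize_scalar(
                    lambda v: objective(np.array([v])),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-8},
                )
                x, obj, success = np.array([res.x]), res.fun, res.success
            else:
                res = optimize.minimize(
                    objective,
                    x0,
                    method="L-BFGS-B",
                    bounds=[tuple(math.log(b) for b in bounds_of[n]) for n in free],
                    options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
                )
                x, obj, success = res.x, res.fun, res.success
            if obj < best_obj:
                best_x, best_obj, ok = x, obj, success
            if len(free) == 1:
                break  # bounded scalar search is global over the bracket

        if best_x is None:
            raise ConvergenceError("all optimisation starts failed")
        if best_obj >= _PENALTY:
            # likelihood is -inf everywhere reachable (e.g. omega fixed at 0
            # with observed amino-acid changes): report the sentinel
            values = dict(fixed)
            for name, xi in zip(free, best_x):
                values[name] = math.exp(xi)
            return CodonModelResults(self, build(values), -np.inf, False, n_used, free)

        values = dict(fixed)
        for name, xi in zip(free, best_x):
            values[name] = math.exp(xi)
        return CodonModelResults(self, build(values), -best_obj, ok, n_used, free)

    def _starts(self, free: list[str], fixed: dict[str, float]) -> list[np.ndarray]:
        defaults = {
            "omega": 0.3,
            "kappa": 2.0,
            "rate_scaler": 1.0,
            "foreground_omega": fixed.get("omega", 0.3),
        }
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        bounds_of = {
            "omega": cfg.omega_bounds,
            "kappa": cfg.kappa_bounds,
            "rate_scaler": cfg.scaler_bounds,
            "foreground_omega": cfg.omega_bounds,
        }
        starts = []
        for k in range(max(1, cfg.n_starts)):
            x0 = []
            for name in free:
                v = math.log(defaults[name])
                if k > 0:
                    v += rng.normal(0.0, 0.8)
                lo, hi = (math.log(b) for b in bounds_of[name])
                x0.append(min(max(v, lo), hi))
            starts.append(np.asarray(x0))
        return starts


# ---------------------------------------------------------------------------
# spec-facing convenience functions


def fit_m0(
    aln: CodonAlignment, tree: PhyloTree, cfg: AnalysisConfig | None = None
) -> CodonModelResults:
    """Single-ratio (M0) fit: free omega, kappa and rate scaler."""
    return CodonModel(aln, tree, config=cfg).fit()


def fit_fixed_omega(
    aln: CodonAlignment,
    tree: PhyloTree,
    omega_fixed: float,
    cfg: AnalysisConfig | None = None,
) -> CodonModelResults:
    """Fit with omega clamped; kappa and rate scaler remain free."""
    if omega_fixed < 0:
        raise ValueError("omega_fixed must be >= 0")
    return CodonModel(aln, tree, config=cfg).fit(fix_omega=omega_fixed)


def fit_branch_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground=None,
    fix_foreground_omega: float | None = None,
    cfg: AnalysisConfig | None = None,
) -> CodonModelResults:
    """Two-ratio branch model: background omega plus a foreground omega.

    ``foreground`` is a marking spec (leaf label, iterable of leaf labels for
    an MRCA stem branch, or ``"all"``); ``None`` uses markers already on the
    tree.  Clamping ``fix_foreground_omega`` (typically to 1) gives the null
    for a purifying-selection test on the foreground branch via
    ``lrt(free, constrained, df=1)``.
    """
    work = tree
    if foreground is not None:
        work = tree.copy()
        work.mark_foreground(foreground)
    if work.foreground_edge_count() == 0:
        raise ValueError("no foreground branches marked")
    return CodonModel(aln, work, config=cfg).fit(
        two_ratio=True, fix_foreground_omega=fix_foreground_omega
    )


def pairwise_dnds_ml(
    s1: str, s2: str, cfg: AnalysisConfig | None = None
) -> PairwiseEstimate:
    """Maximum-likelihood dN/dS for one sequence pair.

    Maximises the two-sequence likelihood over divergence t, kappa and
    omega, then converts to dN and dS using the model's expected flux split
    and physical site composition (sites evaluated at omega = 1).
    """
    cfg = cfg or AnalysisConfig()
    aln = CodonAlignment(["seq_a", "seq_b"], {"seq_a": s1, "seq_b": s2}, allow_stop_codons=False)
    if s1.upper() == s2.upper():
        return PairwiseEstimate(dN=0.0, dS=0.0, omega=None, method="ML", n_codons_used=aln.n_codons)
    tree = PhyloTree.from_newick("(seq_a:0.5,seq_b:0.5);")
    model = CodonModel(aln, tree, config=cfg)
    res = model.fit()  # rate_scaler is the total divergence t (tree length 1)
    t = res.params.rate_scaler
    rho_s, rho_n = expected_substitution_fractions(res.params)
    S, N = site_fractions(res.params)
    dS = t * rho_s / (S / 3.0) if S > 0 else None
    dN = t * rho_n / (N / 3.0) if N > 0 else None
    omega = None
    if dN is not None and dS is not None and dS > 1e-9:
        omega = dN / dS
    return PairwiseEstimate(
        dN=dN, dS=dS, omega=omega, method="ML", n_codons_used=model.engine.n_informative_codons
    )
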