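"""Stepwise joint logistic modelling of trait-association status.

Association status (1 = trait-associated, 0 = background) is regressed on
binary annotation-incidence columns, with the intercept and platform-group
indicators forced into every model: being on a genotyping platform already
predicts catalog membership, so the "empty" model contains those terms and
the annotations must earn their place on top of them.

Model selection is bidirectional stepwise by AIC: at each step the single
add-or-drop move with the largest AIC reduction is taken; the search halts
when no move reduces AIC.  Per-term inference is Wald (the β-coefficient
is estimate/SE, i.e. the Wald z); whole-model comparisons use the
likelihood-ratio (deviance) chi-squared test.  Fit quality is summarized
by McFadden's and McKelvey–Zavoina's pseudo-r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import LdMap, SnpCatalog
from .overlap import OverlapMatrix
from .stats import ContingencyTable, EnrichmentResult, odds_ratio, wald_ci, wald_pvalue

__all__ = [
    "ModelTerm",
    "ModelFit",
    "ModelComparison",
    "PseudoR2",
    "fit_logistic",
    "stepwise_aic",
    "pseudo_r2",
    "lr_deviance_test",
    "combined_annotation_or",
    "distance_to_tss",
]

_LOGISTIC_LATENT_VAR = np.pi**2 / 3  # variance of the standard logistic


@dataclass(frozen=True)
class ModelTerm:
    name: str
    estimate: float  # log-odds
    se: float
    beta_coefficient: float  # estimate / se (Wald z)
    pvalue: float


@dataclass(frozen=True)
class ModelFit:
    """A fitted logistic model with Wald summaries per term."""

    terms: tuple[ModelTerm, ...]
    loglik: float
    aic: float
    n_obs: int
    forced_terms: frozenset[str]
    separation_flag: bool
    linear_predictor: np.ndarray

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio (deviance) comparison of nested fits."""

    deviance: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PseudoR2:
    mcfadden: float
    mckelvey_zavoina: float


def fit_logistic(response, design: pd.DataFrame, forced_terms=(),
                 add_intercept: bool = True, maxiter: int = 100) -> ModelFit:
    """Maximum-likelihood logit fit with separation detection.

    ``design`` columns are the named covariates; an intercept column is
    prepended unless ``add_intercept`` is false.  Complete or
    quasi-complete separation is flagged (not silently accepted) via
    perfect-prediction and exploding-coefficient checks.
    """
    y = np.asarray(response, dtype=float)
    if y.min() == y.max():
        raise ValueError("response needs both classes present")
    X = design.copy()
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if v.min() == v.max():
            raise ValueError(f"constant non-intercept column {col!r}")
    if add_intercept:
        if X.shape[1] == 0:
            X = pd.DataFrame({"const": np.ones(len(y))})
        else:
            X = sm.add_constant(X, prepend=True, has_constant="raise")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X.to_numpy(dtype=float))
        try:
            res = model.fit(disp=0, maxiter=maxiter)
        except Exception as e:  # PerfectSeparationError and friends
            if "separation" not in str(e).lower() and "singular" not in str(e).lower():
                raise
            separation = True
            model.raise_on_perfect_prediction = False  # report, don't crash
            res = model.fit(disp=0, maxiter=maxiter, method="bfgs")
        for w in caught:
            msg = str(w.message).lower()
            if "separation" in msg or "perfectly" in msg:
                separation = True
    retvals = getattr(res, "mle_retvals", None)
    if isinstance(retvals, dict) and not retvals.get("converged", True) and not separation:
        raise RuntimeError(f"logit did not converge: {retvals}")
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    fitted = model.predict(params)
    perfectly = np.all((fitted > 1 - 1e-6) == (y == 1)) and np.all(
        (fitted < 1e-6) == (y == 0)
    )
    if perfectly or np.abs(params).max() > 25:
        separation = True
    names = list(X.columns)
    terms = tuple(
        ModelTerm(
            name=nm,
            estimate=float(b),
            se=float(s),
            beta_coefficient=float(b / s) if s > 0 else np.sign(b) * np.inf,
            pvalue=float(2 * sps.norm.sf(abs(b / s))) if s > 0 else 0.0,
        )
        for nm, b, s in zip(names, params, bse)
    )
    loglik = float(res.llf)
    k = len(params)
    return ModelFit(
        terms=terms,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_obs=len(y),
        forced_terms=frozenset(forced_terms) | ({"const"} if add_intercept else frozenset()),
        separation_flag=separation,
        linear_predictor=np.asarray(X, dtype=float) @ params,
    )


def stepwise_aic(
    response,
    data: pd.DataFrame,
    forced: list[str],
    candidates: list[str],
    blacklist: set[str] = frozenset(),
    step_log: list | None = None,
) -> ModelFit:
    """Bidirectional stepwise selection by AIC from the forced base model.

    ``forced`` columns (platform indicators) are in every model and never
    dropped; ``candidates`` are annotation columns considered for addition
    or removal.  Each step takes the single move with the largest AIC
    reduction (ties broken lexicographically by column name); the search
    halts when no move reduces AIC.  ``blacklist`` removes tautological
    annotations (e.g. trait-defined gene lists) from candidacy.

    When ``step_log`` is given, (action, column, aic) triples are appended
    for every accepted move.
    """
    candidates = sorted(c for c in candidates if c not in blacklist)
    included: list[str] = []
    current = fit_logistic(response, data[forced], forced_terms=forced)
    if step_log is not None:
        step_log.append(("base", None, current.aic))
    while True:
        moves: list[tuple[float, str, str]] = []  # (aic, action, col)
        for col in candidates:
            if col in included:
                continue
            fit = fit_logistic(response, data[forced + sorted(included + [col])],
                               forced_terms=forced)
            moves.append((fit.aic, "add", col))
        for col in included:
            remaining = [c for c in included if c != col]
            fit = fit_logistic(response, data[forced + sorted(remaining)],
                               forced_terms=forced)
            moves.append((fit.aic, "drop", col))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, col = moves[0]
        if best_aic >= current.aic:
            break  # AIC would increase: halt
        if action == "add":
            included.append(col)
        else:
            included.remove(col)
        current = fit_logistic(response, data[forced + sorted(included)],
                               forced_terms=forced)
        if step_log is not None:
            step_log.append((action, col, current.aic))
    return current


def pseudo_r2(fit_empty: ModelFit, fit_full: ModelFit) -> PseudoR2:
    """McFadden and McKelvey–Zavoina pseudo-r² of full vs empty model.

    McFadden: 1 − loglik_full / loglik_empty.  McKelvey–Zavoina: variance
    of the full model's linear predictor over that variance plus the
    logistic latent variance π²/3.
    """
    if fit_empty.loglik == 0:
        raise ValueError("empty-model log-likelihood is 0")
    mcf = 1.0 - fit_full.loglik / fit_empty.loglik
    v = float(np.var(fit_full.linear_predictor, ddof=1)) if fit_full.n_obs > 1 else 0.0
    mz = v / (v + _LOGISTIC_LATENT_VAR)
    return PseudoR2(mcfadden=mcf, mckelvey_zavoina=mz)


def lr_deviance_test(fit_reduced: ModelFit, fit_full: ModelFit) -> ModelComparison:
    """ANOVA-style chi-squared test on the deviance of nested logit fits."""
    df = len(fit_full.terms) - len(fit_reduced.terms)
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits must share the same data")
    dev = 2 * (fit_full.loglik - fit_reduced.loglik)
    if dev < 0:
        warnings.warn("negative deviance clipped to 0 (numerical)", RuntimeWarning)
        dev = 0.0
    return ModelComparison(deviance=dev, df=df, pvalue=float(sps.chi2.sf(dev, df)))


def combined_annotation_or(
    matrix: OverlapMatrix, positive_set: list[str], status
) -> EnrichmentResult:
    """OR of association status against overlap with >=1 annotation of a set.

    A SNP "hits" when it (or an LD partner, via the precomputed matrix)
    overlaps any annotation in ``positive_set``; the 2×2 table crosses hit
    status with association status over all catalog SNPs, with Wald CI and
    p-value.
    """
    if not positive_set:
        raise ValueError("positive_set must be non-empty")
    status = np.asarray(status, dtype=bool)
    cols = np.stack([matrix.column(a) for a in positive_set], axis=1)
    hits = cols.any(axis=1)
    a = int((hits & status).sum())
    b = int((~hits & status).sum())
    c = int((hits & ~status).sum())
    d = int((~hits & ~status).sum())
    table = ContingencyTable(a, b, c, d)
    point = odds_ratio(table)
    lo, hi = wald_ci(table)
    return EnrichmentResult(
        annotation="+".join(positive_set),
        table=table,
        odds_ratio=point,
        ci_low=lo,
        ci_high=hi,
        pvalue=wald_pvalue(table),
        pvalue_is_bound=False,
        fold_enrichment=np.nan,
        method="wald",
    )


def distance_to_tss(
    catalog: SnpCatalog,
    ld: LdMap,
    tss: pd.DataFrame,
    snp_only: bool = False,
    cap: float | None = None,
) -> np.ndarray:
    """Per-SNP minimum upstream distance to a transcription start site.

    ``tss`` holds columns chrom, pos (1-based TSS point), strand.  Upstream
    means 5′ of the TSS respecting strand: for a + strand TSS at t a SNP at
    p ≤ t is t − p away; for a − strand TSS a SNP at p ≥ t is p − t away.
    The distance for a SNP is the minimum over itself and its LD partners
    (unless ``snp_only``).  SNPs with no upstream TSS on their chromosome
    get NaN, or ``cap`` when given.
    """
    if len(tss) == 0:
        raise ValueError("TSS table is empty")
    df = catalog.df
    pos = catalog.positions()
    own = np.full(len(df), np.nan)
    for chrom, sl in catalog.chrom_slices().items():
        sub = tss[tss["chrom"] == chrom]
        p = pos[sl]
        best = np.full(len(p), np.inf)
        plus = np.sort(sub.loc[sub["strand"] == "+", "pos"].to_numpy())
        if len(plus):
            # nearest + strand TSS at or after the SNP
            idx = np.searchsorted(plus, p, side="left")
            ok = idx < len(plus)
            best[ok] = np.minimum(best[ok], plus[idx[ok]] - p[ok])
        minus = np.sort(sub.loc[sub["strand"] == "-", "pos"].to_numpy())
        if len(minus):
            # nearest - strand TSS at or before the SNP
            idx = np.searchsorted(minus, p, side="right") - 1
            ok = idx >= 0
            best[ok] = np.minimum(best[ok], p[ok] - minus[idx[ok]])
        own[sl] = np.where(np.isfinite(best), best, np.nan)
    if not snp_only:
        row_of = {sid: i for i, sid in enumerate(catalog.snp_ids)}
        out = own.copy()
        for sid, partners in ld.items():
            i = row_of.get(sid)
            if i is None:
                continue
            for pid in partners:
                j = row_of.get(pid)
                if j is not None and not np.isnan(own[j]):
                    if np.isnan(out[i]) or own[j] < out[i]:
                        out[i] = own[j]
        own = out
    if cap is not None:
        own = np.where(np.isnan(own), cap, own)
    return own
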