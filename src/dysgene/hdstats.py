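"""Statistical models of hybrid dysgenesis phenotypes.

Ovary counts (0/1/2 functional ovaries per female) are modeled by a
three-category multinomial logit with the healthy two-ovary state as the
reference, so positive logit shifts read as dysgenesis. Mean ovarioles per
functional ovary (rounded to an integer) follow a log-link Poisson GLM;
fully atrophied females carry no ovarioles and are excluded from ovariole
models as missing data, but are full data for ovary-count models.

Terms are tuples of column names, ``()`` being the intercept; an interaction
is simply a longer tuple and its design columns are elementwise products
(categorical columns expand to treatment dummies first). On top of the fits
sit the likelihood-ratio test, type-III (deletion) term tests respecting
marginality, stepwise simplification, the two-sample Fisher-Pitman
permutation test, deviance-explained (D-squared), and a bootstrap comparison
of D-squared between two datasets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "Term",
    "ModelFit",
    "LRTResult",
    "PermutationResult",
    "build_design",
    "fit_multinomial",
    "fit_poisson",
    "poisson_response",
    "lrt",
    "type3_terms",
    "stepwise_simplify",
    "fisher_pitman",
    "senescence_compare",
    "dsquared",
    "bootstrap_r2_compare",
    "hd_summary",
]

Term = tuple  # tuple of column names; () is the intercept

#: ridge strength for the separation fallback (total L2 penalty on the NLL)
_RIDGE_ALPHA = 1e-3
#: |coefficient| beyond this is treated as divergence toward a boundary
_SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    n_permutations: int
    p: float


@dataclass
class ModelFit:
    """A fitted phenotype model.

    ``coefficients`` is a DataFrame indexed by design column: one column per
    logit (``logit0``, ``logit1`` — the 0- and 1-ovary categories against
    the 2-ovary reference) for the multinomial, a single ``coef`` column for
    Poisson. ``bse`` matches its shape. Deviances use the -2*log-likelihood
    convention for the multinomial (individual data, saturated ll = 0) and
    the GLM deviance for Poisson; D-squared is invariant to that choice.
    """

    family: str  # "multinomial" or "poisson"
    terms: tuple[Term, ...]
    coefficients: pd.DataFrame
    bse: pd.DataFrame
    log_likelihood: float
    null_deviance: float
    residual_deviance: float
    df_resid: int
    nobs: int
    converged: bool
    separation: bool = False
    degenerate: bool = False
    term_columns: dict = field(default_factory=dict, repr=False)

    @property
    def n_params(self) -> int:
        per_logit = len(self.coefficients)
        return per_logit * (2 if self.family == "multinomial" else 1)


# ---------------------------------------------------------------------------
# design matrices


def _expand_column(df: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    col = df[name]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(col.astype(str)))
        cols = [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
        names = [f"{name}[{lev}]" for lev in levels[1:]]
        if not cols:  # single level: no contrast
            return np.empty((len(df), 0)), []
        return np.column_stack(cols), names
    return col.to_numpy(float)[:, None], [name]


def build_design(
    df: pd.DataFrame, terms: Sequence[Term]
) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix for a term list.

    Categorical variables become treatment-coded dummies (first level as
    baseline); an interaction term's columns are all pairwise products of
    its factors' columns. Returns (X, column names, term -> column indices).
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    term_columns: dict = {}
    for term in terms:
        term = tuple(term)
        if term == ():
            block, bnames = np.ones((len(df), 1)), ["intercept"]
        else:
            block, bnames = _expand_column(df, term[0])
            for factor in term[1:]:
                nxt, nnames = _expand_column(df, factor)
                block = np.concatenate(
                    [block[:, [i]] * nxt for i in range(block.shape[1])], axis=1
                )
                bnames = [f"{a}:{b}" for a in bnames for b in nnames]
        idx = list(range(len(names), len(names) + len(bnames)))
        term_columns[term] = idx
        blocks.append(block)
        names.extend(bnames)
    X = np.column_stack(blocks) if blocks else np.empty((len(df), 0))
    return X, names, term_columns


def _check_terms(terms: Sequence[Term]) -> tuple[Term, ...]:
    terms = tuple(tuple(t) for t in terms)
    if () not in terms:
        terms = ((),) + terms
    return terms


# ---------------------------------------------------------------------------
# multinomial


def _mn_nll_grad(beta_flat, X, y_codes, alpha):
    n, p = X.shape
    beta = beta_flat.reshape(p, 2)
    eta = np.column_stack([np.zeros(n), X @ beta])
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    denom = expeta.sum(axis=1)
    ll = eta[np.arange(n), y_codes].sum() - np.log(denom).sum()
    probs = expeta / denom[:, None]
    ind = np.zeros((n, 3))
    ind[np.arange(n), y_codes] = 1.0
    grad = -(X.T @ (ind[:, 1:] - probs[:, 1:])) + 2 * alpha * beta
    return -ll + alpha * (beta**2).sum(), grad.ravel()


def _mn_loglik(beta: np.ndarray, X: np.ndarray, y_codes: np.ndarray) -> float:
    n = X.shape[0]
    eta = np.column_stack([np.zeros(n), X @ beta])
    return float(
        eta[np.arange(n), y_codes].sum() - scipy.special.logsumexp(eta, axis=1).sum()
    )


def _mn_null_loglik(y_codes: np.ndarray) -> float:
    n = len(y_codes)
    counts = np.bincount(y_codes, minlength=3)
    return float(sum(c * math.log(c / n) for c in counts if c > 0))


def fit_multinomial(
    records: pd.DataFrame,
    terms: Sequence[Term],
    response: str = "ovary_count",
) -> ModelFit:
    """Maximum-likelihood three-category multinomial logit.

    The response must take values in {0, 1, 2}; both logits contrast against
    the reference category 2 (healthy). Non-convergence or separation (a
    category empty, or coefficients diverging) triggers a small-ridge
    penalized refit and sets flags rather than raising.
    """
    terms = _check_terms(terms)
    df = records
    y = df[response].to_numpy()
    if not np.isin(y, [0, 1, 2]).all():
        raise ValueError("response must be in {0,1,2}")
    # recode so that "2 ovaries" is category 0 (the reference)
    y_codes = np.select([y == 2, y == 0, y == 1], [0, 1, 2]).astype(int)
    X, names, term_columns = build_design(df, terms)

    missing_category = len(np.unique(y_codes)) < 3
    params = None
    converged = False
    separation = False
    if not missing_category:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MNLogit(y_codes, X).fit(method="newton", maxiter=100, disp=0)
                params = np.asarray(res.params)  # (p, 2)
                bse = np.asarray(res.bse)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                params = None
    if params is None or not converged or np.abs(params).max() > _SEPARATION_BOUND:
        separation = params is None or missing_category or (
            params is not None and np.abs(params).max() > _SEPARATION_BOUND
        )
        x0 = np.zeros(2 * X.shape[1])
        opt = scipy.optimize.minimize(
            _mn_nll_grad,
            x0,
            args=(X, y_codes, _RIDGE_ALPHA),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        params = opt.x.reshape(X.shape[1], 2)
        bse = np.full_like(params, np.nan)  # penalized fit: no Wald SEs
        converged = bool(opt.success)

    llf = _mn_loglik(params, X, y_codes)
    ll_null = _mn_null_loglik(y_codes)
    coef = pd.DataFrame(params, index=names, columns=["logit0", "logit1"])
    return ModelFit(
        family="multinomial",
        terms=terms,
        coefficients=coef,
        bse=pd.DataFrame(bse, index=names, columns=["logit0", "logit1"]),
        log_likelihood=llf,
        null_deviance=-2.0 * ll_null,
        residual_deviance=-2.0 * llf,
        df_resid=len(df) - 2 * X.shape[1],
        nobs=len(df),
        converged=converged,
        separation=separation,
        term_columns=term_columns,
    )


# ---------------------------------------------------------------------------
# Poisson


def poisson_response(
    records: pd.DataFrame,
    column: str = "mean_ovarioles",
    rounding: str = "nearest",
) -> pd.DataFrame:
    """Rows with a defined mean-ovariole response, plus an integer-rounded
    copy of it (``rounding``: 'nearest' = half-up, 'up' = ceiling)."""
    df = records[records[column].notna()].copy()
    x = df[column].to_numpy(float)
    if rounding == "nearest":
        df["ovarioles_int"] = np.floor(x + 0.5).astype(int)
    elif rounding == "up":
        df["ovarioles_int"] = np.ceil(x).astype(int)
    else:
        raise ValueError("rounding must be 'nearest' or 'up'")
    return df


def fit_poisson(
    records: pd.DataFrame,
    terms: Sequence[Term],
    response: str = "ovarioles_int",
) -> ModelFit:
    """Log-link Poisson GLM on an integer response."""
    terms = _check_terms(terms)
    df = records
    if len(df) == 0:
        raise ValueError("no records to fit")
    y = df[response].to_numpy(float)
    X, names, term_columns = build_design(df, terms)
    degenerate = bool((y == 0).all())
    if degenerate:
        # mu -> 0 everywhere: the MLE sits on the boundary; report a flagged
        # boundary fit instead of raising
        params = np.full(X.shape[1], 0.0)
        params[0] = -30.0 if names and names[0] == "intercept" else 0.0
        coef = pd.DataFrame({"coef": params}, index=names)
        return ModelFit(
            family="poisson",
            terms=terms,
            coefficients=coef,
            bse=pd.DataFrame({"coef": np.full(X.shape[1], np.nan)}, index=names),
            log_likelihood=0.0,
            null_deviance=0.0,
            residual_deviance=0.0,
            df_resid=len(df) - X.shape[1],
            nobs=len(df),
            converged=True,
            degenerate=True,
            term_columns=term_columns,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
    params = np.asarray(res.params)
    coef = pd.DataFrame({"coef": params}, index=names)
    return ModelFit(
        family="poisson",
        terms=terms,
        coefficients=coef,
        bse=pd.DataFrame({"coef": np.asarray(res.bse)}, index=names),
        log_likelihood=float(res.llf),
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        nobs=len(df),
        converged=bool(getattr(res, "converged", True)),
        degenerate=degenerate,
        term_columns=term_columns,
    )


def _fit(records: pd.DataFrame, terms: Sequence[Term], family: str, response: str | None):
    if family == "multinomial":
        return fit_multinomial(records, terms, response=response or "ovary_count")
    if family == "poisson":
        return fit_poisson(records, terms, response=response or "ovarioles_int")
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# tests on fits


def lrt(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same records."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if reduced.nobs != full.nobs:
        raise ValueError("models were fitted on different numbers of records")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    df = full.n_params - reduced.n_params
    if df < 1:
        return LRTResult(chi2=chi2, df=0, p=1.0)
    return LRTResult(chi2=chi2, df=df, p=float(scipy.stats.chi2.sf(chi2, df)))


def deletable_terms(terms: Sequence[Term]) -> list[Term]:
    """Terms whose removal respects marginality: no other term strictly
    contains them (so a main effect stays while its interaction remains)."""
    terms = [tuple(t) for t in terms]
    out = []
    for t in terms:
        if t == ():
            continue
        if any(set(t) < set(u) for u in terms if u != t):
            continue
        out.append(t)
    return out


def type3_terms(
    records: pd.DataFrame,
    terms: Sequence[Term],
    family: str = "multinomial",
    response: str | None = None,
) -> dict[Term, LRTResult]:
    """Type-III (deletion) tests: each deletable term is tested by LRT of the
    full model against the model without it."""
    terms = _check_terms(terms)
    full = _fit(records, terms, family, response)
    table: dict[Term, LRTResult] = {}
    for t in deletable_terms(terms):
        reduced_terms = tuple(u for u in terms if u != t)
        reduced = _fit(records, reduced_terms, family, response)
        table[t] = lrt(full, reduced)
    return table


def stepwise_simplify(
    records: pd.DataFrame,
    terms: Sequence[Term],
    alpha: float = 0.05,
    family: str = "multinomial",
    response: str | None = None,
) -> ModelFit:
    """Backward stepwise deletion: repeatedly drop the least significant
    deletable term with p > alpha (highest-order interactions first by
    construction of deletability), refit, stop when every remaining
    deletable term is significant."""
    current = _check_terms(terms)
    while True:
        table = type3_terms(records, current, family, response)
        droppable = [(t, r.p) for t, r in table.items() if r.p > alpha]
        if not droppable:
            break
        worst = max(droppable, key=lambda tp: tp[1])[0]
        current = tuple(t for t in current if t != worst)
    return _fit(records, current, family, response)


# ---------------------------------------------------------------------------
# Fisher-Pitman permutation test


def fisher_pitman(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 10000,
    seed: int = 0,
    exact_max_n: int = 10,
) -> PermutationResult:
    """Two-sample Fisher-Pitman permutation test.

    The statistic is the standardized group-sum difference Z; the p-value is
    the two-sided permutation tail probability, computed by exhaustive
    enumeration of label assignments when the pooled sample size is at most
    ``exact_max_n`` and by Monte Carlo otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    z = np.concatenate([x, y])
    n, nx = len(z), len(x)
    mu = nx * z.mean()
    var = nx * (n - nx) / (n * (n - 1)) * ((z - z.mean()) ** 2).sum()
    T = x.sum()
    if var <= 0:
        return PermutationResult(statistic=0.0, n_permutations=0, p=1.0)
    Z = (T - mu) / math.sqrt(var)
    t_obs = abs(T - mu) - 1e-9

    if n <= exact_max_n:
        sums = np.array(
            [z[list(idx)].sum() for idx in itertools.combinations(range(n), nx)]
        )
        p = float(np.mean(np.abs(sums - mu) >= t_obs))
        return PermutationResult(statistic=Z, n_permutations=len(sums), p=p)

    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 in Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    count = 0
    block = 20000
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perm = rng.permuted(np.broadcast_to(z, (b, n)), axis=1)
        sums = perm[:, :nx].sum(axis=1)
        count += int(np.sum(np.abs(sums - mu) >= t_obs))
        done += b
    p = (1 + count) / (1 + n_permutations)
    return PermutationResult(statistic=Z, n_permutations=n_permutations, p=p)


# ---------------------------------------------------------------------------
# senescence


def senescence_compare(
    records: pd.DataFrame,
    rounding: str = "nearest",
) -> tuple[ModelFit, ModelFit, LRTResult, pd.DataFrame]:
    """Reproductive-senescence ANCOVA on mean ovarioles vs age.

    Fits the interaction model (age + cross + age x cross) and the additive
    model (age + cross) as Poisson GLMs and tests the age x cross interaction
    by LRT. Returns both fits, the LRT, and per-cross intercepts/slopes on
    the log scale.
    """
    df = poisson_response(records, rounding=rounding)
    if df["cross"].nunique() < 2:
        raise ValueError("need at least two crosses")
    if df["age"].nunique() < 2:
        raise ValueError("need at least two ages")
    full_terms = ((), ("age",), ("cross",), ("age", "cross"))
    red_terms = ((), ("age",), ("cross",))
    full = fit_poisson(df, full_terms)
    reduced = fit_poisson(df, red_terms)
    result = lrt(full, reduced)

    coef = full.coefficients["coef"]
    levels = sorted(df["cross"].astype(str).unique())
    base_int = coef["intercept"]
    base_slope = coef["age"]
    rows = []
    for lev in levels:
        d_int = coef.get(f"cross[{lev}]", 0.0)
        d_slope = coef.get(f"age:cross[{lev}]", 0.0)
        rows.append(
            {
                "cross": lev,
                "intercept": base_int + d_int,
                "slope": base_slope + d_slope,
                "intercept_contrast": d_int,
                "slope_contrast": d_slope,
            }
        )
    return full, reduced, result, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deviance explained and bootstrap comparison


def dsquared(fit: ModelFit) -> float:
    """Deviance explained, (null - residual)/null: the GLM analogue of R^2.

    0 for an intercept-only fit, 1 for a saturated fit; NaN (undefined) when
    the null deviance is zero.
    """
    if fit.null_deviance <= 0:
        return float("nan")
    return (fit.null_deviance - fit.residual_deviance) / fit.null_deviance


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (w - mu) / sd if sd > 0 else 0.0


def bootstrap_r2_compare(
    records_a: pd.DataFrame,
    terms_a: Sequence[Term],
    records_b: pd.DataFrame,
    terms_b: Sequence[Term],
    n_boot: int = 500,
    seed: int = 0,
    family: str = "poisson",
    response: str | None = None,
    n_permutations: int = 2000,
) -> tuple[PermutationResult, np.ndarray, np.ndarray]:
    """Compare deviance explained between two datasets/models by bootstrap.

    Each dataset is resampled with replacement ``n_boot`` times and its model
    refitted, giving two D-squared distributions; these are compared with a
    two-sided permutation Wilcoxon rank-sum test. Returns the test result
    and both bootstrap distributions.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b, rng_p = (np.random.default_rng(s) for s in ss.spawn(3))

    def _boot(df: pd.DataFrame, terms, rng) -> np.ndarray:
        vals = np.empty(n_boot)
        n = len(df)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            vals[i] = dsquared(_fit(df.iloc[idx], terms, family, response))
        return vals

    d2_a = _boot(records_a, _check_terms(terms_a), rng_a)
    d2_b = _boot(records_b, _check_terms(terms_b), rng_b)

    z_obs = _rank_sum_z(d2_a, d2_b)
    pooled = np.concatenate([d2_a, d2_b])
    count = 0
    for _ in range(n_permutations):
        perm = rng_p.permutation(pooled)
        if abs(_rank_sum_z(perm[: len(d2_a)], perm[len(d2_a) :])) >= abs(z_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermutationResult(statistic=z_obs, n_permutations=n_permutations, p=p), d2_a, d2_b


# ---------------------------------------------------------------------------
# summaries


def hd_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cross dysgenesis summary.

    For each (mother genotype, father type, temperature): counts of females
    with 0/1/2 ovaries, the dysgenic fraction (at least one atrophied
    ovary), and mean +/- SD ovarioles among females with functional ovaries.
    """
    rows = []
    for (mg, ft, temp), grp in records.groupby(
        ["mother_genotype", "father_type", "temperature"], sort=True
    ):
        counts = grp["ovary_count"].value_counts()
        ov = grp["mean_ovarioles"].dropna()
        rows.append(
            {
                "mother_genotype": mg,
                "father_type": ft,
                "temperature": temp,
                "cross": f"{mg}x{ft}",
                "n": len(grp),
                "n_ovary0": int(counts.get(0, 0)),
                "n_ovary1": int(counts.get(1, 0)),
                "n_ovary2": int(counts.get(2, 0)),
                "dysgenic_fraction": float((grp["ovary_count"] < 2).mean()),
                "mean_ovarioles": float(ov.mean()) if len(ov) else float("nan"),
                "sd_ovarioles": float(ov.std()) if len(ov) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
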