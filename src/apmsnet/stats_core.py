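"""Statistical kernels shared by the pipeline.

Implemented here rather than delegated wholesale: missingness
classification, the mixed imputation strategies, the empirical-Bayes
moderated two-group t-test, Benjamini-Hochberg and Hommel multiple-testing
adjustments, Type-II factorial ANOVA and Tukey-Kramer honest significant
differences.  scipy supplies distributions (t, studentized range) and
scikit-learn the kNN imputer that backs the MAR strategy.

Moderated t
-----------
Per protein, the pooled two-group variance ``s^2`` (df ``d``) is shrunk
toward a prior ``s0^2`` with prior df ``d0``::

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod    = log_fc / (s_post * sqrt(1/nA + 1/nB))

referred to a t-distribution on ``d + d0`` degrees of freedom.  The prior
(d0, s0^2) is estimated by method of moments on the log sample variances:
with ``e_g = log s_g^2 - psi(d/2) + log(d/2)`` one has ``Var(e) =
psi'(d/2) + psi'(d0/2)`` and ``E(e) = log s0^2 - psi(d0/2) + log(d0/2)``,
so d0 follows from inverting the trigamma function and s0^2 from the mean.
In the limit d0 -> 0 the statistic is the classical pooled t.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

D0_CAP = 1e6  # numerical cap on the prior degrees of freedom

# --------------------------------------------------------------------- #
# missingness classification
# --------------------------------------------------------------------- #
def classify_missingness(
    intensity: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Label each (protein, group) cell block as MNAR, MAR or complete.

    A protein is MNAR in a group iff it is missing in *all* runs of that
    group while observed in at least one run of some other group (the
    below-detection pattern).  Any other missing cells are MAR; a block
    with no missing cells is complete.
    """
    labels = pd.DataFrame(index=intensity.index, columns=list(groups), dtype=object)
    observed_any = intensity.notna().any(axis=1)
    for gname, runs in groups.items():
        block = intensity[list(runs)]
        n_missing = block.isna().sum(axis=1)
        all_missing = n_missing == len(runs)
        observed_elsewhere = (
            intensity.drop(columns=list(runs)).notna().any(axis=1)
            if intensity.shape[1] > len(runs)
            else pd.Series(False, index=intensity.index)
        )
        lab = np.where(
            n_missing == 0,
            "complete",
            np.where(all_missing & observed_elsewhere, "MNAR", "MAR"),
        )
        labels[gname] = lab
    del observed_any
    return labels


def _missing_cell_masks(
    intensity: pd.DataFrame,
    labels: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean cell masks (proteins x runs) for MNAR and MAR missing cells."""
    miss = intensity.isna()
    mnar = pd.DataFrame(False, index=intensity.index, columns=intensity.columns)
    for gname, runs in groups.items():
        is_mnar = (labels[gname] == "MNAR").to_numpy()
        mnar.loc[is_mnar, list(runs)] = miss.loc[is_mnar, list(runs)]
    mar = miss & ~mnar
    return mnar, mar


# --------------------------------------------------------------------- #
# imputation
# --------------------------------------------------------------------- #
def _impute_knn(X: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-nearest-neighbour imputation among proteins (rows): Euclidean
    distance on shared observed runs, distance-weighted neighbour mean.
    Falls back to column medians when fewer than k neighbour proteins
    exist."""
    if X.shape[0] - 1 < k:
        warnings.warn(
            f"fewer than k={k} neighbour proteins; falling back to column medians",
            stacklevel=2,
        )
        med = X.median(axis=0)
        return X.fillna(med)
    from sklearn.impute import KNNImputer

    imputer = KNNImputer(n_neighbors=k, weights="distance")
    filled = imputer.fit_transform(X.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=X.index, columns=X.columns)
    # columns that were entirely missing come back dropped by sklearn; guard
    if out.isna().any().any():  # pragma: no cover - defensive
        out = out.fillna(out.stack().median())
    return out


def _impute_minprob(
    X: pd.DataFrame, rng: np.random.Generator, q: float = 0.01
) -> pd.DataFrame:
    """MinProb-style draws: per run, Normal(q-quantile of the run's observed
    distribution, median of the per-run SDs)."""
    scale = float(np.nanmedian(X.std(axis=0, skipna=True).to_numpy()))
    if not np.isfinite(scale) or scale <= 0:
        scale = 0.1
    out = X.copy()
    for col in X.columns:
        vals = X[col]
        n_miss = int(vals.isna().sum())
        if n_miss == 0:
            continue
        observed = vals.dropna()
        loc = float(observed.quantile(q)) if len(observed) else float(np.nanmin(X.to_numpy()))
        out.loc[vals.isna(), col] = rng.normal(loc, scale, n_miss)
    return out


def _impute_ppca(
    X: pd.DataFrame, n_components: int = 2, tol: float = 1e-6, max_iter: int = 500
) -> pd.DataFrame:
    """EM-style low-rank imputation: alternate a rank-``n_components`` SVD
    reconstruction with refilling the missing cells, to convergence.
    Deterministic (initialised from row means)."""
    A = X.to_numpy(dtype=float).copy()
    miss = np.isnan(A)
    if not miss.any():
        return X.copy()
    row_mean = np.nanmean(np.where(miss, np.nan, A), axis=1)
    row_mean = np.where(np.isfinite(row_mean), row_mean, np.nanmean(A))
    fill = np.take(row_mean, np.nonzero(miss)[0])
    A[miss] = fill
    prev = A[miss].copy()
    for _ in range(max_iter):
        mu = A.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(A - mu, full_matrices=False)
        k = min(n_components, len(s))
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        A[miss] = recon[miss]
        delta = np.max(np.abs(A[miss] - prev)) if miss.any() else 0.0
        if delta < tol:
            break
        prev = A[miss].copy()
    return pd.DataFrame(A, index=X.index, columns=X.columns)


def impute(
    intensity: pd.DataFrame,
    labels: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    strategy_mar: str = "knn",
    strategy_mnar: str = "zero_floor",
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mixed imputation on a log2 matrix: MAR cells by ``knn`` or
    ``minprob``, MNAR cells by ``zero_floor`` (global observed minimum, a
    below-detection floor) or ``ppca``.  Observed cells are untouched."""
    if strategy_mar not in {"knn", "minprob"}:
        raise ValueError(f"unknown MAR strategy {strategy_mar!r}")
    if strategy_mnar not in {"zero_floor", "ppca"}:
        raise ValueError(f"unknown MNAR strategy {strategy_mnar!r}")
    if not intensity.isna().any().any():
        return intensity.copy()
    mnar_cells, mar_cells = _missing_cell_masks(intensity, labels, groups)
    rng = np.random.default_rng(seed)
    out = intensity.copy()

    if mar_cells.any().any():
        if strategy_mar == "knn":
            filled = _impute_knn(intensity, k=k)
        else:
            filled = _impute_minprob(intensity, rng)
        out = out.mask(mar_cells, filled)

    if mnar_cells.any().any():
        if strategy_mnar == "zero_floor":
            floor = float(np.nanmin(intensity.to_numpy(dtype=float)))
            out = out.mask(mnar_cells, floor)
        else:
            filled = _impute_ppca(out)
            out = out.mask(mnar_cells, filled)
    return out


# --------------------------------------------------------------------- #
# moderated t
# --------------------------------------------------------------------- #
@dataclasses.dataclass
class ModeratedTestResult:
    log_fc: float
    s2_pooled: float
    s2_prior: float
    df_prior: float
    t_mod: float
    df_total: float
    p: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return D0_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x + dif, 1e-8)
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on the log sample variances."""
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return 0.0, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(excess), D0_CAP)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


def moderated_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    d0: float = 0.0,
    s0_sq: float = 1.0,
) -> ModeratedTestResult:
    """Moderated two-group t for one protein, with an explicit prior.

    With ``d0=0`` this is exactly the classical pooled two-sample t.
    ``log_fc`` is mean(A) - mean(B) on the (log2) input scale.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least two values per group")
    df = na + nb - 2
    log_fc = float(a.mean() - b.mean())
    s2 = float(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t_mod = log_fc / se if se > 0 else np.inf * np.sign(log_fc)
    df_total = df + d0
    p = float(2.0 * stats.t.sf(abs(t_mod), df_total))
    return ModeratedTestResult(
        log_fc=log_fc,
        s2_pooled=s2,
        s2_prior=s0_sq,
        df_prior=d0,
        t_mod=float(t_mod),
        df_total=float(df_total),
        p=p,
    )


def moderated_t_table(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Vectorised moderated t across proteins (rows of ``A`` and ``B``).

    The variance prior is fitted by method of moments across all rows.
    Returns a frame with ``log_fc``, ``s2_pooled``, ``t``, ``df_total``,
    ``p`` and the fitted prior as attributes ``d0`` / ``s0_sq`` in
    ``DataFrame.attrs``.
    """
    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least two runs per group")
    df = na + nb - 2
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    d0, s0_sq = fit_variance_prior(s2, df)
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, np.inf * np.sign(log_fc))
    df_total = df + d0
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame(
        {
            "log_fc": log_fc,
            "s2_pooled": s2,
            "t": t_mod,
            "df_total": df_total,
            "p": p,
        },
        index=A.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


# --------------------------------------------------------------------- #
# multiple-testing adjustments
# --------------------------------------------------------------------- #
def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def adjust_hommel(p: np.ndarray) -> np.ndarray:
    """Hommel FWER adjustment (standard closed algorithm)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n <= 1:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, n + 1)
    q = np.full(n, min(np.min(n * ps / i), 1.0))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)          # first n-m+1 positions
        i2 = np.arange(n - m + 1, n)       # remaining m-1 positions
        q1 = np.min(m * ps[i2] / np.arange(2, m + 1))
        q[i1] = np.minimum(m * ps[i1], q1)
        q[i2] = q[i1[-1]]
        pa = np.maximum(pa, q)
    adj = np.minimum(np.maximum(pa, ps), 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# --------------------------------------------------------------------- #
# factorial ANOVA (Type II) and Tukey HSD
# --------------------------------------------------------------------- #
@dataclasses.dataclass
class AnovaResult:
    """Type-II factorial ANOVA table plus what Tukey tests need."""

    table: pd.DataFrame  # index effect; columns sum_sq, df, F, p
    df_resid: float
    ss_resid: float
    notes: list[str]
    data: pd.DataFrame  # original long frame (value + factor columns)
    factors: list[str]
    response: str = "value"
    degenerate: bool = False


def _dummy(values: pd.Series) -> np.ndarray:
    levels = pd.unique(values)
    return (values.to_numpy()[:, None] == np.asarray(levels)[None, :]).astype(float)


def _term_columns(data: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    cols = _dummy(data[term[0]])
    for f in term[1:]:
        d = _dummy(data[f])
        cols = np.einsum("ij,ik->ijk", cols, d).reshape(len(data), -1)
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the design via lstsq."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def factorial_anova(
    data: pd.DataFrame,
    factors: Sequence[str],
    response: str = "value",
    include_interactions: bool = True,
) -> AnovaResult:
    """Factorial ANOVA with Type-II sums of squares.

    ``data`` is a long frame: one response column plus one column per
    factor.  All interaction orders among ``factors`` are included where
    estimable; aliased terms (no rank contribution over the Type-II base
    model) are dropped with a note.  Type-II SS of term T compares the
    model of all terms not containing T against the same model plus T.
    """
    factors = list(factors)
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    terms: list[tuple[str, ...]] = []
    orders = range(1, len(factors) + 1) if include_interactions else [1]
    for k in orders:
        terms.extend(combinations(factors, k))

    cols = {t: _term_columns(data, t) for t in terms}
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [cols[t] for t in terms])
    ss_resid, rank_full = _rss(X_full, y)
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    notes: list[str] = []
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = ss_resid <= 1e-10 * max(tss, 1.0)
    if degenerate:
        notes.append("residual SS ~ 0: F statistics are degenerate")
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rows = []
    for t in terms:
        base_terms = [u for u in terms if not set(t) <= set(u)]
        X_base = np.hstack([intercept] + [cols[u] for u in base_terms])
        X_with = np.hstack([X_base, cols[t]])
        rss_base, rank_base = _rss(X_base, y)
        rss_with, rank_with = _rss(X_with, y)
        df_t = rank_with - rank_base
        if df_t == 0:
            notes.append(f"term {':'.join(t)} aliased; dropped")
            continue
        ss_t = max(rss_base - rss_with, 0.0)
        if degenerate or ms_resid <= 0:
            F = np.nan
            pval = np.nan
        else:
            F = (ss_t / df_t) / ms_resid
            pval = float(stats.f.sf(F, df_t, df_resid))
        rows.append(
            {"effect": ":".join(t), "sum_sq": ss_t, "df": df_t, "F": F, "p": pval}
        )
    table = pd.DataFrame(rows).set_index("effect") if rows else pd.DataFrame(
        columns=["sum_sq", "df", "F", "p"]
    )
    return AnovaResult(
        table=table,
        df_resid=float(df_resid),
        ss_resid=ss_resid,
        notes=notes,
        data=data,
        factors=factors,
        response=response,
        degenerate=degenerate,
    )


def tukey_hsd(anova: AnovaResult, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons for one factor's levels.

    p-values come from the studentized-range distribution with the ANOVA's
    residual df; confidence intervals at level ``1 - alpha``.  Collective
    BH correction across many Tukey families is applied by the caller.
    """
    if factor not in anova.data.columns:
        raise ValueError(f"factor {factor!r} not in the ANOVA data")
    groups = anova.data.groupby(factor)[anova.response]
    means = groups.mean()
    sizes = groups.size()
    levels = list(means.index)
    k = len(levels)
    mse = anova.ss_resid / anova.df_resid
    rows = []
    for la, lb in combinations(levels, 2):
        diff = float(means[la] - means[lb])
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[la] + 1.0 / sizes[lb]))
        if se == 0:
            qstat, pval = np.inf, 0.0
            ci_half = 0.0
        else:
            qstat = abs(diff) / se
            pval = float(stats.studentized_range.sf(qstat, k, anova.df_resid))
            qcrit = stats.studentized_range.ppf(1 - alpha, k, anova.df_resid)
            ci_half = float(qcrit * se)
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "diff": diff,
                "ci_low": diff - ci_half,
                "ci_high": diff + ci_half,
                "p": min(max(pval, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)
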