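"""Group comparisons, longitudinal trends and correlation networks.

Three model families cover the study's statistics:

* single-timepoint group contrasts: a linear mixed model of the metric on
  exposure group plus clinical covariates with a random intercept per
  enrolment site, fitted by REML;
* longitudinal exposure trends: an additive model with natural cubic-spline
  smooths (basis size ``k = 4``) for days of azithromycin and each of the six
  common co-antibiotics, a smooth for days from admission, linear covariate
  terms and a patient-level random intercept; the azithromycin smooth is
  tested by a likelihood-ratio comparison of ML-fitted nested models (REML
  likelihoods are not comparable across fixed-effect structures);
* taxa x ARG correlation networks: Spearman correlations between the 30 most
  abundant genera (by summed RPM) and MLS gene DPM, BH-adjusted over all
  pairs, with edges where rho > 0.2 and q < 0.05.

Rank-based two-group comparisons use the Wilcoxon rank-sum statistic with
midranks for ties, an exact enumeration null for small samples (combined
n <= 12) and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "bh_adjust",
    "pairwise_rank_test",
    "fold_change",
    "natural_cubic_basis",
    "fit_group_model",
    "fit_exposure_trend",
    "spearman_network",
    "top_features",
]

CO_ABX_COLUMNS = (
    "vancomycin_days",
    "ceftriaxone_days",
    "cefepime_days",
    "piperacillin-tazobactam_days",
    "doxycycline_days",
    "meropenem_days",
)


@dataclass
class AssociationResult:
    """Tidy model output: one row per term with estimate, se, p and BH q."""

    table: pd.DataFrame
    n_per_group: dict[str, int] = field(default_factory=dict)
    curve: pd.DataFrame | None = None
    lrt: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# elementary procedures


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank_sum_exact_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact p by enumeration of all group-label assignments."""
    n = ranks.size
    w_obs = ranks[:n1].sum()
    total = 0
    le = 0
    ge = 0
    for comb in itertools.combinations(range(n), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def pairwise_rank_test(x, y, exact_limit: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks for ties.

    Exact enumeration when the combined sample size is at most
    ``exact_limit``; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n <= exact_limit:
        return _rank_sum_exact_p(ranks, n1)
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return 1.0
    z = (w - mean_w - np.sign(w - mean_w) * 0.5) / np.sqrt(var_w)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def fold_change(a, b) -> float:
    """Ratio of arithmetic group means, ``mean(a) / mean(b)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mb = b.mean()
    if mb == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    return float(a.mean() / mb)


def top_features(table, n: int = 30) -> list[str]:
    """The ``n`` most abundant features by column sum of a feature table."""
    values = table.values if hasattr(table, "values") and hasattr(table, "value_kind") else table
    sums = values.sum(axis=0)
    return list(sums.sort_values(ascending=False, kind="mergesort").index[:n])


# ---------------------------------------------------------------------------
# spline basis


def natural_cubic_basis(x, k: int = 4, knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic regression-spline basis (no intercept column).

    ``k`` interior+boundary knots are placed at evenly spaced quantiles of
    the unique values of ``x`` (the usual 'cr' placement); the basis spans
    ``k - 1`` columns: the linear term plus ``k - 2`` curvature terms with
    natural (linear-beyond-boundary) tails.  With fewer unique values than
    knots the basis degrades gracefully: the linear term alone for 2-3
    unique values, and an empty basis (with a warning) for a constant.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        uniq = np.unique(x)
        if uniq.size < 2:
            warnings.warn("constant covariate: empty spline basis")
            return np.empty((x.size, 0))
        if uniq.size < k:
            warnings.warn(
                f"only {uniq.size} unique values; spline basis shrunk to linear"
            )
            return (x - x.mean()).reshape(-1, 1)
        knots = np.quantile(uniq, np.linspace(0, 1, k))
        knots = np.unique(knots)
        if knots.size < 3:
            return (x - x.mean()).reshape(-1, 1)
    kn = np.asarray(knots, dtype=float)
    K = kn.size

    def d(j: int, t: np.ndarray) -> np.ndarray:
        num = np.clip(t - kn[j], 0, None) ** 3 - np.clip(t - kn[K - 1], 0, None) ** 3
        return num / (kn[K - 1] - kn[j])

    cols = [x - x.mean()]
    for j in range(K - 2):
        cols.append(d(j, x) - d(K - 2, x))
    basis = np.column_stack(cols)
    # center curvature columns for a well-scaled design
    basis[:, 1:] -= basis[:, 1:].mean(axis=0)
    return basis


# ---------------------------------------------------------------------------
# mixed models


def _fit_mixed(model, reml: bool):
    """Fit a MixedLM, falling back across optimizers on numerical failure."""
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=reml, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_err = exc
    raise last_err


def _encode_covariates(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns for the stated covariates (dummies for strings)."""
    cols = {}
    for c in covariates:
        col = data[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (col.astype(str) == lev).astype(float)
        elif col.dtype == bool:
            cols[c] = col.astype(float)
        else:
            cols[c] = col.astype(float)
    return pd.DataFrame(cols, index=data.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name one offending column for the error message
        bad = []
        cum = X.iloc[:, :1]
        for c in X.columns[1:]:
            cand = pd.concat([cum, X[c]], axis=1)
            if np.linalg.matrix_rank(cand.to_numpy()) == cum.shape[1]:
                bad.append(c)
            else:
                cum = cand
        raise ValueError(f"singular design; collinear column(s): {bad}")


def fit_group_model(
    data: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    reference: str = "No-Abx",
    covariates: Sequence[str] = (),
    random_effect: str | None = "site_id",
    bh_family: Sequence[str] | None = None,
) -> AssociationResult:
    """Linear mixed model of a metric on exposure group with a site random intercept.

    Group contrasts are coded against ``reference``; their p-values are
    BH-adjusted (optionally within a caller-supplied family of extra
    p-values via ``bh_family`` — the returned q then reflects that family).
    With ``random_effect=None`` the model reduces to ordinary least squares.
    """
    import statsmodels.api as sm

    data = data.copy()
    groups = sorted(data[group_col].astype(str).unique())
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    contrast_cols = {}
    for g in groups:
        if g != reference:
            contrast_cols[f"{group_col}[{g}]"] = (
                data[group_col].astype(str) == g
            ).astype(float)
    X = pd.concat(
        [
            pd.Series(1.0, index=data.index, name="Intercept"),
            pd.DataFrame(contrast_cols, index=data.index),
            _encode_covariates(data, covariates),
        ],
        axis=1,
    )
    _check_full_rank(X)
    y = data[metric].astype(float)
    if random_effect is None:
        fit = sm.OLS(y, X).fit()
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
    else:
        fit = _fit_mixed(sm.MixedLM(y, X, groups=data[random_effect].astype(str)), reml=True)
        params = fit.params[X.columns]
        bse = fit.bse[X.columns]
        pvalues = fit.pvalues[X.columns]
    table = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": params.to_numpy(),
            "se": bse.to_numpy(),
            "p": pvalues.to_numpy(),
        }
    )
    is_contrast = table["term"].str.startswith(f"{group_col}[")
    fam_p = table.loc[is_contrast, "p"].to_numpy()
    if bh_family is not None:
        fam_p = np.concatenate([fam_p, np.asarray(bh_family, dtype=float)])
    q_fam = bh_adjust(fam_p)
    table["q"] = np.nan
    table.loc[is_contrast, "q"] = q_fam[: int(is_contrast.sum())]
    n_per_group = data.groupby(group_col)[metric].size().to_dict()
    return AssociationResult(table=table, n_per_group=n_per_group)


def fit_exposure_trend(
    data: pd.DataFrame,
    metric: str,
    exposure_col: str = "azithro_days",
    co_abx_cols: Sequence[str] = CO_ABX_COLUMNS,
    time_col: str = "day_from_admission",
    covariates: Sequence[str] = ("trajectory_group", "sex", "age_quintile", "steroids_ever"),
    patient_col: str = "patient_id",
    k: int = 4,
    max_day: int = 10,
    max_exposure: int = 5,
    curve_points: int = 51,
) -> AssociationResult:
    """Additive exposure-trend model with spline smooths and a patient intercept.

    Samples are restricted to the first ``max_day`` days of hospitalization
    and ``max_exposure`` days of the exposure of interest (longer courses are
    rare).  Each antibiotic's days-of-exposure enters through a natural
    cubic-spline basis of size ``k``; the significance of the azithromycin
    smooth is a likelihood-ratio test between ML fits with and without its
    columns.  Returns the fitted exposure-response curve with a pointwise
    95% interval (other terms held at their sample means).
    """
    import statsmodels.api as sm

    data = data[(data[time_col] <= max_day) & (data[exposure_col] <= max_exposure)]
    data = data.reset_index(drop=True)
    if data.empty:
        raise ValueError("no samples left after day/exposure restriction")

    uniq = np.unique(data[exposure_col].to_numpy(dtype=float))
    knots = (
        np.quantile(uniq, np.linspace(0, 1, k)) if uniq.size >= k else None
    )
    smooth_blocks: dict[str, np.ndarray] = {}
    exp_basis = natural_cubic_basis(data[exposure_col], k=k, knots=np.unique(knots) if knots is not None else None)
    smooth_blocks[exposure_col] = exp_basis
    for c in co_abx_cols:
        smooth_blocks[c] = natural_cubic_basis(data[c], k=k)
    smooth_blocks[time_col] = natural_cubic_basis(data[time_col], k=k)

    pieces = [pd.Series(1.0, index=data.index, name="Intercept")]
    for name, block in smooth_blocks.items():
        for i in range(block.shape[1]):
            pieces.append(pd.Series(block[:, i], index=data.index, name=f"s({name}).{i}"))
    pieces.append(_encode_covariates(data, covariates))
    X = pd.concat(pieces, axis=1)
    # drop exactly collinear columns rather than failing: degenerate synthetic
    # designs (e.g. an antibiotic nobody received) yield all-zero blocks
    keep = [c for c in X.columns if X[c].abs().sum() > 0]
    X = X[keep]
    y = data[metric].astype(float)
    groups = data[patient_col].astype(str)

    exp_cols = [c for c in X.columns if c.startswith(f"s({exposure_col}).")]
    X_red = X.drop(columns=exp_cols)

    def _ml_fit(design: pd.DataFrame):
        return _fit_mixed(sm.MixedLM(y, design, groups=groups), reml=False)

    full = _ml_fit(X)
    reduced = _ml_fit(X_red)
    lrt_stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = len(exp_cols)
    lrt_p = float(stats.chi2.sf(lrt_stat, df)) if df > 0 else 1.0

    table = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": full.params[X.columns].to_numpy(),
            "se": full.bse[X.columns].to_numpy(),
            "p": full.pvalues[X.columns].to_numpy(),
        }
    )
    table["q"] = np.nan

    # fitted exposure-response curve: vary the exposure smooth, hold the rest
    grid = np.linspace(0, data[exposure_col].max(), curve_points)
    if knots is not None and np.unique(knots).size >= 3:
        grid_basis = natural_cubic_basis(
            np.concatenate([data[exposure_col].to_numpy(dtype=float), grid]),
            knots=np.unique(knots),
        )[-grid.size:]
    else:
        gb = natural_cubic_basis(
            np.concatenate([data[exposure_col].to_numpy(dtype=float), grid])
        )
        grid_basis = gb[-grid.size:] if gb.shape[1] else np.empty((grid.size, 0))
    x_mean = X.mean(axis=0)
    design = pd.DataFrame(
        np.tile(x_mean.to_numpy(), (grid.size, 1)), columns=X.columns
    )
    for i, c in enumerate(exp_cols):
        design[c] = grid_basis[:, i]
    beta = full.params[X.columns].to_numpy()
    cov = pd.DataFrame(full.cov_params(), index=full.params.index,
                       columns=full.params.index).loc[X.columns, X.columns].to_numpy()
    pred = design.to_numpy() @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", design.to_numpy(), cov, design.to_numpy()))
    curve = pd.DataFrame(
        {
            exposure_col: grid,
            "fit": pred,
            "lo": pred - 1.96 * se,
            "hi": pred + 1.96 * se,
        }
    )
    return AssociationResult(
        table=table,
        curve=curve,
        lrt={"stat": float(lrt_stat), "df": float(df), "p": lrt_p},
    )


# ---------------------------------------------------------------------------
# correlation network


def spearman_network(
    taxa_table,
    arg_table,
    rho_threshold: float = 0.2,
    q_threshold: float = 0.05,
    top_n: int | None = 30,
) -> pd.DataFrame:
    """Spearman correlations between taxon RPM and ARG DPM, with edge calls.

    Both tables must cover the same samples.  When ``top_n`` is given, taxa
    are first restricted to the ``top_n`` most abundant by summed RPM.
    Returns all pairs with rho, two-sided p, BH q over the pairs, and
    ``edge = (rho > rho_threshold) & (q < q_threshold)``; pairs involving a
    constant vector are flagged undefined and excluded from the BH family.
    """
    tx = taxa_table.values if hasattr(taxa_table, "value_kind") else taxa_table
    ar = arg_table.values if hasattr(arg_table, "value_kind") else arg_table
    if list(tx.index) != list(ar.index):
        common = tx.index.intersection(ar.index)
        if len(common) == 0:
            raise ValueError("tables share no samples")
        tx, ar = tx.loc[common], ar.loc[common]
    if top_n is not None:
        tx = tx[top_features(tx, top_n)]
    rows = []
    for taxon in tx.columns:
        u = tx[taxon].to_numpy(dtype=float)
        for gene in ar.columns:
            v = ar[gene].to_numpy(dtype=float)
            if np.all(u == u[0]) or np.all(v == v[0]):
                rows.append((taxon, gene, np.nan, np.nan, True))
                continue
            rho, p = stats.spearmanr(u, v)
            rows.append((taxon, gene, float(rho), float(p), False))
    out = pd.DataFrame(rows, columns=["taxon", "gene", "rho", "p", "undefined"])
    out["q"] = np.nan
    defined = ~out["undefined"]
    out.loc[defined, "q"] = bh_adjust(out.loc[defined, "p"].to_numpy())
    out["edge"] = defined & (out["rho"] > rho_threshold) & (out["q"] < q_threshold)
    return out
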