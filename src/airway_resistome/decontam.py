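"""Negative-binomial background/batch decontamination.

Water (negative-control) samples are sequenced alongside biological samples
in each processing batch.  Counts of each feature (taxon or ARG) in the
controls of a batch define a contamination null: a negative binomial with

* a per ``(batch, feature)`` mean — the arithmetic mean of that feature's
  counts over the batch's controls, and
* a single dispersion parameter ``theta`` shared across all features,
  estimated by maximizing the pooled profile log-likelihood with the cell
  means held at their sample means.

A biological sample's count is then tested against its batch's cell with an
upper-tail p-value; Benjamini–Hochberg adjustment is applied (within each
sample by default) and only features significantly above the null
(``q < fdr``, default 0.1) are retained.  A feature never seen in a batch's
controls carries no contamination evidence: any positive count is retained
and flagged ``unseen_in_controls`` rather than entering the BH family
(a zero mean would otherwise force ``p = 0`` artifacts).

Parameterization: ``X ~ NB(mean=mu, size=theta)`` with
``Var X = mu + mu**2 / theta``; ``theta -> inf`` is the Poisson limit.
Taxa and ARGs are decontaminated as two separate runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_data import FeatureTable
from .association_stats import bh_adjust

__all__ = ["NullModel", "DecontamResult", "fit_null", "tail_pvalue", "apply_decontam"]

THETA_MIN = 1e-3
THETA_MAX = 1e6


@dataclass
class NullModel:
    """Contamination null: per (batch, feature) means plus one shared dispersion."""

    mu: dict[tuple[str, str], float]
    theta: float
    fitted_on: dict[str, int]  # batch -> number of control samples
    theta_at_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")

    def mean_for(self, batch: str, feature: str) -> float:
        return self.mu.get((batch, feature), 0.0)


@dataclass
class DecontamResult:
    """Per (sample, feature) decisions from one decontamination run."""

    decisions: pd.DataFrame  # sample_id, feature, count, batch, mu, p, q, retained, unseen_in_controls
    fdr: float
    family: str

    def retained_pairs(self) -> set[tuple[str, str]]:
        kept = self.decisions[self.decisions["retained"]]
        return set(zip(kept["sample_id"], kept["feature"]))


def _nb_loglik(counts: np.ndarray, means: np.ndarray, theta: float) -> float:
    """Pooled NB log-likelihood over observations with positive cell means."""
    x = counts
    mu = means
    return float(
        np.sum(
            special.gammaln(x + theta)
            - special.gammaln(theta)
            - special.gammaln(x + 1)
            + theta * np.log(theta / (theta + mu))
            + x * np.log(mu / (theta + mu))
        )
    )


def fit_null(control_tables: dict[str, FeatureTable]) -> NullModel:
    """Fit the contamination null from per-batch negative-control tables.

    ``control_tables`` maps batch label to a reads-kind :class:`FeatureTable`
    whose rows are that batch's negative controls.  Cells whose control mean
    is zero put all null mass at zero and are excluded from the dispersion
    optimization.
    """
    mu: dict[tuple[str, str], float] = {}
    fitted_on: dict[str, int] = {}
    counts_list: list[np.ndarray] = []
    means_list: list[np.ndarray] = []
    n_controls = 0
    for batch, table in control_tables.items():
        if table.value_kind != "reads":
            raise ValueError("decontamination nulls are fitted on raw read counts")
        mat = table.values.to_numpy(dtype=float)
        n_controls += mat.shape[0]
        fitted_on[batch] = mat.shape[0]
        cell_means = mat.mean(axis=0)
        for feature, m in zip(table.features, cell_means):
            mu[(batch, feature)] = float(m)
        pos = cell_means > 0
        if pos.any():
            counts_list.append(mat[:, pos].ravel())
            means_list.append(np.broadcast_to(cell_means[pos], mat[:, pos].shape).ravel())
    if n_controls < 2:
        raise ValueError("need at least 2 negative-control samples to fit the null")
    if not counts_list:
        raise ValueError("no contamination signal; theta undefined")
    counts = np.concatenate(counts_list)
    means = np.concatenate(means_list)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("control counts must be non-negative integers")

    # 1-D profile likelihood in log(theta), bracketed to [THETA_MIN, THETA_MAX].
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik(counts, means, float(np.exp(lt))),
        bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(np.exp(res.x))
    at_boundary = theta >= THETA_MAX * 0.99 or theta <= THETA_MIN * 1.01
    if at_boundary:
        # zero-variance data pushes theta to the Poisson limit: report the cap
        theta = THETA_MAX if theta > 1.0 else THETA_MIN
    return NullModel(mu=mu, theta=theta, fitted_on=fitted_on, theta_at_boundary=at_boundary)


def tail_pvalue(x, mu: float, theta: float):
    """Upper-tail probability ``P(X >= x)`` for ``X ~ NB(mean=mu, size=theta)``.

    ``mu = 0`` is the degenerate null with all mass at zero: the tail is 1 at
    ``x = 0`` and 0 for any positive count.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if not theta > 0:
        raise ValueError("theta must be positive")
    x_arr = np.asarray(x)
    if np.any(x_arr < 0) or np.any(x_arr != np.round(x_arr)):
        raise ValueError("counts must be non-negative integers")
    x_arr = x_arr.astype(float)
    if mu == 0:
        out = np.where(x_arr > 0, 0.0, 1.0)
    else:
        p = theta / (theta + mu)
        out = stats.nbinom.sf(x_arr - 1, theta, p)
    return out if np.ndim(x) else float(out)


def apply_decontam(
    sample_table: FeatureTable,
    null: NullModel,
    sample_batches: dict[str, str],
    fdr: float = 0.1,
    family: str = "per-sample",
) -> tuple[DecontamResult, FeatureTable]:
    """Test each (sample, feature) count against the batch null and filter.

    Features with ``q < fdr`` — or with a positive count but no control
    evidence in the sample's batch — are retained; everything else is zeroed
    in the returned table.  ``family`` selects the BH adjustment family:
    ``"per-sample"`` adjusts across each sample's observed features,
    ``"global"`` across all observed (sample, feature) pairs.
    """
    if family not in ("per-sample", "global"):
        raise ValueError("family must be 'per-sample' or 'global'")
    if sample_table.value_kind != "reads":
        raise ValueError("decontamination operates on raw read counts")
    unknown = sorted(
        {sample_batches.get(s) for s in sample_table.samples} - set(null.fitted_on)
        - {None}
    )
    missing = [s for s in sample_table.samples if s not in sample_batches]
    if missing:
        raise ValueError(f"samples without batch assignment: {missing}")
    if unknown:
        raise ValueError(f"batch(es) not covered by the null model: {unknown}")

    long = sample_table.values.stack()
    long = long[long > 0]
    samples = long.index.get_level_values(0).to_numpy()
    features = long.index.get_level_values(1).to_numpy()
    counts = long.to_numpy(dtype=float)
    batches = np.array([sample_batches[s] for s in samples])
    mus = np.array([null.mu.get((b, f), 0.0) for b, f in zip(batches, features)])
    unseen = mus == 0.0
    pvals = np.zeros(counts.size)  # p = 0 for positive counts against mu = 0
    seen = ~unseen
    if seen.any():
        p_nb = null.theta / (null.theta + mus[seen])
        pvals[seen] = stats.nbinom.sf(counts[seen] - 1, null.theta, p_nb)
    decisions = pd.DataFrame(
        {
            "sample_id": samples,
            "feature": features,
            "count": counts,
            "batch": batches,
            "mu": mus,
            "p": pvals,
            "unseen_in_controls": unseen,
        }
    )
    decisions["q"] = np.nan
    if not decisions.empty:
        tested = ~decisions["unseen_in_controls"]
        if family == "per-sample":
            for _, idx in decisions[tested].groupby("sample_id").groups.items():
                decisions.loc[idx, "q"] = bh_adjust(decisions.loc[idx, "p"].to_numpy())
        else:
            idx = decisions.index[tested]
            decisions.loc[idx, "q"] = bh_adjust(decisions.loc[idx, "p"].to_numpy())
        decisions["retained"] = decisions["unseen_in_controls"] | (decisions["q"] < fdr)
    else:
        decisions["retained"] = pd.Series(dtype=bool)

    filtered = sample_table.values.copy()
    removed = decisions[~decisions["retained"]]
    if not removed.empty:
        row_pos = filtered.index.get_indexer(removed["sample_id"])
        col_pos = filtered.columns.get_indexer(removed["feature"])
        arr = filtered.to_numpy()
        arr[row_pos, col_pos] = 0.0
        filtered = pd.DataFrame(arr, index=filtered.index, columns=filtered.columns)
    result = DecontamResult(decisions=decisions, fdr=fdr, family=family)
    return result, FeatureTable(filtered, "reads", sample_table.feature_meta)
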