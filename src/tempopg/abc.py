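"""Rejection ABC on binned joint-SFS summaries.

Summaries are standardized dimension-wise by median/MAD computed over the
pooled reference table, distances are Euclidean, and the posterior sample
is the epsilon-fraction of reference rows closest to the observed summary.
Model posterior probabilities are the model composition of the globally
accepted rows (each model contributing equal prior counts). Optional
local-linear regression adjustment follows standard ABC practice
(Epanechnikov-weighted regression of parameters on summaries, positive
parameters handled on log scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .demography import HistoryParams, ModelSpec
from .simulate import ReferenceTable, SummaryPipeline

__all__ = [
    "PosteriorSample",
    "ConfusionMatrix",
    "GofReport",
    "abc_reject",
    "model_posteriors",
    "cross_validate_models",
    "best_fit_history",
    "gof_fit",
    "ovl",
]


@dataclass
class PosteriorSample:
    """Accepted reference rows for one model, with distances and marginals."""

    accepted: pd.DataFrame
    distances: np.ndarray
    epsilon: float
    adjusted: pd.DataFrame | None = None
    marginals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        vals = (self.adjusted if self.adjusted is not None else self.accepted)[param].dropna()
        a = (1 - level) / 2
        return (float(vals.quantile(a)), float(vals.quantile(1 - a)))


@dataclass
class ConfusionMatrix:
    """Cross-validation model-choice confusion matrix (rows = true model)."""

    matrix: pd.DataFrame
    n_pseudo_per_model: int

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")


@dataclass
class GofReport:
    """Goodness-of-fit of a best-fit history to the observed bin vector.

    ``d_obs`` holds distances from the observed bins to each of R replicate
    bin vectors simulated under the history; ``d_pseudo`` holds distances
    from one replicate (designated pseudo-observed) to the remaining R-1.
    Good fits make the two distance distributions overlap (OVL near 1,
    two-sample KS non-significant).
    """

    d_obs: np.ndarray
    d_pseudo: np.ndarray
    ovl: float
    ks_statistic: float
    ks_pvalue: float

    def ecdf(self, which: str = "obs"):
        x = np.sort(self.d_obs if which == "obs" else self.d_pseudo)
        return x, np.arange(1, len(x) + 1) / len(x)


def _standardized(ref: ReferenceTable, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med, mad = ref.standardization()
    s = (ref.summaries() - med) / mad
    obs = (np.asarray(observed, dtype=float) - med) / mad
    return s, obs


def _check_observed(ref: ReferenceTable, observed: np.ndarray) -> np.ndarray:
    observed = np.asarray(observed, dtype=float).ravel()
    k = len(ref.summary_cols)
    if len(observed) != k:
        raise ValueError(f"observed summary has length {len(observed)}, reference has {k}")
    return observed


def _n_accept(epsilon: float, n_rows: int) -> int:
    if not 0 < epsilon <= 1:
        raise ValueError(f"epsilon must be in (0, 1], got {epsilon}")
    return max(1, int(round(epsilon * n_rows)))


def abc_reject(
    observed: np.ndarray,
    ref: ReferenceTable,
    epsilon: float = 0.008,
    adjust: str = "none",
) -> PosteriorSample:
    """Rejection sampling: keep the epsilon-quantile of closest rows.

    ``adjust="loclinear"`` additionally regresses each parameter on the
    standardized summaries among accepted rows (Epanechnikov weights in the
    acceptance radius) and translates the draws to the observed summary;
    strictly positive parameters are adjusted on log scale.
    """
    observed = _check_observed(ref, observed)
    s, obs = _standardized(ref, observed)
    dist = np.sqrt(((s - obs) ** 2).sum(axis=1))
    k = _n_accept(epsilon, len(dist))
    order = np.argsort(dist, kind="stable")
    acc_idx = order[:k]
    accepted = ref.df.iloc[acc_idx].reset_index(drop=True)
    d_acc = dist[acc_idx]

    adjusted = None
    if adjust == "loclinear":
        adjusted = _loclinear_adjust(
            accepted[ref.param_cols], s[acc_idx], obs, d_acc
        )
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")

    source = adjusted if adjusted is not None else accepted[ref.param_cols]
    marg = source.quantile([0.5, 0.025, 0.975])
    marg.index = ["median", "q2.5", "q97.5"]
    return PosteriorSample(
        accepted=accepted, distances=d_acc, epsilon=epsilon,
        adjusted=adjusted, marginals=marg,
    )


def _loclinear_adjust(
    params: pd.DataFrame, s_acc: np.ndarray, obs: np.ndarray, d_acc: np.ndarray
) -> pd.DataFrame:
    delta = d_acc.max()
    w = 1.0 - (d_acc / delta) ** 2 if delta > 0 else np.ones_like(d_acc)
    w = np.clip(w, 1e-12, None)
    X = np.column_stack([np.ones(len(s_acc)), s_acc - obs])
    sw = np.sqrt(w)
    out = {}
    for col in params.columns:
        y = params[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < X.shape[1] + 1:
            out[col] = y
            continue
        positive = np.all(y[ok] > 0)
        z = np.log(y[ok]) if positive else y[ok]
        beta, *_ = np.linalg.lstsq(X[ok] * sw[ok, None], z * sw[ok], rcond=None)
        fitted = X[ok] @ beta
        adj = beta[0] + (z - fitted)
        ynew = y.copy()
        ynew[ok] = np.exp(adj) if positive else adj
        out[col] = ynew
    return pd.DataFrame(out)


def model_posteriors(
    observed: np.ndarray, ref: ReferenceTable, epsilon: float = 0.008
) -> dict[str, float]:
    """Rejection estimate of model posterior probabilities.

    Among the globally accepted epsilon-fraction of rows (all models pooled,
    equal prior row counts per model), the posterior probability of a model
    is its share of accepted rows.
    """
    observed = _check_observed(ref, observed)
    models = list(dict.fromkeys(ref.df["model"]))
    counts = ref.df["model"].value_counts()
    if len(set(counts[m] for m in models)) > 1:
        raise ValueError(f"models must contribute equal row counts, got {dict(counts)}")
    if len(models) == 1:
        return {models[0]: 1.0}
    s, obs = _standardized(ref, observed)
    dist = np.sqrt(((s - obs) ** 2).sum(axis=1))
    k = _n_accept(epsilon, len(dist))
    acc = ref.df["model"].to_numpy()[np.argsort(dist, kind="stable")[:k]]
    return {m: float(np.mean(acc == m)) for m in models}


def cross_validate_models(
    ref: ReferenceTable,
    n_pseudo_per_model: int,
    epsilon: float = 0.008,
    seed: int = 0,
) -> ConfusionMatrix:
    """Leave-one-out model-choice cross-validation.

    Randomly chosen reference rows serve as pseudo-observed datasets; each
    is classified by argmax model posterior computed from the remaining
    rows (one row removed from every model to keep prior counts equal).
    """
    if n_pseudo_per_model < 1:
        raise ValueError("n_pseudo_per_model must be >= 1")
    models = list(dict.fromkeys(ref.df["model"]))
    rng = np.random.default_rng(seed)
    k_check = _n_accept(epsilon, len(ref.df) - len(models))
    if k_check < 1:
        raise ValueError("epsilon too small: no rows would be accepted")
    tallies = pd.DataFrame(0.0, index=models, columns=models)
    med, mad = ref.standardization()
    for true_model in models:
        rows = np.nonzero((ref.df["model"] == true_model).to_numpy())[0]
        chosen = rng.choice(rows, size=n_pseudo_per_model, replace=n_pseudo_per_model > len(rows))
        for i in chosen:
            obs = ref.summaries()[i]
            # drop one row per model (the pseudo-observed one for its model,
            # a random one for the others) to keep prior counts equal
            drop = [i]
            for m in models:
                if m == true_model:
                    continue
                mrows = np.nonzero((ref.df["model"] == m).to_numpy())[0]
                drop.append(int(rng.choice(mrows)))
            keep = np.setdiff1d(np.arange(len(ref.df)), np.asarray(drop))
            sub = ReferenceTable(ref.df.iloc[keep].reset_index(drop=True), meta=dict(ref.meta))
            sub.meta["std_median"] = med.tolist()
            sub.meta["std_mad"] = mad.tolist()
            post = model_posteriors(obs, sub, epsilon)
            best = max(post, key=lambda m: (post[m], m))
            tallies.loc[true_model, best] += 1
    matrix = tallies.div(tallies.sum(axis=1), axis=0)
    return ConfusionMatrix(matrix=matrix, n_pseudo_per_model=n_pseudo_per_model)


def best_fit_history(
    observed: np.ndarray, ref: ReferenceTable, model_id: str | None = None
) -> HistoryParams:
    """The reference row closest to the observed summary ("best-fit history").

    Operationalizes the maximum-likelihood history as the minimum
    standardized-distance simulation; ties break to the lowest row index.
    """
    if model_id is not None:
        ref = ref.subset(model_id)
    if len(ref.df) == 0:
        raise ValueError("empty reference table")
    observed = _check_observed(ref, observed)
    s, obs = _standardized(ref, observed)
    dist = np.sqrt(((s - obs) ** 2).sum(axis=1))
    i = int(np.argmin(dist))  # argmin returns the first minimum
    row = ref.df.iloc[i]
    return HistoryParams.from_flat(
        {c: row[c] for c in ref.param_cols}, model_id=str(row["model"])
    )


def gof_fit(
    observed: np.ndarray,
    h_best: HistoryParams,
    spec: ModelSpec | int,
    pipeline: SummaryPipeline,
    R: int = 1000,
    seed: int = 0,
) -> GofReport:
    """Posterior-predictive style goodness-of-fit under a best-fit history.

    Simulates ``R`` replicate bin vectors under ``h_best``, measures the
    Euclidean distance from the observed bins to every replicate (d_obs)
    and from a designated pseudo-observed replicate to the remaining ones
    (d_pseudo), and compares the two distance samples by Weitzman's OVL and
    a two-sample KS test.
    """
    if R < 10:
        raise ValueError("R must be >= 10 for meaningful diagnostics")
    observed = np.asarray(observed, dtype=float).ravel()
    seeds = np.random.default_rng(np.random.SeedSequence((int(seed), 0x60F))).integers(
        1, 2**31 - 1, size=R
    )
    reps = np.vstack([
        pipeline.simulate_summary(h_best, spec, int(s)) for s in seeds
    ])
    if reps.shape[1] != len(observed):
        raise ValueError("observed and replicate summary lengths differ")
    d_obs = np.sqrt(((reps - observed) ** 2).sum(axis=1))
    pseudo = reps[0]
    d_pseudo = np.sqrt(((reps[1:] - pseudo) ** 2).sum(axis=1))
    ks = stats.ks_2samp(d_obs, d_pseudo, method="auto")
    return GofReport(
        d_obs=d_obs,
        d_pseudo=d_pseudo,
        ovl=ovl(d_obs, d_pseudo),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def ovl(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Weitzman's coefficient of overlapping of two empirical distributions.

    Histograms share breaks spanning the pooled range with Freedman-Diaconis
    bin width on the pooled sample (at least 10 bins); the overlap is the
    summed bin-wise minimum of the two probability mass functions, in
    [0, 1], symmetric in its arguments.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ovl requires two non-empty samples")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        return 1.0
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    width = 2 * iqr / len(pooled) ** (1 / 3)
    nbins = 10 if width <= 0 else max(10, int(np.ceil((hi - lo) / width)))
    edges = np.linspace(lo, hi, nbins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / len(a), pb / len(b)).sum())
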