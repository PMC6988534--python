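"""Approximate Bayesian computation over the spatial gene-flow models.

The reference table (one row per simulation: model label, parameter draw,
summary-statistic vector) is the training set of a kNN-style procedure:
statistics are standardized by median/MAD over the pooled table, a
pseudo-observation is compared to all rows by Euclidean distance, and the
nearest ``tol`` fraction of rows is accepted.

Model choice is exposed as a scikit-learn classifier (:class:`ABCModelChoice`)
with two methods: ``rejection`` (posterior probability = share of each model
among accepted rows) and ``mnlogistic`` (an Epanechnikov-weighted multinomial
logistic — soft-max — classifier fitted on the accepted rows and evaluated at
the observed statistics; the regression/"neural network" correction).
Parameter estimation (:class:`ABCParameterEstimator`) is rejection acceptance
followed by weighted local-linear regression adjustment toward the observed
statistics.  Leave-one-out cross-validation and the goodness-of-fit test
(median accepted distance against a null of pseudo-observed rows) are
functions over these estimators.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .demography import (
    DemographicModel,
    PriorSpec,
    sample_prior,
    simulate_counts_dataset,
    sumstat_names,
    sumstats_from_counts,
)

__all__ = [
    "ReferenceTable",
    "ModelPosterior",
    "CvResult",
    "GofResult",
    "ParamPosterior",
    "ABCModelChoice",
    "ABCParameterEstimator",
    "build_reference_table",
    "abc_reject",
    "regression_model_probs",
    "cross_validate",
    "goodness_of_fit",
    "estimate_parameters",
]


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summary statistics) rows plus the
    median/MAD standardization constants of the pooled table."""

    labels: np.ndarray  # (N,) model label per row
    params: np.ndarray  # (N, P)
    stats: np.ndarray  # (N, S)
    param_names: list[str]
    stat_names: list[str]
    center: np.ndarray = field(default=None)  # per-stat median
    scale: np.ndarray = field(default=None)  # per-stat MAD
    retained: np.ndarray = field(default=None)  # stats with MAD > 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        self.stats = np.atleast_2d(np.asarray(self.stats, dtype=float))
        if not np.isfinite(self.stats).all():
            raise ValueError("non-finite summary statistics in reference table")
        if self.center is None:
            self.center = np.median(self.stats, axis=0)
            self.scale = np.median(np.abs(self.stats - self.center), axis=0)
            self.retained = self.scale > 0
            if not self.retained.all():
                dropped = [
                    s for s, keep in zip(self.stat_names, self.retained) if not keep
                ]
                warnings.warn(
                    f"statistics with zero MAD excluded from distances: {dropped}",
                    stacklevel=2,
                )

    @property
    def models(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def standardized(self, stats: np.ndarray | None = None) -> np.ndarray:
        x = self.stats if stats is None else np.atleast_2d(np.asarray(stats, float))
        return (x[:, self.retained] - self.center[self.retained]) / self.scale[
            self.retained
        ]

    def restrict(self, model: str) -> "ReferenceTable":
        """Single-model view; standardization constants are inherited."""
        mask = self.labels == model
        if not mask.any():
            raise ValueError(f"model {model!r} absent from table")
        return ReferenceTable(
            labels=self.labels[mask],
            params=self.params[mask],
            stats=self.stats[mask],
            param_names=self.param_names,
            stat_names=self.stat_names,
            center=self.center,
            scale=self.scale,
            retained=self.retained,
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        for i, p in enumerate(self.param_names):
            df.insert(i, p, self.params[:, i])
        df.insert(0, "model", self.labels)
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "param_names": self.param_names,
                        "stat_names": self.stat_names,
                        "center": self.center.tolist(),
                        "scale": self.scale.tolist(),
                    },
                    fh,
                    indent=1,
                )

    @classmethod
    def from_csv(cls, path, param_names: list[str] | None = None) -> "ReferenceTable":
        df = pd.read_csv(path)
        if param_names is None:
            param_names = [c for c in df.columns if c == "m" or c.startswith("Ne")]
        stat_names = [c for c in df.columns if c != "model" and c not in param_names]
        return cls(
            labels=df["model"].to_numpy(),
            params=df[param_names].to_numpy(),
            stats=df[stat_names].to_numpy(),
            param_names=param_names,
            stat_names=stat_names,
        )


def build_reference_table(
    models: list[str],
    n_per_model: int,
    prior: PriorSpec,
    samples: np.ndarray,
    n_snps: int,
    rng: np.random.Generator,
    elevations: np.ndarray | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_model`` datasets per model under the prior and collect
    (parameters, summary statistics) rows."""
    samples = np.asarray(samples, dtype=np.int64)
    d = len(samples)
    labels, params, stats = [], [], []
    for label in models:
        for _ in range(n_per_model):
            m, Ne = sample_prior(prior, d, rng)
            model = DemographicModel(label, Ne=Ne, m=m, elevations=elevations)
            counts, het = simulate_counts_dataset(model, samples, n_snps, rng)
            labels.append(label)
            params.append(np.concatenate([[m], Ne]))
            stats.append(sumstats_from_counts(counts, het, samples))
    return ReferenceTable(
        labels=np.asarray(labels),
        params=np.asarray(params),
        stats=np.asarray(stats),
        param_names=["m"] + [f"Ne{k + 1}" for k in range(d)],
        stat_names=sumstat_names(d),
    )


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ModelPosterior:
    """Per-model posterior probabilities for one method."""

    method: str
    probabilities: dict[str, float]
    untestable: list[str] = field(default_factory=list)

    def best_model(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)

    def bayes_factors(self) -> pd.DataFrame:
        """Posterior-odds ratios under equal model priors."""
        models = list(self.probabilities)
        bf = np.full((len(models), len(models)), np.nan)
        for i, a in enumerate(models):
            for j, b in enumerate(models):
                pb = self.probabilities[b]
                bf[i, j] = self.probabilities[a] / pb if pb > 0 else np.inf
        return pd.DataFrame(bf, index=models, columns=models)


@dataclass
class CvResult:
    method: str
    tol: float
    confusion: pd.DataFrame  # rows: true model; columns: assigned model
    mean_correct: float


@dataclass
class GofResult:
    observed: float
    null: np.ndarray
    p_value: float


@dataclass
class ParamPosterior:
    param_names: list[str]
    sample: np.ndarray  # (n_accept, P) possibly regression-adjusted
    weights: np.ndarray
    median: np.ndarray
    lower: np.ndarray  # 2.5% weighted quantile
    upper: np.ndarray  # 97.5% weighted quantile
    adjusted: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "q2.5": self.lower, "q97.5": self.upper},
            index=self.param_names,
        )


# ---------------------------------------------------------------------------
# distances and acceptance


def _n_accept(tol: float, n_rows: int) -> int:
    if not 0 < tol <= 1:
        raise ValueError(f"tolerance must be in (0, 1], got {tol}")
    n = math.ceil(tol * n_rows)
    if n < 1:
        raise ValueError("tolerance accepts no rows")
    return n


def _distances(table: ReferenceTable, obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs, dtype=float)
    if not np.isfinite(obs).all():
        raise ValueError("non-finite observed summary statistic")
    z = table.standardized()
    zo = table.standardized(obs[None, :])[0]
    return np.sqrt(((z - zo) ** 2).sum(axis=1))


def _accept_indices(
    dist: np.ndarray, n_acc: int, rng: np.random.Generator | None
) -> np.ndarray:
    """Indices of the n_acc nearest rows; boundary ties broken by table order
    after a seeded shuffle."""
    rng = rng or np.random.default_rng(0)
    perm = rng.permutation(len(dist))
    order = perm[np.argsort(dist[perm], kind="stable")]
    return order[:n_acc]


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max()
    if dmax == 0:
        return np.ones_like(dist)
    w = 1.0 - (dist / dmax) ** 2
    w[w <= 0] = np.finfo(float).tiny  # boundary row keeps infinitesimal weight
    return w


# ---------------------------------------------------------------------------
# estimators


class ABCModelChoice(BaseEstimator, ClassifierMixin):
    """ABC model-choice classifier over a reference table.

    Parameters
    ----------
    tol : fraction of reference rows accepted per query.
    method : "rejection" or "mnlogistic".
    random_state : seed for acceptance tie-breaking.

    After :meth:`fit`, ``classes_`` holds the model labels and
    ``table_`` the internal standardized reference table.
    """

    def __init__(self, tol: float = 0.001, method: str = "rejection", random_state=0):
        self.tol = tol
        self.method = method
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if self.method not in ("rejection", "mnlogistic"):
            raise ValueError(f"unknown method {self.method!r}")
        self.table_ = ReferenceTable(
            labels=y,
            params=np.zeros((len(y), 1)),
            stats=X,
            param_names=["_"],
            stat_names=[f"s{i}" for i in range(X.shape[1])],
        )
        self.classes_ = np.asarray(self.table_.models)
        return self

    def fit_table(self, table: ReferenceTable) -> "ABCModelChoice":
        self.table_ = table
        self.classes_ = np.asarray(table.models)
        return self

    def _posterior_one(self, obs: np.ndarray, exclude: int | None = None) -> np.ndarray:
        table = self.table_
        dist = _distances(table, obs)
        if exclude is not None:
            dist[exclude] = np.inf
        n_rows = table.n_rows - (exclude is not None)
        n_acc = _n_accept(self.tol, n_rows)
        rng = np.random.default_rng(self.random_state)
        idx = _accept_indices(dist, n_acc, rng)
        acc_labels = table.labels[idx]
        if self.method == "rejection":
            return np.array(
                [np.mean(acc_labels == c) for c in self.classes_]
            )
        return self._mnlogistic_probs(table, obs, idx, dist[idx], acc_labels)

    def _mnlogistic_probs(self, table, obs, idx, dist, acc_labels) -> np.ndarray:
        present = np.unique(acc_labels)
        probs = np.zeros(len(self.classes_))
        pos = {c: k for k, c in enumerate(self.classes_)}
        if len(present) == 1:
            probs[pos[present[0]]] = 1.0
            return probs
        z = table.standardized()[idx]
        zo = table.standardized(np.asarray(obs, float)[None, :])[0]
        w = _epanechnikov(dist)
        clf = LogisticRegression(C=1e6, max_iter=500, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny separable fits hit max_iter
            clf.fit(z - zo, acc_labels, sample_weight=w)
        p = clf.predict_proba(np.zeros((1, z.shape[1])))[0]
        for c, pc in zip(clf.classes_, p):
            probs[pos[c]] = pc
        return probs

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self._posterior_one(x) for x in X])

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def posterior(self, obs) -> ModelPosterior:
        """Full posterior for one observed vector, with untestable models
        (absent from the accepted set) flagged."""
        p = self._posterior_one(np.asarray(obs, dtype=float))
        probs = dict(zip(self.classes_.tolist(), p.tolist()))
        untestable = [c for c, pc in probs.items() if pc == 0.0]
        return ModelPosterior(
            method=self.method, probabilities=probs, untestable=untestable
        )


class ABCParameterEstimator(BaseEstimator):
    """Rejection + weighted local-linear adjustment parameter estimator.

    ``log_mask`` marks parameters handled on the log scale (effective sizes);
    adjusted draws are clamped to the prior support given by ``bounds``.
    """

    def __init__(
        self,
        tol: float = 0.05,
        adjust: bool = True,
        log_mask: np.ndarray | None = None,
        bounds: list[tuple[float, float]] | None = None,
        random_state=0,
    ):
        self.tol = tol
        self.adjust = adjust
        self.log_mask = log_mask
        self.bounds = bounds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        self.table_ = ReferenceTable(
            labels=np.repeat("model", len(X)),
            params=y,
            stats=X,
            param_names=[f"p{i}" for i in range(y.shape[1])],
            stat_names=[f"s{i}" for i in range(X.shape[1])],
        )
        return self

    def fit_table(self, table: ReferenceTable) -> "ABCParameterEstimator":
        if len(set(table.labels.tolist())) != 1:
            raise ValueError("parameter estimation requires a single-model table")
        self.table_ = table
        return self

    def posterior(self, obs) -> ParamPosterior:
        table = self.table_
        obs = np.asarray(obs, dtype=float)
        P = table.params.shape[1]
        log_mask = (
            np.asarray(self.log_mask, dtype=bool)
            if self.log_mask is not None
            else np.zeros(P, dtype=bool)
        )
        dist = _distances(table, obs)
        n_acc = _n_accept(self.tol, table.n_rows)
        rng = np.random.default_rng(self.random_state)
        idx = _accept_indices(dist, n_acc, rng)
        theta = table.params[idx].copy()
        theta[:, log_mask] = np.log(theta[:, log_mask])
        w = _epanechnikov(dist[idx])
        adjusted = False
        if self.adjust:
            z = table.standardized()[idx]
            zo = table.standardized(obs[None, :])[0]
            X = np.column_stack([np.ones(len(idx)), z - zo])
            Xw = X * np.sqrt(w)[:, None]
            yw = theta * np.sqrt(w)[:, None]
            beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            if rank == X.shape[1]:
                fitted = X @ beta
                theta = beta[0][None, :] + (theta - fitted)
                adjusted = True
            else:
                warnings.warn(
                    "degenerate regression design; returning unadjusted "
                    "rejection sample",
                    stacklevel=2,
                )
        if self.bounds is not None:
            for j, (lo, hi) in enumerate(self.bounds):
                if log_mask[j]:
                    lo, hi = np.log(lo), np.log(hi)
                theta[:, j] = np.clip(theta[:, j], lo, hi)
        qs = np.vstack(
            [_weighted_quantiles(theta[:, j], w, (0.025, 0.5, 0.975)) for j in range(P)]
        )
        theta_nat = theta.copy()
        theta_nat[:, log_mask] = np.exp(theta_nat[:, log_mask])
        lower, med, upper = qs[:, 0].copy(), qs[:, 1].copy(), qs[:, 2].copy()
        lower[log_mask] = np.exp(lower[log_mask])
        med[log_mask] = np.exp(med[log_mask])
        upper[log_mask] = np.exp(upper[log_mask])
        return ParamPosterior(
            param_names=list(table.param_names),
            sample=theta_nat,
            weights=w,
            median=med,
            lower=lower,
            upper=upper,
            adjusted=adjusted,
        )

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([self.posterior(x).median for x in X])


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(qs, cw, x)


# ---------------------------------------------------------------------------
# functional wrappers


def abc_reject(
    obs, table: ReferenceTable, tol: float, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, ModelPosterior]:
    """Rejection acceptance; returns (accepted row indices, model posterior)."""
    dist = _distances(table, obs)
    n_acc = _n_accept(tol, table.n_rows)
    idx = _accept_indices(dist, n_acc, rng)
    clf = ABCModelChoice(tol=tol, method="rejection").fit_table(table)
    return idx, clf.posterior(obs)


def regression_model_probs(
    obs, table: ReferenceTable, tol: float
) -> ModelPosterior:
    """Distance-weighted multinomial-logistic model probabilities."""
    return ABCModelChoice(tol=tol, method="mnlogistic").fit_table(table).posterior(obs)


def cross_validate(
    table: ReferenceTable,
    n_cv: int = 100,
    tol: float = 0.001,
    method: str = "rejection",
    rng: np.random.Generator | None = None,
) -> CvResult:
    """Leave-one-out cross-validation of model assignment.

    For each model, ``n_cv`` table rows are held out in turn as
    pseudo-observations and classified against the table without themselves.
    """
    return cross_validate_multi(table, n_cv, [(method, tol)], rng)[0]


def cross_validate_multi(
    table: ReferenceTable,
    n_cv: int,
    method_tols: list[tuple[str, float]],
    rng: np.random.Generator | None = None,
) -> list[CvResult]:
    """Run several (method, tol) cross-validations sharing one distance pass."""
    rng = rng or np.random.default_rng(0)
    for method, _tol in method_tols:
        if method not in ("rejection", "mnlogistic"):
            raise ValueError(f"unknown method {method!r}")
    models = table.models
    pseudo: list[int] = []
    for mlabel in models:
        rows = np.flatnonzero(table.labels == mlabel)
        if n_cv > len(rows):
            raise ValueError(f"n_cv={n_cv} exceeds rows for model {mlabel!r}")
        pseudo.extend(rng.choice(rows, size=n_cv, replace=False).tolist())

    clfs = {
        (method, tol): ABCModelChoice(
            tol=tol, method=method, random_state=int(rng.integers(2**31 - 1))
        ).fit_table(table)
        for method, tol in method_tols
    }
    assigned = {key: [] for key in clfs}
    z = table.standardized()
    for row in pseudo:
        dist = np.sqrt(((z - z[row]) ** 2).sum(axis=1))
        dist[row] = np.inf
        n_rows = table.n_rows - 1
        for (method, tol), clf in clfs.items():
            n_acc = _n_accept(tol, n_rows)
            idx = _accept_indices(dist, n_acc, np.random.default_rng(clf.random_state))
            acc_labels = table.labels[idx]
            if method == "rejection":
                probs = np.array([np.mean(acc_labels == c) for c in clf.classes_])
            else:
                probs = clf._mnlogistic_probs(
                    table, table.stats[row], idx, dist[idx], acc_labels
                )
            assigned[(method, tol)].append(clf.classes_[int(np.argmax(probs))])

    true = np.repeat(models, n_cv)
    results = []
    for (method, tol), ass in assigned.items():
        ass = np.asarray(ass)
        conf = pd.DataFrame(0, index=models, columns=models)
        for t, a in zip(true, ass):
            conf.loc[t, a] += 1
        mean_correct = float(np.mean([conf.loc[mname, mname] / n_cv for mname in models]))
        results.append(
            CvResult(method=method, tol=tol, confusion=conf, mean_correct=mean_correct)
        )
    return results


def median_accepted_distance(dist: np.ndarray, tol: float) -> float:
    """Goodness-of-fit statistic: median distance to the accepted set."""
    n_acc = _n_accept(tol, len(dist))
    part = np.partition(dist, n_acc - 1)[:n_acc]
    return float(np.median(part))


def goodness_of_fit(
    obs,
    table: ReferenceTable,
    tol: float = 0.01,
    n_rep: int = 1000,
    rng: np.random.Generator | None = None,
) -> GofResult:
    """Median-distance goodness-of-fit test against a single-model table.

    The null distribution is built from pseudo-observed rows of the table,
    each scored against the table without itself.  The p-value uses the
    permutation +1 correction, so it is never 0.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if len(set(table.labels.tolist())) != 1:
        raise ValueError("goodness-of-fit requires a single-model table")
    rng = rng or np.random.default_rng(0)
    obs_stat = median_accepted_distance(_distances(table, obs), tol)
    z = table.standardized()
    rows = rng.choice(table.n_rows, size=n_rep, replace=n_rep > table.n_rows)
    null = np.empty(n_rep)
    for i, row in enumerate(rows):
        dist = np.sqrt(((z - z[row]) ** 2).sum(axis=1))
        dist[row] = np.inf
        null[i] = median_accepted_distance(dist, tol)
    p = (1.0 + np.sum(null >= obs_stat)) / (n_rep + 1.0)
    return GofResult(observed=obs_stat, null=null, p_value=p)


def estimate_parameters(
    obs,
    table: ReferenceTable,
    tol: float = 0.05,
    prior: PriorSpec | None = None,
    adjust: bool = True,
    rng: np.random.Generator | None = None,
) -> ParamPosterior:
    """Posterior parameter sample under the (single-model) table's model."""
    prior = prior or PriorSpec()
    P = table.params.shape[1]
    log_mask = np.array([name.startswith("Ne") for name in table.param_names])
    bounds = [
        prior.ne_bounds if log_mask[j] else prior.m_bounds for j in range(P)
    ]
    seed = int((rng or np.random.default_rng(0)).integers(2**31 - 1))
    est = ABCParameterEstimator(
        tol=tol, adjust=adjust, log_mask=log_mask, bounds=bounds, random_state=seed
    ).fit_table(table)
    return est.posterior(obs)
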