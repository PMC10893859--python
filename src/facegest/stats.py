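"""Filters, cell summaries, fixed-effects logistic fits and cluster bootstrap.

The inferential layer is deliberately a fixed-effects logistic regression
(maximum likelihood via iteratively reweighted least squares, written out
here) plus a cluster bootstrap over grouping factors, rather than a crossed
random-effects GLMM: with as few observations per dyad/individual as these
tables carry, mixed models routinely return singular fits, and percentile
intervals over whole-cluster resamples are an honest, testable substitute
for random-effect uncertainty.

Percent values are kept at full precision internally; rounding to integers
happens only in reporting. Separation (fitted probabilities collapsing to
0/1, as happens when a cell is nearly empty of one response) is detected
and flagged, never silently reported as a converged estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .simulate import ObservationRecord, records_to_dataframe

__all__ = [
    "FilterSpec",
    "FilterResult",
    "apply_filters",
    "CellSummary",
    "cell_percentages",
    "DesignError",
    "design_matrix",
    "LogisticFit",
    "fit_logistic",
    "odds_multiplier",
    "BootstrapResult",
    "cluster_bootstrap",
]

REQUIRED_FIELDS = ("face", "gesture", "recipient_dominant", "response_affiliative")


@dataclass(frozen=True)
class FilterSpec:
    """Keep positive-context rows where all analysis fields are encoded."""

    require_context: str | None = "positive"
    require_complete: tuple[str, ...] = REQUIRED_FIELDS


@dataclass(frozen=True)
class FilterResult:
    records: tuple[ObservationRecord, ...]
    removed: Mapping[str, int]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def apply_filters(
    records: Iterable[ObservationRecord], spec: FilterSpec = FilterSpec()
) -> FilterResult:
    """Subset the table, preserving order and counting removals per reason."""
    kept = []
    removed: Counter[str] = Counter()
    for r in records:
        if any(getattr(r, f) is None for f in spec.require_complete):
            removed["incomplete"] += 1
        elif spec.require_context is not None and r.context != spec.require_context:
            removed["context"] += 1
        else:
            kept.append(r)
    return FilterResult(tuple(kept), dict(removed))


@dataclass(frozen=True)
class CellSummary:
    """Affiliative-response tally for one cell (or marginal)."""

    key: tuple
    n: int
    n_affiliative: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_affiliative <= self.n:
            raise ValueError(f"inconsistent tally for cell {self.key}")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_affiliative / self.n

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))


def cell_percentages(
    records: Iterable[ObservationRecord],
    by: Sequence[str] = ("gesture", "face", "recipient_dominant"),
) -> list[CellSummary]:
    """Tally affiliative responses per nonempty cell of the grouping.

    Marginals are obtained by passing a coarser ``by`` (aggregation of
    counts), never by averaging cell percentages. Empty cells are omitted.
    """
    df = records_to_dataframe(records)
    if df.empty:
        return []
    df["response_affiliative"] = pd.to_numeric(df["response_affiliative"])
    grouped = df.groupby(list(by), sort=True)["response_affiliative"].agg(["count", "sum"])
    out = []
    for key, row in grouped.iterrows():
        key = key if isinstance(key, tuple) else (key,)
        out.append(CellSummary(tuple(key), int(row["count"]), int(row["sum"])))
    return out


def summaries_to_dataframe(summaries: Sequence[CellSummary], by: Sequence[str]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(zip(by, s.key))
        row.update(n=s.n, n_affiliative=s.n_affiliative, percent=s.percent)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixed-effects logistic regression (IRLS)
# ---------------------------------------------------------------------------


class DesignError(ValueError):
    """Raised for rank-deficient or malformed design specifications."""


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """One design column from a term token.

    Tokens: ``intercept``; ``dominant`` (recipient_dominant); level
    indicators ``gesture[STRETCHED]``/``face[HOOT]``; and ``:``-joined
    products of the above for interactions.
    """
    if ":" in term:
        cols = [_term_column(df, part) for part in term.split(":")]
        out = cols[0].copy()
        for c in cols[1:]:
            out = out * c
        return out
    if term == "intercept":
        return np.ones(len(df))
    if term == "dominant":
        return pd.to_numeric(df["recipient_dominant"]).to_numpy(dtype=float)
    if "[" in term and term.endswith("]"):
        var, level = term[:-1].split("[", 1)
        if var not in ("gesture", "face"):
            raise DesignError(f"unknown factor {var!r} in term {term!r}")
        return (df[var] == level).to_numpy(dtype=float)
    raise DesignError(f"unknown design term {term!r}")


def design_matrix(
    records: Iterable[ObservationRecord], terms: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = records_to_dataframe(records)
    if df.empty:
        raise DesignError("no records to fit")
    X = np.column_stack([_term_column(df, t) for t in terms])
    y = pd.to_numeric(df["response_affiliative"]).to_numpy(dtype=float)
    if np.any(~np.isin(y, (0.0, 1.0))):
        raise DesignError("response_affiliative must be binary and encoded")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_terms(X, list(terms), rank)
        raise DesignError(f"rank-deficient design; aliased term(s): {aliased}")
    return X, y, list(terms)


def _aliased_terms(X: np.ndarray, terms: list[str], rank: int) -> list[str]:
    # greedy scan: a column is aliased if it does not increase the rank of
    # the columns before it
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept):
            aliased.append(terms[j])
        else:
            kept.append(j)
    return aliased


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    terms: tuple[str, ...]
    params: Mapping[str, float]
    bse: Mapping[str, float]
    zvalues: Mapping[str, float]
    pvalues: Mapping[str, float]
    converged: bool
    separation: bool
    n: int
    deviance: float
    formula: str
    filters_applied: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "beta": [self.params[t] for t in self.terms],
                "se": [self.bse[t] for t in self.terms],
                "z": [self.zvalues[t] for t in self.terms],
                "p": [self.pvalues[t] for t in self.terms],
            }
        )

    def report(self) -> str:
        head = (
            f"logistic fit: {self.formula}  (n={self.n}, converged={self.converged}, "
            f"separation={self.separation})"
        )
        if self.filters_applied:
            head += f"\nfilters: {self.filters_applied}"
        return head + "\n" + self.to_dataframe().to_string(index=False)


_SEP_TOL = 1e-8
_MAX_ITER = 100


def fit_logistic(
    records: Iterable[ObservationRecord],
    terms: Sequence[str] = ("intercept", "dominant"),
    ridge: float = 0.0,
    filters_applied: str = "",
) -> LogisticFit:
    """Fit a binomial GLM with logit link by IRLS.

    Deterministic given the data. ``ridge`` adds an optional L2 penalty
    (off by default) for users who want finite estimates under separation;
    by default separation is only detected and flagged.
    """
    X, y, terms = design_matrix(records, terms)
    n, p = X.shape
    beta = np.zeros(p)
    dev_old = np.inf
    converged = False
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        H = X.T @ WX + ridge * np.eye(p)
        beta_new = np.linalg.solve(H, WX.T @ z)
        mu_new = np.clip(expit(X @ beta_new), 1e-300, 1 - 1e-16)
        dev = -2 * np.sum(y * np.log(mu_new) + (1 - y) * np.log1p(-mu_new))
        beta = beta_new
        if abs(dev - dev_old) < 1e-10 * (abs(dev) + 1e-10):
            converged = True
            break
        dev_old = dev
    mu = expit(X @ beta)
    separation = bool(np.any(mu < _SEP_TOL) or np.any(mu > 1 - _SEP_TOL))
    if separation:
        converged = False  # ML estimate lies on the boundary; do not report as converged
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = X.T @ (X * w[:, None]) + ridge * np.eye(p)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    pval = 2 * sps.norm.sf(np.abs(zval))
    return LogisticFit(
        terms=tuple(terms),
        params=dict(zip(terms, beta)),
        bse=dict(zip(terms, se)),
        zvalues=dict(zip(terms, zval)),
        pvalues=dict(zip(terms, pval)),
        converged=converged,
        separation=separation,
        n=n,
        deviance=float(dev_old if not np.isfinite(dev) else dev),
        formula="response_affiliative ~ " + " + ".join(terms),
        filters_applied=filters_applied,
    )


def odds_multiplier(beta: float) -> float:
    """Fold change in the odds for a coefficient, to one decimal.

    The magnitude of the effect: a coefficient of -1.37 reads "exp(1.37) =
    3.9 times less likely", a coefficient of +1.37 "3.9 times more likely".
    """
    if not np.isfinite(beta):
        raise ValueError("odds multiplier requires a finite coefficient")
    return round(float(np.exp(abs(beta))), 1)


# ---------------------------------------------------------------------------
# Cluster bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    lower: float
    upper: float
    replicates: int
    cluster_key: str
    n_clusters: int


def cluster_bootstrap(
    records: Sequence[ObservationRecord],
    cluster_key: str,
    statistic: Callable[[Sequence[ObservationRecord]], float],
    B: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile interval of a statistic under whole-cluster resampling.

    Clusters (dyads, individuals, groups) are resampled with replacement;
    the statistic is recomputed on each resample. This propagates
    within-cluster dependence into the interval without fitting a
    random-effects model.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if cluster_key not in ("dyad_id", "initiator_id", "recipient_id", "group_id"):
        raise ValueError(f"unsupported cluster key {cluster_key!r}")
    records = list(records)
    by_cluster: dict[str, list[ObservationRecord]] = {}
    for r in records:
        by_cluster.setdefault(getattr(r, cluster_key), []).append(r)
    clusters = sorted(by_cluster)
    if len(clusters) < 2:
        raise ValueError("cluster bootstrap needs at least two clusters")
    rng = np.random.default_rng(seed)
    point = float(statistic(records))
    stats_b = np.empty(B)
    for b in range(B):
        sample: list[ObservationRecord] = []
        for idx in rng.integers(len(clusters), size=len(clusters)):
            sample.extend(by_cluster[clusters[idx]])
        stats_b[b] = statistic(sample)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats_b, [alpha, 1.0 - alpha])
    return BootstrapResult(point, float(lower), float(upper), B, cluster_key, len(clusters))
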