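"""Time-interval PCA: per-interval variance-contribution ranking of mediators.

A single PCA over the whole 0–48 h window summarizes which (mediator,
compartment) variables dominate overall, but hides *when* each compartment
dominates.  Time-interval PCA (TI-PCA) instead partitions the study window
into consecutive intervals, runs a PCA within each on the z-scored
observations × (mediator × compartment) matrix, scores every variable by its
eigenvalue-weighted loading contribution, and selects the minimal ranked set
of variables accounting for the top 25% of variance.  Counting and summing
those contributions per compartment per interval yields a temporal profile
whose per-compartment peaks order the compartments — the inferred sequence
in which inflammation sweeps across organs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, InsufficientDataError, IntervalError
from .panel_io import TimecourseDataset, _pivot, _zscore_frame

#: Six consecutive analysis windows (h) partitioning the 0–48 h course.
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (0, 1), (1, 4), (4, 6), (6, 12), (12, 24), (24, 48),
)


@dataclass(frozen=True)
class IntervalSpec:
    """Ordered consecutive (start_h, end_h) windows covering the study."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise IntervalError("interval spec must be non-empty")
        for a, b in ivs:
            if not a < b:
                raise IntervalError(f"interval ({a}, {b}) must have start < end")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if b0 != a1:
                raise IntervalError(
                    f"intervals must be consecutive; {b0} != {a1}")

    @classmethod
    def from_string(cls, text: str) -> "IntervalSpec":
        """Parse e.g. ``"0-1,1-4,4-6"``."""
        parts = []
        for token in text.split(","):
            a, _, b = token.strip().partition("-")
            parts.append((float(a), float(b)))
        return cls(tuple(parts))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{_fmt(a)}-{_fmt(b)}h" for a, b in self.intervals)

    @property
    def midpoints(self) -> tuple[float, ...]:
        return tuple((a + b) / 2.0 for a, b in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def partition_intervals(ds: TimecourseDataset, spec: IntervalSpec
                        ) -> list[tuple[float, ...]]:
    """Sampling times falling in each interval, inclusive on both ends.

    Because intervals share endpoints, a boundary time point belongs to the
    two adjacent intervals.
    """
    grid = set(ds.sampling_times)
    for a, b in spec.intervals:
        for endpoint in (a, b):
            if endpoint not in grid:
                raise IntervalError(
                    f"interval endpoint {endpoint} h is not a sampling time "
                    f"{ds.sampling_times}")
    return [tuple(t for t in ds.sampling_times if a <= t <= b)
            for a, b in spec.intervals]


@dataclass
class PCAResult:
    """Correlation-scale PCA of one observation window.

    Eigenvalues use the population (denominator n) convention matching the
    z-scoring, so they sum to the number of retained (non-constant)
    variables.  Loading columns are unit-norm with the largest-magnitude
    entry forced positive.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray            # J × K, unit-norm columns
    explained_fraction: np.ndarray
    n_obs: int
    var_keys: list[tuple[str, str]]  # (mediator, compartment) per row of loadings


def run_interval_pca(ds: TimecourseDataset, genotype: str | None,
                     interval_obs: Iterable[float],
                     zscore_scope: str = "interval",
                     log_transform: bool = False) -> PCAResult:
    """PCA of the z-scored observations within one time interval.

    ``zscore_scope`` controls the normalization reference:

    * ``"interval"`` — mean/SD recomputed within the interval, so the PCA is
      on the correlation scale and the eigenvalues sum to the number of
      retained variables (trace conservation).
    * ``"global"`` — each variable is scaled by its whole-course mean/SD for
      the genotype, then centered per time point within the interval, so the
      PCA captures inter-animal covariance at the interval's times rather
      than the deterministic time trend.  A variable quiescent in the
      interval then carries little variance, so contribution scores reflect
      *when* each variable is active — the scope used for compartment
      ordering.

    Observations with any missing variable are dropped; constant variables
    are excluded.  Computed via SVD of the centered matrix; eigenvalues are
    singular values squared over n (population convention).
    """
    if zscore_scope not in {"interval", "global"}:
        raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
    wide = _pivot(ds, genotype, interval_obs)
    wide = wide.dropna(axis=0, how="any")
    if len(wide) < 3:
        raise InsufficientDataError(
            f"interval PCA needs >=3 complete observations, got {len(wide)}")
    if zscore_scope == "interval":
        z, const = _zscore_frame(wide, log_transform=log_transform)
    else:
        full = _pivot(ds, genotype, ds.sampling_times).to_numpy(dtype=float)
        sub = wide.to_numpy(dtype=float)
        if log_transform:
            full = np.log10(full + 1.0)
            sub = np.log10(sub + 1.0)
        mu = np.nanmean(full, axis=0)
        sd = np.nanstd(full, axis=0, ddof=0)
        const_mask = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
        scaled = np.zeros_like(sub)
        scaled[:, ~const_mask] = (sub[:, ~const_mask] - mu[~const_mask]) \
            / sd[~const_mask]
        # center per time point: keep inter-animal spread, drop time trend
        tvals = np.asarray([t for _, t in wide.index], dtype=float)
        for t in np.unique(tvals):
            rows = tvals == t
            scaled[rows] -= scaled[rows].mean(axis=0)
        z = pd.DataFrame(scaled, index=wide.index, columns=wide.columns)
        const = tuple(wide.columns[i] for i in np.flatnonzero(const_mask))
    keep = [c for c in z.columns if c not in set(const)]
    if not keep:
        raise DegenerateInputError("all variables constant in interval")
    zmat = z.loc[:, keep].to_numpy(dtype=float)
    n = zmat.shape[0]
    u, s, vt = np.linalg.svd(zmat, full_matrices=False)
    eigenvalues = s ** 2 / n
    loadings = vt.T
    # resolve sign indeterminacy: largest-|entry| of each column positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    total = eigenvalues.sum()
    return PCAResult(
        eigenvalues=eigenvalues,
        loadings=loadings,
        explained_fraction=eigenvalues / total,
        n_obs=n,
        var_keys=[tuple(k) for k in keep],
    )


@dataclass
class ContributionTable:
    """Normalized variance-contribution score per (mediator, compartment).

    ``table`` is sorted by rank and has columns ``variable, mediator,
    compartment, score, rank``; scores sum to 1.
    """

    table: pd.DataFrame
    components_retained: int
    interval: str | None = None
    total_variance: float = float("nan")  # sum of PCA eigenvalues (trace)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def contribution_scores(pca: PCAResult, f_pc: float = 0.95,
                        scheme: str = "abs_loading",
                        panel_order: Sequence[str] | None = None,
                        compartment_order: Sequence[str] | None = None,
                        interval: str | None = None) -> ContributionTable:
    """Score each variable's contribution to the retained variance.

    The smallest leading component set with cumulative explained fraction
    ≥ ``f_pc`` is retained; the raw weight of variable j is
    ``w_j = Σ_{k∈K} (λ_k/Σλ)·|v_jk|`` (``scheme="abs_loading"``) or the
    squared-loading analogue (``scheme="sq_loading"``), normalized to sum
    to 1.  Ranks are descending by score with ties broken by panel order
    then compartment order.
    """
    if not 0 < f_pc <= 1:
        raise ValueError("f_pc must lie in (0, 1]")
    if scheme not in {"abs_loading", "sq_loading"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    cum = np.cumsum(pca.explained_fraction)
    k = int(np.searchsorted(cum, f_pc - 1e-12) + 1)
    k = min(k, len(pca.eigenvalues))
    lam_frac = pca.eigenvalues[:k] / pca.eigenvalues.sum()
    v = pca.loadings[:, :k]
    if scheme == "abs_loading":
        w = np.abs(v) @ lam_frac
    else:
        w = (v ** 2) @ lam_frac
    if not np.any(w > 0):
        raise DegenerateInputError("all-zero loadings: no variance to attribute")
    w = w / w.sum()

    mediators = [m for m, _ in pca.var_keys]
    comps = [c for _, c in pca.var_keys]
    p_order = {m: i for i, m in enumerate(panel_order)} if panel_order else {}
    c_order = {c: i for i, c in enumerate(compartment_order)} if compartment_order else {}
    df = pd.DataFrame({
        "variable": [f"{m}@{c}" for m, c in pca.var_keys],
        "mediator": mediators,
        "compartment": comps,
        "score": w,
        "_p": [p_order.get(m, i) for i, m in enumerate(mediators)],
        "_c": [c_order.get(c, i) for i, c in enumerate(comps)],
    })
    df = df.sort_values(["score", "_p", "_c"],
                        ascending=[False, True, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.drop(columns=["_p", "_c"]).reset_index(drop=True)
    return ContributionTable(table=df, components_retained=k, interval=interval,
                             total_variance=float(pca.eigenvalues.sum()))


@dataclass
class TopSelection:
    """Minimal rank-prefix of variables whose scores reach fraction ``f``."""

    interval: str | None
    variables: list[tuple[str, str]]   # (mediator, compartment), rank order
    cumulative_score: float
    fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.variables) + 1),
            "mediator": [m for m, _ in self.variables],
            "compartment": [c for _, c in self.variables],
            "interval": self.interval,
        })

    def __len__(self) -> int:
        return len(self.variables)


def select_top_fraction(ct: ContributionTable, f: float = 0.25) -> TopSelection:
    """Variables accounting for the top fraction ``f`` of total contribution.

    Returns the minimal rank-prefix whose cumulative normalized score
    reaches ``f``; deterministic given the documented tie rule.
    """
    if not 0 < f < 1:
        raise ValueError("f must lie in (0, 1)")
    scores = ct.table["score"].to_numpy()
    cum = np.cumsum(scores)
    stop = int(np.searchsorted(cum, f - 1e-12) + 1)
    sel = ct.table.iloc[:stop]
    return TopSelection(
        interval=ct.interval,
        variables=list(zip(sel["mediator"], sel["compartment"])),
        cumulative_score=float(cum[stop - 1]),
        fraction=f,
    )


@dataclass
class CompartmentProfile:
    """Per-compartment, per-interval activity summary.

    ``counts``: number of top-selected variables (compartments × intervals);
    ``contributions``: summed normalized contribution over *all* variables
    of the compartment in the interval — its share of that interval's
    variance.  Normalizing per interval cancels cohort-level severity
    fluctuations (all compartments of one sacrifice cohort share the same
    animals), which would otherwise dominate any absolute variance measure.
    ``peak_interval``: index of the interval maximizing the share (ties
    resolved to the earlier interval).
    """

    counts: pd.DataFrame
    contributions: pd.DataFrame
    peak_interval: dict[str, int]
    spec: IntervalSpec = field(default_factory=IntervalSpec)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.counts.index:
            for j, label in enumerate(self.counts.columns):
                rows.append({
                    "compartment": comp, "interval": label,
                    "count": int(self.counts.loc[comp, label]),
                    "summed_contribution": float(
                        self.contributions.loc[comp, label]),
                    "is_peak": j == self.peak_interval[comp],
                })
        return pd.DataFrame(rows)


def count_by_compartment(selections: Mapping[int, TopSelection],
                         contributions: Mapping[int, ContributionTable],
                         compartments: Sequence[str],
                         spec: IntervalSpec) -> CompartmentProfile:
    """Aggregate selections and contribution mass per compartment per interval."""
    if set(selections) != set(range(len(spec))):
        raise IntervalError("selections must cover all intervals")
    labels = spec.labels
    counts = pd.DataFrame(0, index=list(compartments), columns=list(labels))
    contrib = pd.DataFrame(0.0, index=list(compartments), columns=list(labels))
    for i in range(len(spec)):
        for _, c in selections[i].variables:
            counts.loc[c, labels[i]] += 1
        by_c = contributions[i].table.groupby("compartment")["score"].sum()
        for c, val in by_c.items():
            contrib.loc[c, labels[i]] = float(val)
    peak = {c: int(np.argmax(contrib.loc[c].to_numpy()))
            for c in compartments}  # argmax takes the earliest on ties
    return CompartmentProfile(counts=counts, contributions=contrib,
                              peak_interval=peak, spec=spec)


def peak_variance_ordering(profile: CompartmentProfile) -> list[list[str]]:
    """Compartments ordered by peak-interval midpoint, grouped on ties.

    Returns a list of tie groups, e.g. ``[[spleen], [plasma], [gut, lung]]``;
    compartments sharing a peak interval form one group.
    """
    mids = profile.spec.midpoints
    order = sorted(profile.peak_interval.items(), key=lambda kv: mids[kv[1]])
    groups: list[list[str]] = []
    last = None
    for comp, idx in order:
        if last is not None and idx == last:
            groups[-1].append(comp)
        else:
            groups.append([comp])
        last = idx
    return groups


def whole_course_pca_top_k(ds: TimecourseDataset, genotype: str | None,
                           k: int = 10, f_pc: float = 0.95,
                           scheme: str = "abs_loading",
                           log_transform: bool = True
                           ) -> tuple[list[tuple[str, str]], int]:
    """Top-k variables of a single PCA over all time points.

    Returns the k highest-ranked (mediator, compartment) variables and the
    number of them located in the plasma compartment.  Computed on the
    log10(x+1) scale by default, like the interval analysis.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pca = run_interval_pca(ds, genotype, ds.sampling_times,
                           log_transform=log_transform)
    ct = contribution_scores(pca, f_pc=f_pc, scheme=scheme,
                             panel_order=ds.panel.names,
                             compartment_order=ds.compartments.names,
                             interval="0-48h")
    top = list(zip(ct.table["mediator"], ct.table["compartment"]))[:k]
    plasma = ds.compartments.plasma_label
    return top, sum(1 for _, c in top if c == plasma)


class TimeIntervalPCA(BaseEstimator):
    """Time-interval PCA analyzer in scikit-learn estimator style.

    Parameters
    ----------
    intervals : IntervalSpec, str or None
        Consecutive analysis windows; default six windows over 0–48 h.
    fraction : float, default 0.25
        Cumulative-contribution cutoff for the top selection.
    f_pc : float, default 0.5
        Cumulative explained-variance cutoff for component retention.  With
        n ≪ J the trailing components are sampling noise; attributing
        contributions to the leading components that explain half the
        variance keeps the ranking driven by the dominant covariance axes.
        (The lower-level :func:`contribution_scores` keeps 0.95 as its
        default for standalone use.)
    genotype : str or None
        Restrict the analysis to one genotype label.
    scheme : {"abs_loading", "sq_loading"}
        Contribution weighting of loadings by eigenvalue fraction.
    zscore_scope : {"global", "interval"}, default "global"
        Normalization reference for the per-interval PCA.  "global" scales
        each variable by its whole-course SD so that interval contributions
        reflect when the variable is active (used for compartment
        ordering); "interval" rescales within each window (correlation-scale
        PCA, trace = number of variables).
    log_transform : bool, default True
        Apply log10(x+1) before scaling; concentrations span decades, so the
        log scale keeps the PCA from being dominated by a few extreme
        animals.

    Attributes (after :meth:`fit`)
    ------------------------------
    interval_times_ : list of sampling-time tuples per interval
    pca_results_ : dict interval-index → PCAResult
    contributions_ : dict interval-index → ContributionTable
    selections_ : dict interval-index → TopSelection
    profile_ : CompartmentProfile
    ordering_ : list of tie groups of compartments (peak-variance order)
    """

    def __init__(self, intervals=None, fraction: float = 0.25,
                 f_pc: float = 0.5, genotype: str | None = None,
                 scheme: str = "abs_loading", zscore_scope: str = "global",
                 log_transform: bool = True):
        self.intervals = intervals
        self.fraction = fraction
        self.f_pc = f_pc
        self.genotype = genotype
        self.scheme = scheme
        self.zscore_scope = zscore_scope
        self.log_transform = log_transform

    def _spec(self) -> IntervalSpec:
        if self.intervals is None:
            return IntervalSpec()
        if isinstance(self.intervals, IntervalSpec):
            return self.intervals
        if isinstance(self.intervals, str):
            return IntervalSpec.from_string(self.intervals)
        return IntervalSpec(tuple(self.intervals))

    def fit(self, X: TimecourseDataset, y=None) -> "TimeIntervalPCA":
        ds = X
        spec = self._spec()
        self.interval_times_ = partition_intervals(ds, spec)
        self.pca_results_ = {}
        self.contributions_ = {}
        self.selections_ = {}
        for i, times in enumerate(self.interval_times_):
            pca = run_interval_pca(ds, self.genotype, times,
                                   zscore_scope=self.zscore_scope,
                                   log_transform=self.log_transform)
            ct = contribution_scores(pca, f_pc=self.f_pc, scheme=self.scheme,
                                     panel_order=ds.panel.names,
                                     compartment_order=ds.compartments.names,
                                     interval=spec.labels[i])
            self.pca_results_[i] = pca
            self.contributions_[i] = ct
            self.selections_[i] = select_top_fraction(ct, f=self.fraction)
        self.profile_ = count_by_compartment(
            self.selections_, self.contributions_, ds.compartments.names, spec)
        self.ordering_ = peak_variance_ordering(self.profile_)
        return self

    def ordering_flat_(self) -> list[str]:
        """Peak-variance ordering flattened across tie groups."""
        return [c for group in self.ordering_ for c in group]
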