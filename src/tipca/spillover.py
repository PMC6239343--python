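"""Per-timepoint mediator correlation networks and spillover-onset inference.

At each sacrifice time, the 20×20 Pearson correlation matrix of mediator
concentrations — computed across the mice sacrificed at that time — captures
the co-regulation structure of a compartment.  Circulating mediators can
come either from blood-local production or from spillover out of inflamed
organs; when spillover dominates, the plasma correlation matrix starts to
resemble the organ matrices.  The onset detector quantifies that resemblance
as the Pearson correlation between the vectorized upper triangles of the
significance-filtered matrices (a Mantel-type statistic without
permutation), and calls onset at the earliest post-challenge time where at
least ``min_organs`` organs exceed a similarity threshold.

The onset call operationalizes a qualitative visual comparison; the full
similarity trajectory is always reported alongside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .panel_io import TimecourseDataset

logger = logging.getLogger("tipca")


@dataclass
class CorrelationSet:
    """Per (compartment, time) Pearson matrices for one genotype.

    ``r[(compartment, time)]`` is a 20×20 DataFrame of pairwise-complete
    Pearson coefficients across mice; ``p`` holds two-sided p-values from the
    t-distribution with n−2 degrees of freedom (NaN where n < 3); ``n`` the
    per-cell sample sizes.
    """

    genotype: str | None
    mediators: tuple[str, ...]
    r: dict[tuple[str, float], pd.DataFrame] = field(default_factory=dict)
    p: dict[tuple[str, float], pd.DataFrame] = field(default_factory=dict)
    n: dict[tuple[str, float], pd.DataFrame] = field(default_factory=dict)

    @property
    def keys(self) -> list[tuple[str, float]]:
        return sorted(self.r.keys(), key=lambda k: (k[1], k[0]))

    @property
    def times(self) -> list[float]:
        return sorted({t for _, t in self.r})

    @property
    def compartments(self) -> list[str]:
        return sorted({c for c, _ in self.r})


def _pearson_pvalues(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for H0: rho=0, via t = r·sqrt((n−2)/(1−r²)), df = n−2."""
    p = np.full_like(r, np.nan, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = n - 2.0
        valid = (df >= 1) & np.isfinite(r)
        rr = np.clip(r, -1.0, 1.0)
        denom = 1.0 - rr ** 2
        t = np.where(denom > 0, np.abs(rr) * np.sqrt(df / np.maximum(denom, 1e-300)),
                     np.inf)
        p_valid = 2.0 * sps.t.sf(t[valid], df[valid])
        p[valid] = np.minimum(p_valid, 1.0)
    return p


def correlation_matrices(ds: TimecourseDataset, genotype: str | None,
                         log_transform: bool = True) -> CorrelationSet:
    """Pairwise-complete Pearson r and p per compartment per time point.

    With ``log_transform`` (default) correlations are computed on
    log10(x + 1) concentrations; mediator levels are approximately
    log-normal across animals, and on the raw scale a single severe animal
    inflates every pairwise coefficient toward 1, erasing the pattern
    differences between compartments.  Set it to False for plain Pearson on
    raw concentrations.

    Mediator pairs with fewer than 3 complete mouse pairs get p = NaN (the
    coefficient is still reported when defined); such cells are logged.
    """
    meds = ds.panel.names
    out = CorrelationSet(genotype=genotype, mediators=meds)
    df = ds.subset(genotype)
    n_small = 0
    for (comp, t), sub in df.groupby(["compartment", "time_h"], sort=True):
        mat = sub.pivot_table(index="mouse_id", columns="mediator",
                              values="concentration", aggfunc="first")
        mat = mat.reindex(columns=list(meds))
        if log_transform:
            mat = np.log10(mat + 1.0)
        r = mat.corr(method="pearson", min_periods=2)
        notnull = mat.notna().to_numpy(dtype=float)
        n = notnull.T @ notnull
        p = _pearson_pvalues(r.to_numpy(), n)
        np.fill_diagonal(p, 0.0)
        rdf = r.reindex(index=list(meds), columns=list(meds))
        key = (str(comp), float(t))
        out.r[key] = rdf
        out.p[key] = pd.DataFrame(p, index=rdf.index, columns=rdf.columns)
        out.n[key] = pd.DataFrame(n, index=rdf.index, columns=rdf.columns)
        if (n < 3).any():
            n_small += 1
    if n_small:
        logger.info("correlation_matrices: %d matrix(es) contain cells with "
                    "n < 3; p undefined there", n_small)
    return out


def significance_filter(cs: CorrelationSet, alpha: float = 0.05
                        ) -> CorrelationSet:
    """Zero out correlations that are not significant at ``p < alpha``.

    Strict inequality; the diagonal is kept at 1; no multiplicity
    correction is applied (a deliberate, documented caveat).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = CorrelationSet(genotype=cs.genotype, mediators=cs.mediators)
    for key, r in cs.r.items():
        p = cs.p[key].to_numpy()
        rv = r.to_numpy(dtype=float).copy()
        keep = np.isfinite(p) & (p < alpha) & np.isfinite(rv)
        rv = np.where(keep, rv, 0.0)
        np.fill_diagonal(rv, 1.0)
        out.r[key] = pd.DataFrame(rv, index=r.index, columns=r.columns)
        out.p[key] = cs.p[key].copy()
        out.n[key] = cs.n[key].copy()
    return out


def matrix_similarity(a: pd.DataFrame | np.ndarray,
                      b: pd.DataFrame | np.ndarray) -> float:
    """Pearson correlation between the strict upper triangles of A and B.

    NaN when either triangle is constant (similarity undefined) or the
    matrices have mismatched shape (raises).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.shape[0] != av.shape[1]:
        raise ValueError(f"matrix shapes differ: {av.shape} vs {bv.shape}")
    iu = np.triu_indices(av.shape[0], k=1)
    x, y = av[iu], bv[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SpilloverReport:
    """Plasma–organ matrix-similarity trajectory and inferred onset."""

    similarity: pd.DataFrame      # index: organ, columns: time (h)
    theta: float
    min_organs: int
    onset_time: float | None
    genotype: str | None = None

    def to_json_dict(self) -> dict:
        sim = {
            organ: {str(t): (None if not np.isfinite(v) else float(v))
                    for t, v in row.items()}
            for organ, row in self.similarity.iterrows()
        }
        return {
            "genotype": self.genotype,
            "theta": self.theta,
            "min_organs": self.min_organs,
            "onset_time_h": self.onset_time,
            "similarity": sim,
        }


def infer_spillover_time(cs: CorrelationSet, theta: float = 0.5,
                         min_organs: int = 2,
                         plasma_label: str = "plasma") -> SpilloverReport:
    """Earliest post-challenge time when plasma resembles ≥ ``min_organs`` organs.

    ``cs`` should already be significance-filtered.  Onset is the earliest
    sampling time t > 0 at which the plasma–organ similarity is ≥ ``theta``
    for at least ``min_organs`` organ compartments; None if never.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must lie in (0, 1]")
    if min_organs < 1:
        raise ValueError("min_organs must be >= 1")
    organs = [c for c in cs.compartments if c != plasma_label]
    if plasma_label not in cs.compartments:
        raise ValueError(f"plasma compartment {plasma_label!r} absent")
    times = cs.times
    sim = pd.DataFrame(np.nan, index=organs, columns=times, dtype=float)
    for t in times:
        pl = cs.r.get((plasma_label, t))
        if pl is None:
            continue
        for organ in organs:
            om = cs.r.get((organ, t))
            if om is not None:
                sim.loc[organ, t] = matrix_similarity(pl, om)
    onset = None
    for t in times:
        if t <= 0:
            continue
        col = sim[t].to_numpy()
        if np.sum(col[np.isfinite(col)] >= theta) >= min_organs:
            onset = float(t)
            break
    return SpilloverReport(similarity=sim, theta=theta, min_organs=min_organs,
                           onset_time=onset, genotype=cs.genotype)


class SpilloverAnalyzer(BaseEstimator):
    """Correlation-network spillover detector, scikit-learn estimator style.

    Parameters
    ----------
    alpha : float, default 0.05
        Per-cell significance level of the correlation filter (strict
        ``p < alpha``; no multiplicity correction, mirroring standard usage).
    theta : float, default 0.5
        Plasma–organ matrix-similarity threshold.
    min_organs : int, default 2
        Number of organs that must exceed ``theta`` simultaneously.
    genotype : str or None
        Restrict to one genotype label.
    log_transform : bool, default True
        Correlate log10(x+1) concentrations (see
        :func:`correlation_matrices`).

    Attributes (after :meth:`fit`)
    ------------------------------
    correlations_ : CorrelationSet (unfiltered)
    filtered_ : CorrelationSet (significance-filtered)
    report_ : SpilloverReport
    onset_time_ : float or None
    """

    def __init__(self, alpha: float = 0.05, theta: float = 0.5,
                 min_organs: int = 2, genotype: str | None = None,
                 log_transform: bool = True):
        self.alpha = alpha
        self.theta = theta
        self.min_organs = min_organs
        self.genotype = genotype
        self.log_transform = log_transform

    def fit(self, X: TimecourseDataset, y=None) -> "SpilloverAnalyzer":
        ds = X
        self.correlations_ = correlation_matrices(
            ds, self.genotype, log_transform=self.log_transform)
        self.filtered_ = significance_filter(self.correlations_, self.alpha)
        self.report_ = infer_spillover_time(
            self.filtered_, theta=self.theta, min_organs=self.min_organs,
            plasma_label=ds.compartments.plasma_label)
        self.onset_time_ = self.report_.onset_time
        return self
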