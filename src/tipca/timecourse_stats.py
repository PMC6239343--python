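"""Classical time-course statistics: two-way ANOVA, post hoc tests, AUCs.

These are the per-mediator univariate companions to the multivariate
analyses: a fixed-effects genotype × time ANOVA per (compartment, mediator)
with Type-III sums of squares (group sizes differ between genotypes), a
step-down Holm–Šidák adjustment of the per-timepoint genotype contrasts, and
trapezoidal areas under the mean concentration–time curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError
from .panel_io import TimecourseDataset


def holm_sidak_posthoc(pvalues) -> np.ndarray:
    """Step-down Holm–Šidák adjustment, returned in the original order.

    Sort ascending; adjusted p_(i) = max_{j<=i} 1 − (1 − p_(j))^(m − j + 1),
    clipped to 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def auc_trapezoid(ds: TimecourseDataset, genotype: str, compartment: str,
                  mediator: str, n_boot: int = 0,
                  seed: int | None = None) -> tuple[float, float | None]:
    """Trapezoidal area under the per-timepoint mean concentration curve.

    Returns ``(auc, se)`` in concentration·h; ``se`` is a per-mouse
    resampling bootstrap standard error when ``n_boot > 0``, else None.
    """
    df = ds.subset(genotype)
    df = df[(df["compartment"] == compartment) & (df["mediator"] == mediator)]
    times = np.asarray(ds.sampling_times, dtype=float)
    if len(times) < 2:
        raise InsufficientDataError("AUC needs >=2 time points")
    groups = {t: df.loc[df["time_h"] == t, "concentration"].dropna().to_numpy()
              for t in times}
    for t, vals in groups.items():
        if len(vals) == 0:
            raise InsufficientDataError(
                f"no observations at t={t} h for {mediator}@{compartment} "
                f"({genotype})")
    means = np.array([groups[t].mean() for t in times])
    auc = float(np.trapezoid(means, times))
    se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bmeans = np.array([
                rng.choice(groups[t], size=len(groups[t]), replace=True).mean()
                for t in times])
            reps[i] = np.trapezoid(bmeans, times)
        se = float(np.std(reps, ddof=1))
    return auc, se


@dataclass
class AnovaResult:
    """Two-way ANOVA of one (compartment, mediator) time course.

    ``effects`` maps 'genotype' / 'time' / 'interaction' to (F, df, p);
    ``posthoc`` holds per-timepoint genotype contrasts with raw and
    Holm–Šidák-adjusted p-values; ``degenerate`` flags zero residual
    variance (p-values undefined).
    """

    compartment: str
    mediator: str
    effects: dict[str, tuple[float, float, float]]
    posthoc: pd.DataFrame
    degenerate: bool = False


def two_way_anova(ds: TimecourseDataset, compartment: str, mediator: str,
                  log_scale: bool = False) -> AnovaResult:
    """Fixed-effects genotype × time ANOVA with Type-III sums of squares.

    Runs on raw concentrations by default (``log_scale`` applies
    log10(x+1) first, useful for heavy-tailed panels).  Requires two
    genotypes, ≥2 time points and no empty genotype × time cell.
    """
    df = ds.data
    df = df[(df["compartment"] == compartment) & (df["mediator"] == mediator)]
    df = df.dropna(subset=["concentration"]).copy()
    genos = sorted(df["genotype"].unique())
    times = sorted(df["time_h"].unique())
    if len(genos) != 2:
        raise InsufficientDataError(
            f"two-way ANOVA needs exactly 2 genotypes, found {genos}")
    if len(times) < 2:
        raise InsufficientDataError("two-way ANOVA needs >=2 time points")
    cell_n = df.groupby(["genotype", "time_h"]).size()
    if len(cell_n) < 2 * len(times) or (cell_n < 2).any():
        raise InsufficientDataError(
            f"empty or singleton genotype×time cell for {mediator}@{compartment}")
    y = df["concentration"].to_numpy(dtype=float)
    if log_scale:
        y = np.log10(y + 1.0)
    work = pd.DataFrame({"y": y, "genotype": df["genotype"].to_numpy(),
                         "time": df["time_h"].astype(str).to_numpy()})
    model = smf.ols("y ~ C(genotype, Sum) * C(time, Sum)", data=work).fit()
    scale = max(model.centered_tss, float(np.mean(y ** 2)) * len(y), 1e-300)
    degenerate = model.ssr <= 1e-12 * scale
    table = sm.stats.anova_lm(model, typ=3)

    def _row(name_part: str) -> tuple[float, float, float]:
        row = next(r for r in table.index if name_part in r and ":" not in r) \
            if name_part != ":" else next(r for r in table.index if ":" in r)
        rec = table.loc[row]
        F = float(rec["F"]) if not degenerate else float("nan")
        p = float(rec["PR(>F)"]) if not degenerate else float("nan")
        return F, float(rec["df"]), p

    effects = {
        "genotype": _row("genotype"),
        "time": _row("time"),
        "interaction": _row(":"),
    }

    # Per-timepoint genotype contrasts pooled on the model's residual MS.
    mse = model.ssr / model.df_resid if model.df_resid > 0 else float("nan")
    rows = []
    for t in times:
        a = work.loc[(work["genotype"] == genos[0]) & (work["time"] == str(t)), "y"]
        b_ = work.loc[(work["genotype"] == genos[1]) & (work["time"] == str(t)), "y"]
        diff = a.mean() - b_.mean()
        if degenerate or not np.isfinite(mse) or mse <= 0:
            tval, praw = float("nan"), float("nan")
        else:
            tval = diff / np.sqrt(mse * (1 / len(a) + 1 / len(b_)))
            praw = float(2 * sps.t.sf(abs(tval), model.df_resid))
        rows.append({"time_h": t, f"mean_{genos[0]}": a.mean(),
                     f"mean_{genos[1]}": b_.mean(), "t": tval, "p_raw": praw})
    posthoc = pd.DataFrame(rows)
    if posthoc["p_raw"].notna().all():
        posthoc["p_adj"] = holm_sidak_posthoc(posthoc["p_raw"])
    else:
        posthoc["p_adj"] = np.nan
    return AnovaResult(compartment=compartment, mediator=mediator,
                       effects=effects, posthoc=posthoc, degenerate=degenerate)


def anova_screen(ds: TimecourseDataset, compartments=None, mediators=None,
                 log_scale: bool = False) -> pd.DataFrame:
    """Tidy table of two-way ANOVA results over (compartment, mediator) pairs."""
    compartments = list(compartments or ds.compartments.names)
    mediators = list(mediators or ds.panel.names)
    rows = []
    for c in compartments:
        for m in mediators:
            res = two_way_anova(ds, c, m, log_scale=log_scale)
            rec = {"compartment": c, "mediator": m, "degenerate": res.degenerate}
            for eff, (F, dfree, p) in res.effects.items():
                rec[f"F_{eff}"] = F
                rec[f"df_{eff}"] = dfree
                rec[f"p_{eff}"] = p
            rows.append(rec)
    return pd.DataFrame(rows)


def auc_table(ds: TimecourseDataset, n_boot: int = 0,
              seed: int | None = None) -> pd.DataFrame:
    """AUC of every (genotype, compartment, mediator) mean time course."""
    rows = []
    for g in ds.genotypes:
        for c in ds.compartments.names:
            for m in ds.panel.names:
                auc, se = auc_trapezoid(ds, g, c, m, n_boot=n_boot, seed=seed)
                rows.append({"genotype": g, "compartment": c, "mediator": m,
                             "auc": auc, "auc_se": se})
    return pd.DataFrame(rows)


class AnovaScreen(BaseEstimator):
    """Estimator wrapper around the per-mediator ANOVA screen.

    Attributes after :meth:`fit`: ``results_`` (tidy DataFrame of F/p per
    effect per (compartment, mediator)) and ``auc_`` (AUC table).
    """

    def __init__(self, log_scale: bool = False, n_boot: int = 0,
                 seed: int | None = None):
        self.log_scale = log_scale
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X: TimecourseDataset, y=None) -> "AnovaScreen":
        self.results_ = anova_screen(X, log_scale=self.log_scale)
        self.auc_ = auc_table(X, n_boot=self.n_boot, seed=self.seed)
        return self
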