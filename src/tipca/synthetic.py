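"""Synthetic multi-organ endotoxemia datasets with planted ground truth.

The generator emulates the statistical structure of a cross-sectional
LPS-challenge study: two genotypes (wild-type and receptor-null), seven
compartments (plasma + six organs), a 20-mediator panel, seven sacrifice
times over 0–48 h, and a handful of mice per genotype per time point.  It is
an *emulator* of that structure for testing the analysis pipeline, not a
mechanistic model of TLR4 signaling.

Model
-----
Each organ compartment ``c`` mounts a gamma-shaped pulse in log10
concentration space, peaking at time τ_c::

    pulse(t; τ, α) = (t/τ)^α · exp(α · (1 − t/τ))      (peak height 1 at t=τ)

The log10 concentration of mediator ``m`` in organ ``c`` for mouse ``i``
sacrificed at time ``t`` is::

    x = b_m + s_i · A_{m,c} · g · pulse(t; τ_c + δ·[KO], α_c) + ε

where ``A_{m,c} = a_m·β_{m,c}`` combines a per-mediator amplitude with a
per-compartment responsiveness mask β (each compartment induces a seeded
subset of the panel, giving compartments distinct correlation signatures),
``g = ρ`` for the receptor-null genotype and 1 otherwise, ``s_i = exp(u_i)``
with ``u_i ~ N(0, σ_mouse²)`` is a per-mouse severity multiplier shared
across all mediators and compartments of that mouse (the sole source of
cross-mediator correlation, as befits a cross-sectional design where
correlations arise across animals), and ``ε ~ N(0, σ²)`` i.i.d.

Plasma mixes local production with lagged spillover from the organs::

    plasma pulse term = φ · A_{m,plasma} · pulse(t; τ_p)
                      + (1−φ) · Σ_c w_c · A_{m,c} · pulse(max(t−L, 0); τ_c)

so with lag ``L > 0`` the organs' correlation signatures appear in plasma
only after their pulses have risen — the signal the spillover detector must
recover.  Concentrations are ``10**x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import SchemaError
from .panel_io import (
    DEFAULT_COMPARTMENTS,
    DEFAULT_MEDIATORS,
    DEFAULT_SAMPLING_TIMES,
    CompartmentSet,
    MediatorPanel,
    TimecourseDataset,
)

#: Default organ/plasma peak times (h), mirroring a spleen-first cascade.
DEFAULT_TAU = {
    "spleen": 1.0, "plasma": 2.0, "heart": 5.0, "liver": 9.0,
    "kidney": 14.0, "gut": 18.0, "lung": 18.0,
}

#: Plasma spillover mixing weights over organs (sum to 1); concentrated on
#: the large filtering organs whose signatures dominate the systemic
#: compartment.
DEFAULT_WEIGHTS = {
    "liver": 0.40, "heart": 0.40, "kidney": 0.12, "gut": 0.08,
    "lung": 0.0, "spleen": 0.0,
}


class KineticsConfig(BaseModel):
    """Parameters of the synthetic endotoxemia generator.

    Times are hours; baselines, amplitudes and noise SDs are log10 pg/ml
    (pg/mg protein for tissues).  Defaults are the package's standard study
    conditions and are documented in the methods note.
    """

    mediators: tuple[str, ...] = DEFAULT_MEDIATORS
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    plasma_label: str = "plasma"
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES

    tau: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_TAU))
    pulse_shape: float = 2.0          # α: dimensionless pulse-width parameter
    baseline_range: tuple[float, float] = (0.5, 1.5)   # b_m ~ U(range), log10
    amplitude_range: tuple[float, float] = (1.8, 2.8)  # a_m ~ U(range), log10
    n_responsive: int = 14            # mediators induced per organ
    n_core: int = 12                  # shared parenchymal-core mediators

    rho: float = 0.2                  # KO amplitude multiplier, in [0, 1]
    delta: float = 6.0                # KO peak delay (h)

    weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    lag: float = 4.0                  # spillover lag L (h)
    phi: float = 0.7                  # local plasma production fraction

    sigma: float = 0.15               # measurement noise SD (log10)
    sigma_mouse: float = 0.6          # per-mouse severity SD (log scale)

    n_wt: int = 8                     # mice per time point, wild-type
    n_ko: int = 4                     # mice per time point, receptor-null
    genotypes: tuple[str, str] = ("WT", "KO")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "KineticsConfig":
        organs = [c for c in self.compartments if c != self.plasma_label]
        if self.plasma_label not in self.compartments:
            raise ValueError("plasma_label must be a compartment")
        missing = [c for c in self.compartments if c not in self.tau]
        if missing:
            raise ValueError(f"tau missing for compartments: {missing}")
        if any(self.tau[c] <= 0 for c in self.compartments):
            raise ValueError("all tau must be positive")
        if self.pulse_shape <= 0:
            raise ValueError("pulse_shape must be positive")
        w = [self.weights.get(c, 0.0) for c in organs]
        if any(x < 0 for x in w):
            raise ValueError("spillover weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"spillover weights must sum to 1 over organs, got {sum(w)}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.sigma < 0 or self.sigma_mouse < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 < self.n_responsive <= len(self.mediators):
            raise ValueError("n_responsive must be in 1..len(mediators)")
        if not 0 <= self.n_core <= self.n_responsive:
            raise ValueError("n_core must be in 0..n_responsive")
        if (self.n_responsive - self.n_core) > len(self.mediators) - self.n_core:
            raise ValueError("too few non-core mediators for the specific set")
        if max(self.tau.values()) > max(self.sampling_times):
            import warnings
            warnings.warn("sampling_times do not cover the slowest planted peak",
                          stacklevel=2)
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of one synthetic dataset, for recovery tests."""

    ordering: tuple[str, ...]            # compartments sorted by effective peak
    peak_times: dict[str, float]         # effective peak time per compartment
    spillover_lag: float
    genotype_multiplier: float
    responsive: dict[str, tuple[str, ...]]  # induced mediators per compartment
    seed: int


def mediator_curve(t, tau: float, alpha: float, b: float, a: float):
    """Expected log10 concentration of a gamma-shaped mediator pulse.

    ``b + a·(t/τ)^α·exp(α·(1 − t/τ))``: equals ``b + a`` exactly at ``t = τ``,
    ``b`` at ``t = 0``, and decays back to ``b`` as ``t → ∞``.
    """
    params = np.asarray([tau, alpha, b, a], dtype=float)
    if not np.all(np.isfinite(params)):
        raise SchemaError("mediator_curve parameters must be finite")
    if tau <= 0 or alpha <= 0:
        raise SchemaError("mediator_curve requires tau > 0 and alpha > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise SchemaError("mediator_curve requires t >= 0")
    return b + a * _pulse(t, tau, alpha)


def _pulse(t, tau, alpha):
    """Unit-peak gamma pulse; scalar tau/alpha or broadcastable arrays."""
    t = np.asarray(t, dtype=float)
    x = t / tau
    with np.errstate(divide="ignore"):
        out = np.where(x > 0, np.power(x, alpha) * np.exp(alpha * (1.0 - x)), 0.0)
    return out


def _draw_structure(cfg: KineticsConfig, rng: np.random.Generator):
    """Per-mediator baselines/amplitudes and per-compartment response mask.

    Organs induce a shared systemic core of ``n_core`` mediators (the
    canonical broadly-induced parenchymal program) plus an organ-specific
    complement drawn from the non-core panel.  Plasma's *locally produced*
    program is the non-core complement — blood-cell-derived mediators
    distinct from the parenchymal core — so the plasma correlation signature
    resembles the organs' only to the extent spillover actually carries
    their programs into the blood.
    """
    m = len(cfg.mediators)
    b = rng.uniform(*cfg.baseline_range, size=m)
    a = rng.uniform(*cfg.amplitude_range, size=m)
    mask = np.zeros((m, len(cfg.compartments)))
    core = rng.choice(m, size=cfg.n_core, replace=False)
    noncore = np.setdiff1d(np.arange(m), core)
    n_specific = cfg.n_responsive - cfg.n_core
    responsive: dict[str, tuple[str, ...]] = {}
    for j, c in enumerate(cfg.compartments):
        if c == cfg.plasma_label:
            idx = noncore
        else:
            idx = np.concatenate(
                [core, rng.choice(noncore, size=n_specific, replace=False)])
        mask[idx, j] = 1.0
        responsive[c] = tuple(cfg.mediators[i] for i in sorted(idx))
    return b, a, mask, responsive


def _amplitude_profile(cfg: KineticsConfig, a: np.ndarray, mask: np.ndarray,
                       t: float, genotype_is_ko: bool) -> np.ndarray:
    """Pulse term A_{m,c}·pulse_c(t) for every (mediator, compartment)."""
    tau_shift = cfg.delta if genotype_is_ko else 0.0
    organs = [c for c in cfg.compartments if c != cfg.plasma_label]
    prof = np.zeros((len(cfg.mediators), len(cfg.compartments)))
    for j, c in enumerate(cfg.compartments):
        if c == cfg.plasma_label:
            own = _pulse(t, cfg.tau[c] + tau_shift, cfg.pulse_shape)
            spill = np.zeros(len(cfg.mediators))
            for oc in organs:
                jo = cfg.compartments.index(oc)
                gp = _pulse(max(t - cfg.lag, 0.0), cfg.tau[oc] + tau_shift,
                            cfg.pulse_shape)
                spill += cfg.weights.get(oc, 0.0) * a * mask[:, jo] * gp
            prof[:, j] = cfg.phi * a * mask[:, j] * own + (1 - cfg.phi) * spill
        else:
            g = _pulse(t, cfg.tau[c] + tau_shift, cfg.pulse_shape)
            prof[:, j] = a * mask[:, j] * g
    return prof


def _effective_peak_times(cfg: KineticsConfig, a: np.ndarray,
                          mask: np.ndarray) -> dict[str, float]:
    """Planted peak time per compartment (wild-type kinetics).

    Organs peak exactly at τ_c.  Plasma is a mixture of its own pulse and the
    lagged organ pulses, so its observable peak is the argmax of the mixed
    mean pulse, found numerically on a fine grid.
    """
    peaks = {c: cfg.tau[c] for c in cfg.compartments if c != cfg.plasma_label}
    grid = np.arange(0.0, max(cfg.sampling_times) + 0.05, 0.05)
    mixed = np.array([
        _amplitude_profile(cfg, a, mask, t, genotype_is_ko=False)[
            :, cfg.compartments.index(cfg.plasma_label)].mean()
        for t in grid
    ])
    peaks[cfg.plasma_label] = float(grid[int(np.argmax(mixed))])
    return peaks


def simulate_dataset(cfg: KineticsConfig,
                     seed: Optional[int] = None
                     ) -> tuple[TimecourseDataset, GroundTruth]:
    """Generate one cross-sectional dataset plus its planted ground truth.

    Fully reproducible from ``seed`` (defaults to ``cfg.seed``).
    """
    seed = cfg.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    b, a, mask, responsive = _draw_structure(cfg, rng)

    rows_vals: list[np.ndarray] = []
    rows_meta: list[tuple[str, str, float]] = []
    n_by_g = {cfg.genotypes[0]: cfg.n_wt, cfg.genotypes[1]: cfg.n_ko}
    for g in cfg.genotypes:
        is_ko = g == cfg.genotypes[1]
        amp_factor = cfg.rho if is_ko else 1.0
        for ti, t in enumerate(cfg.sampling_times):
            prof = _amplitude_profile(cfg, a, mask, float(t), is_ko)
            for i in range(n_by_g[g]):
                u = rng.normal(0.0, cfg.sigma_mouse)
                severity = np.exp(u)
                eps = rng.normal(0.0, cfg.sigma,
                                 size=(len(cfg.mediators), len(cfg.compartments)))
                logx = b[:, None] + severity * amp_factor * prof + eps
                rows_vals.append(10.0 ** logx)
                rows_meta.append((f"{g}_t{ti:02d}_m{i + 1}", g, float(t)))

    med_idx = np.repeat(np.arange(len(cfg.mediators)), len(cfg.compartments))
    comp_idx = np.tile(np.arange(len(cfg.compartments)), len(cfg.mediators))
    records = []
    for (mouse, g, t), vals in zip(rows_meta, rows_vals):
        flat = vals[med_idx, comp_idx]
        records.append(pd.DataFrame({
            "mouse_id": mouse, "genotype": g, "time_h": t,
            "compartment": np.asarray(cfg.compartments)[comp_idx],
            "mediator": np.asarray(cfg.mediators)[med_idx],
            "concentration": flat,
        }))
    data = pd.concat(records, ignore_index=True)
    ds = TimecourseDataset(
        data,
        panel=MediatorPanel(cfg.mediators),
        compartments=CompartmentSet(cfg.compartments, plasma_label=cfg.plasma_label),
        sampling_times=cfg.sampling_times,
    )
    peaks = _effective_peak_times(cfg, a, mask)
    ordering = tuple(sorted(cfg.compartments, key=lambda c: peaks[c]))
    truth = GroundTruth(ordering=ordering, peak_times=peaks,
                        spillover_lag=cfg.lag, genotype_multiplier=cfg.rho,
                        responsive=responsive, seed=seed)
    return ds, truth


def null_dataset(cfg: KineticsConfig, seed: Optional[int] = None
                 ) -> TimecourseDataset:
    """Dataset with no time and no genotype effect (all amplitudes zero).

    Used for type-I-error calibration: concentrations are i.i.d. log-normal
    around per-mediator baselines.
    """
    null_cfg = cfg.model_copy(update={"amplitude_range": (0.0, 0.0), "rho": 1.0})
    ds, _ = simulate_dataset(null_cfg, seed=seed)
    return ds


def no_spillover_config(cfg: KineticsConfig) -> KineticsConfig:
    """Variant with fully local plasma production (φ = 1): no spillover."""
    return cfg.model_copy(update={"phi": 1.0})
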