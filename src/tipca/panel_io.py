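"""Data model, validation, normalization and I/O for multiplex mediator panels.

The central container is :class:`TimecourseDataset`: a long-format table of
mediator concentrations with one row per (mouse, genotype, time, compartment,
mediator).  The design is cross-sectional — every mouse is sacrificed at
exactly one time point — so time courses are population-level summaries, not
longitudinal trajectories.  Concentrations are pg/ml for plasma and pg/mg
total protein for solid tissues; the unit is implied by the compartment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, IntegrityError, SchemaError

logger = logging.getLogger("tipca")

#: 20-plex mouse cytokine/chemokine/growth-factor bead panel.
DEFAULT_MEDIATORS: tuple[str, ...] = (
    "GM-CSF", "IFN-g", "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6",
    "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-17A", "IP-10", "KC",
    "MCP-1", "MIG", "MIP-1a", "TNF-a", "VEGF",
)

#: Sampled compartments: systemic circulation plus six parenchymal organs.
DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "plasma", "liver", "heart", "gut", "lung", "spleen", "kidney",
)

DEFAULT_SAMPLING_TIMES: tuple[float, ...] = (0.0, 1.0, 4.0, 6.0, 12.0, 24.0, 48.0)

#: Canonical long-format column names.
CANONICAL_COLUMNS = (
    "mouse_id", "genotype", "time_h", "compartment", "mediator", "concentration",
)


@dataclass(frozen=True)
class MediatorPanel:
    """Ordered, unique list of mediator identifiers."""

    names: tuple[str, ...] = DEFAULT_MEDIATORS

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise SchemaError("mediator panel must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("mediator panel names must be unique")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


@dataclass(frozen=True)
class CompartmentSet:
    """Ordered compartments with one name designated as systemic circulation."""

    names: tuple[str, ...] = DEFAULT_COMPARTMENTS
    plasma_label: str = "plasma"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError("compartment names must be unique")
        if self.plasma_label not in self.names:
            raise SchemaError(
                f"plasma_label {self.plasma_label!r} not among compartments {self.names}"
            )

    @property
    def organs(self) -> tuple[str, ...]:
        """Compartments other than the systemic circulation."""
        return tuple(n for n in self.names if n != self.plasma_label)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


@dataclass
class TimecourseDataset:
    """Validated long-format collection of concentration measurements.

    Parameters
    ----------
    data
        DataFrame with the canonical columns ``mouse_id, genotype, time_h,
        compartment, mediator, concentration``.  Missing concentrations are
        NaN; negative concentrations are rejected.
    panel, compartments
        Variable spaces; measurements referencing unknown mediators or
        compartments are rejected.
    sampling_times
        The cross-sectional sacrifice grid, ascending, starting at 0.
    """

    data: pd.DataFrame
    panel: MediatorPanel = field(default_factory=MediatorPanel)
    compartments: CompartmentSet = field(default_factory=CompartmentSet)
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"dataset missing mandatory columns: {missing}")
        self.data = self.data.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        self.data["time_h"] = self.data["time_h"].astype(float)
        self.data["concentration"] = pd.to_numeric(
            self.data["concentration"], errors="coerce"
        )
        self.sampling_times = tuple(float(t) for t in self.sampling_times)
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise SchemaError("sampling_times must be sorted ascending")
        if self.sampling_times[0] != 0.0:
            raise SchemaError("sampling_times must start at 0 (pre-challenge baseline)")

        bad_time = ~self.data["time_h"].isin(self.sampling_times)
        if bad_time.any():
            t = self.data.loc[bad_time, "time_h"].iloc[0]
            raise IntegrityError(
                f"time {t} h not on the declared sampling grid {self.sampling_times}"
            )
        unknown_m = ~self.data["mediator"].isin(self.panel.names)
        if unknown_m.any():
            raise SchemaError(
                f"unknown mediator {self.data.loc[unknown_m, 'mediator'].iloc[0]!r}"
            )
        unknown_c = ~self.data["compartment"].isin(self.compartments.names)
        if unknown_c.any():
            raise SchemaError(
                f"unknown compartment {self.data.loc[unknown_c, 'compartment'].iloc[0]!r}"
            )
        neg = self.data["concentration"] < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise IntegrityError(f"negative concentration at row {row}")

        dup = self.data.duplicated(
            subset=["mouse_id", "time_h", "compartment", "mediator"], keep=False
        )
        if dup.any():
            first = self.data.loc[dup].iloc[0]
            raise IntegrityError(
                "duplicate measurement for "
                f"(mouse={first['mouse_id']!r}, time={first['time_h']}, "
                f"compartment={first['compartment']!r}, mediator={first['mediator']!r})"
            )

        # Cross-sectional design: a mouse exists at exactly one time and one genotype.
        per_mouse = self.data.groupby("mouse_id")[["time_h", "genotype"]].nunique()
        offending = per_mouse[(per_mouse["time_h"] > 1) | (per_mouse["genotype"] > 1)]
        if len(offending):
            raise IntegrityError(
                f"mouse {offending.index[0]!r} appears at multiple times or genotypes "
                "(cross-sectional sacrifice design requires exactly one)"
            )

    # -- introspection -------------------------------------------------
    @property
    def genotypes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.data["genotype"]:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def n_measurements(self) -> int:
        return len(self.data)

    def subset(self, genotype: str | None = None,
               times: Iterable[float] | None = None) -> pd.DataFrame:
        df = self.data
        if genotype is not None:
            df = df[df["genotype"] == genotype]
        if times is not None:
            df = df[df["time_h"].isin([float(t) for t in times])]
        return df

    def equals(self, other: "TimecourseDataset") -> bool:
        a = self.data.sort_values(list(CANONICAL_COLUMNS[:5])).reset_index(drop=True)
        b = other.data.sort_values(list(CANONICAL_COLUMNS[:5])).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        keys_equal = all(a[c].astype(str).equals(b[c].astype(str))
                         for c in CANONICAL_COLUMNS[:5])
        vals = np.allclose(a["concentration"], b["concentration"],
                           rtol=1e-9, atol=1e-12, equal_nan=True)
        return bool(keys_equal and vals
                    and self.panel == other.panel
                    and self.compartments == other.compartments
                    and self.sampling_times == other.sampling_times)


@dataclass
class ZScoredMatrix:
    """Observations × variables matrix standardized column-wise.

    Each column has mean 0 and *population* (denominator n) standard
    deviation 1 over non-missing entries, so that Σz² = n per column and the
    correlation-scale PCA trace equals the number of variables.  Columns that
    are constant are set to zero and recorded in ``constant_columns``.
    """

    values: pd.DataFrame  # index (mouse_id, time_h); columns (mediator, compartment)
    constant_columns: tuple[tuple[str, str], ...]
    scaling_scope: str

    @property
    def obs_keys(self) -> list[tuple[str, float]]:
        return list(self.values.index)

    @property
    def var_keys(self) -> list[tuple[str, str]]:
        return list(self.values.columns)


def _pivot(ds: TimecourseDataset, genotype: str | None,
           times: Iterable[float] | None) -> pd.DataFrame:
    """Observations × (mediator, compartment) wide matrix for one genotype."""
    df = ds.subset(genotype, times)
    if df.empty:
        raise InsufficientDataError(
            f"no observations for genotype={genotype!r}, times={times}"
        )
    wide = df.pivot_table(
        index=["mouse_id", "time_h"],
        columns=["mediator", "compartment"],
        values="concentration",
        aggfunc="first",
        dropna=False,
    )
    cols = [(m, c) for m in ds.panel.names for c in ds.compartments.names
            if (m, c) in wide.columns]
    return wide.loc[:, cols]


def _zscore_frame(wide: pd.DataFrame, log_transform: bool = False
                  ) -> tuple[pd.DataFrame, tuple[tuple[str, str], ...]]:
    vals = wide.to_numpy(dtype=float)
    if log_transform:
        vals = np.log10(vals + 1.0)
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=0)  # population convention
    n_nonmiss = np.sum(~np.isnan(vals), axis=0)
    # relative tolerance: cancellation error scales with column magnitude
    constant = (sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)) | (n_nonmiss < 2)
    z = np.zeros_like(vals)
    ok = ~constant
    z[:, ok] = (vals[:, ok] - mean[ok]) / sd[ok]
    z[:, constant] = 0.0
    z[np.isnan(vals)] = np.nan
    z[:, constant] = np.where(np.isnan(vals[:, constant]), np.nan, 0.0)
    out = pd.DataFrame(z, index=wide.index, columns=wide.columns)
    const_keys = tuple(wide.columns[i] for i in np.flatnonzero(constant))
    return out, const_keys


def zscore(ds: TimecourseDataset, genotype: str | None = None,
           obs_filter: Iterable[float] | None = None,
           log_transform: bool = False) -> ZScoredMatrix:
    """Standardize each (mediator, compartment) column to mean 0, SD 1.

    The SD uses the population (denominator n) convention so that Σz² = n per
    column.  If ``log_transform``, values are mapped through log10(x + 1)
    before centering (cytokine data are heavy-tailed; off by default).
    Constant columns are set to 0 and flagged.
    """
    wide = _pivot(ds, genotype, obs_filter)
    if len(wide) < 2:
        raise InsufficientDataError(
            f"z-scoring needs >=2 observations, got {len(wide)}"
        )
    z, const = _zscore_frame(wide, log_transform=log_transform)
    times = sorted(set(t for _, t in z.index))
    scope = (f"genotype={genotype};times={','.join(str(t) for t in times)};"
             f"log10={log_transform}")
    if const:
        logger.info("z-scoring: %d constant column(s) set to 0", len(const))
    return ZScoredMatrix(values=z, constant_columns=const, scaling_scope=scope)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_dataset(path: str | Path,
                 schema: Mapping[str, str] | None = None,
                 panel: MediatorPanel | None = None,
                 compartments: CompartmentSet | None = None,
                 sampling_times: Sequence[float] | None = None,
                 wide: bool = False) -> TimecourseDataset:
    """Read a long-format CSV/TSV of mediator concentrations.

    Parameters
    ----------
    schema
        Optional mapping from canonical names (``mouse_id``, ``genotype``,
        ``time_h``, ``compartment``, ``mediator``, ``concentration``) to the
        column names used in the file.
    wide
        If True, the file has one column per mediator instead of a
        mediator/concentration pair; remaining mapped id columns are kept and
        mediator columns are melted into long format.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    id_cols = ["mouse_id", "genotype", "time_h", "compartment"]
    if wide:
        missing = [c for c in id_cols if c not in raw.columns]
        if missing:
            raise SchemaError(f"wide input missing mandatory columns: {missing}")
        value_cols = [c for c in raw.columns if c not in id_cols]
        raw = raw.melt(id_vars=id_cols, value_vars=value_cols,
                       var_name="mediator", value_name="concentration")
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"input missing mandatory columns: {missing}")

    conc = pd.to_numeric(raw["concentration"], errors="coerce")
    n_bad = int((conc.isna() & raw["concentration"].notna()).sum())
    if n_bad:
        logger.warning("load_dataset: %d unparseable concentration cell(s) set "
                       "to missing", n_bad)
    neg = conc < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise IntegrityError(f"negative concentration at row {row} of {path.name}")
    raw = raw.assign(concentration=conc)

    if panel is None:
        names = list(dict.fromkeys(raw["mediator"]))
        default = [m for m in DEFAULT_MEDIATORS if m in names]
        panel = MediatorPanel(tuple(default) if len(default) == len(names)
                              else tuple(names))
    if compartments is None:
        names = list(dict.fromkeys(raw["compartment"]))
        default = [c for c in DEFAULT_COMPARTMENTS if c in names]
        ordered = tuple(default) if len(default) == len(names) else tuple(names)
        plasma = "plasma" if "plasma" in ordered else ordered[0]
        compartments = CompartmentSet(ordered, plasma_label=plasma)
    if sampling_times is None:
        sampling_times = tuple(sorted(raw["time_h"].astype(float).unique()))
    return TimecourseDataset(raw, panel=panel, compartments=compartments,
                             sampling_times=tuple(sampling_times))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(obj, path: str | Path) -> None:
    """Write a pipeline result deterministically.

    Tabular objects (DataFrames, datasets, contribution tables) become CSV
    with a header; nested report objects become JSON.  Floats are written at
    full double precision so write→read round-trips are exact to 1e-12.
    """
    path = Path(path)
    if not path.parent.exists():
        raise SchemaError(f"parent directory does not exist: {path.parent}")
    to_frame = getattr(obj, "to_frame", None)
    if isinstance(obj, TimecourseDataset):
        obj.data.to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif to_frame is not None and path.suffix.lower() != ".json":
        to_frame().to_csv(path, index=False)
    else:
        to_json = getattr(obj, "to_json_dict", None)
        payload = to_json() if to_json is not None else obj
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
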