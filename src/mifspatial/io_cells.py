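"""Reading, validation and writing of per-cell and clinical tables.

A multiplex-immunofluorescence (mIF) image-analysis export is one row per
segmented cell: patient, region (invasive margin ``IM`` / tumor center
``TC``), tissue-microarray core index, 2-D nucleus coordinates in microns,
tumor/stroma compartment, and one pre-thresholded boolean column per marker.
This module assembles such tables into :class:`TissueSite` objects (one per
patient x region x core x staining panel), reads the patient-level clinical
table, and round-trips tidy metric tables.

Coordinates are 2-D and translation-invariant; the origin is arbitrary per
core. Marker positivity arrives as binary calls - continuous intensities are
out of scope. A declarative :class:`TableDialect` maps foreign column names,
region labels and truthy strings so Inform/phenoptr-style exports can be
ingested without code changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REGIONS = ("IM", "TC")
COMPARTMENTS = ("tumor", "stroma")

#: Marker sets per staining panel. ``combined`` is the union, used by the
#: synthetic generator so that cross-lineage distances (e.g. CD8 to CD4)
#: exist within one site.
PANEL_MARKERS: Mapping[str, tuple[str, ...]] = {
    "panel1": ("CD8", "CD103", "PD1", "TIM3", "GZMB", "PANCK"),
    "panel2": ("CD4", "FOXP3", "CD31", "ASMA", "HIF1A", "PANCK"),
    "combined": (
        "CD8", "CD103", "PD1", "TIM3", "GZMB",
        "CD4", "FOXP3", "CD31", "ASMA", "HIF1A", "PANCK",
    ),
}

ALL_MARKERS: tuple[str, ...] = PANEL_MARKERS["combined"]

MANDATORY_CELL_COLUMNS = (
    "patient_id", "region", "core", "x_um", "y_um", "compartment",
)

_DEFAULT_TRUTHY = frozenset({"1", "true", "yes", "pos", "+", "t", "y"})
_DEFAULT_FALSY = frozenset({"0", "false", "no", "neg", "-", "f", "n", ""})


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable layout."""


# ---------------------------------------------------------------------------
# geometry descriptors for core extents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Disc:
    """Circular core extent (TMA cores are 1 mm diameter discs)."""

    cx: float = 0.0
    cy: float = 0.0
    radius: float = 500.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2 <= self.radius**2 * (1 + 1e-12)

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangular window (used for simulation checks)."""

    width: float
    height: float
    x0: float = 0.0
    y0: float = 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x0) & (x <= self.x0 + self.width)
            & (y >= self.y0) & (y <= self.y0 + self.height)
        )

    @property
    def area(self) -> float:
        return self.width * self.height


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """One segmented cell: nucleus position, marker calls, optional label."""

    cell_id: str
    x: float
    y: float
    compartment: str
    markers: Mapping[str, bool]
    phenotype: Optional[str] = None


@dataclass
class TissueSite:
    """All cells of one TMA core (patient x region x core x panel).

    Cells live in ``df`` with columns ``cell_id, x, y, compartment``, one
    boolean column per panel marker, and ``phenotype`` (NaN until assigned).
    """

    patient_id: str
    region: str
    core_index: int
    panel_id: str
    df: pd.DataFrame
    extent: Union[Disc, Rect, None] = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}, expected one of {REGIONS}")
        if self.core_index < 1:
            raise ValueError("core_index must be >= 1")
        if self.panel_id not in PANEL_MARKERS:
            raise ValueError(f"unknown panel {self.panel_id!r}")
        missing = [m for m in self.markers if m not in self.df.columns]
        if missing:
            raise SchemaError(f"site is missing marker column(s): {missing}")
        if "phenotype" not in self.df.columns:
            self.df = self.df.assign(phenotype=pd.Series(pd.NA, index=self.df.index, dtype="object"))
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("non-finite cell coordinates")
        if self.extent is not None and len(self.df):
            inside = self.extent.contains(xy[:, 0], xy[:, 1])
            if not inside.all():
                raise ValueError(
                    f"{int((~inside).sum())} cell(s) outside the declared extent"
                )

    # -- convenience -------------------------------------------------------
    @property
    def markers(self) -> tuple[str, ...]:
        return PANEL_MARKERS[self.panel_id]

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.patient_id, self.region, self.core_index, self.panel_id)

    def phenotype_mask(self, labels: Union[str, Iterable[str]]) -> np.ndarray:
        if isinstance(labels, str):
            labels = {labels}
        return self.df["phenotype"].isin(set(labels)).to_numpy()

    def coords(self, labels: Union[str, Iterable[str], None] = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to phenotype labels."""
        if labels is None:
            sub = self.df
        else:
            sub = self.df[self.phenotype_mask(labels)]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def cells(self) -> Iterator[Cell]:
        marker_cols = list(self.markers)
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield Cell(
                cell_id=str(d["cell_id"]),
                x=float(d["x"]),
                y=float(d["y"]),
                compartment=d["compartment"],
                markers={m: bool(d[m]) for m in marker_cols},
                phenotype=None if pd.isna(d.get("phenotype")) else d["phenotype"],
            )


@dataclass
class PatientRecord:
    """One patient's clinical covariates and recurrence-free survival."""

    patient_id: str
    age: Optional[float] = None
    gender: Optional[str] = None
    smoking_index: Optional[float] = None
    ecog: Optional[int] = None
    tumor_diameter: Optional[float] = None
    histology: Optional[str] = None
    t_stage: Optional[str] = None
    n_stage: Optional[str] = None
    ajcc_stage: Optional[str] = None
    lnm: Optional[bool] = None
    rfs_time: Optional[float] = None
    rfs_event: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_stage is not None:
            derived = _n_stage_positive(self.n_stage)
            if self.lnm is None:
                self.lnm = derived
            elif bool(self.lnm) != derived:
                raise ValueError(
                    f"patient {self.patient_id}: lnm={self.lnm} inconsistent "
                    f"with n_stage={self.n_stage}"
                )
        if self.rfs_time is not None and not self.rfs_time > 0:
            raise ValueError(f"patient {self.patient_id}: rfs_time must be > 0")


def _n_stage_positive(n_stage: Union[str, int, float]) -> bool:
    if isinstance(n_stage, str):
        s = n_stage.strip().upper()
        if s.startswith("N"):
            s = s[1:]
        value = int(s)
    else:
        value = int(n_stage)
    return value >= 1


# ---------------------------------------------------------------------------
# dialect
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """Declarative mapping from a foreign per-cell CSV onto the canonical schema.

    ``columns`` maps canonical names (``patient_id``, ``region``, ``core``,
    ``panel``, ``x_um``, ``y_um``, ``compartment`` and marker names) to the
    column names actually present in the file. ``region_map`` translates raw
    region strings (e.g. ``margin``) onto ``IM``/``TC``.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    region_map: Mapping[str, str] = field(default_factory=dict)
    truthy: frozenset = _DEFAULT_TRUTHY
    falsy: frozenset = _DEFAULT_FALSY

    def source_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def map_region(self, raw: str) -> Optional[str]:
        raw = str(raw).strip()
        if raw in self.region_map:
            return self.region_map[raw]
        if raw.upper() in REGIONS:
            return raw.upper()
        return None

    def coerce_bool(self, values: pd.Series, column: str) -> np.ndarray:
        if values.dtype == bool:
            return values.to_numpy()
        out = np.empty(len(values), dtype=bool)
        for i, v in enumerate(values):
            if isinstance(v, (bool, np.bool_)):
                out[i] = bool(v)
                continue
            if isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool):
                if pd.isna(v):
                    raise ValueError(f"missing marker value in column {column!r} at row {values.index[i]}")
                out[i] = bool(v)
                continue
            s = str(v).strip().lower()
            if s in self.truthy:
                out[i] = True
            elif s in self.falsy:
                out[i] = False
            else:
                raise ValueError(
                    f"cannot interpret {v!r} in column {column!r} as a boolean"
                )
        return out

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TableDialect":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            columns=raw.get("columns", {}),
            region_map=raw.get("region_map", {}),
            truthy=frozenset(raw.get("truthy", _DEFAULT_TRUTHY)),
            falsy=frozenset(raw.get("falsy", _DEFAULT_FALSY)),
        )


# ---------------------------------------------------------------------------
# per-cell table I/O
# ---------------------------------------------------------------------------

def read_cell_table(
    path: Union[str, Path],
    dialect: Optional[TableDialect] = None,
    extent: Union[Disc, Rect, None] = None,
) -> list[TissueSite]:
    """Read a per-cell CSV into one :class:`TissueSite` per (patient, region,
    core, panel), preserving row order within each site."""
    dialect = dialect or TableDialect()
    raw = pd.read_csv(path)
    for canonical in MANDATORY_CELL_COLUMNS:
        src = dialect.source_column(canonical)
        if src not in raw.columns:
            raise SchemaError(f"missing mandatory column {src!r} (for {canonical!r})")
    if raw.empty:
        logger.warning("cell table %s has a header but no rows", path)
        return []

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw[dialect.source_column("patient_id")].astype(str)
    df["core"] = raw[dialect.source_column("core")].astype(int)

    panel_src = dialect.source_column("panel")
    if panel_src in raw.columns:
        df["panel"] = raw[panel_src].astype(str)
    else:
        df["panel"] = "panel1"
    bad_panel = ~df["panel"].isin(PANEL_MARKERS)
    if bad_panel.any():
        idx = int(df.index[bad_panel][0])
        raise ValueError(f"unknown panel {df['panel'][idx]!r} at row {idx}")

    regions = raw[dialect.source_column("region")].map(dialect.map_region)
    if regions.isna().any():
        idx = int(regions.index[regions.isna()][0])
        raise ValueError(
            f"unknown region label {raw[dialect.source_column('region')][idx]!r} at row {idx}"
        )
    df["region"] = regions

    for canonical, out in (("x_um", "x"), ("y_um", "y")):
        vals = pd.to_numeric(raw[dialect.source_column(canonical)], errors="coerce")
        if vals.isna().any():
            idx = int(vals.index[vals.isna()][0])
            raise ValueError(
                f"non-numeric coordinate in column {dialect.source_column(canonical)!r} at row {idx}"
            )
        df[out] = vals.astype(float)

    comp = raw[dialect.source_column("compartment")].astype(str).str.strip().str.lower()
    bad = ~comp.isin(COMPARTMENTS)
    if bad.any():
        idx = int(comp.index[bad][0])
        raise ValueError(f"unknown compartment {comp[idx]!r} at row {idx}")
    df["compartment"] = comp

    id_src = dialect.source_column("cell_id")
    if id_src in raw.columns:
        df["cell_id"] = raw[id_src].astype(str)
    else:
        df["cell_id"] = [f"c{i}" for i in raw.index]

    pheno_src = dialect.source_column("phenotype")
    if pheno_src in raw.columns:
        df["phenotype"] = raw[pheno_src].where(raw[pheno_src].notna(), pd.NA).astype("object")

    sites: list[TissueSite] = []
    for (pid, region, core, panel), group_idx in df.groupby(
        ["patient_id", "region", "core", "panel"], sort=True
    ).groups.items():
        sub = df.loc[group_idx]
        site_df = sub.drop(columns=["core", "panel"]).reset_index(drop=True)
        for marker in PANEL_MARKERS[panel]:
            src = dialect.source_column(marker)
            if src not in raw.columns:
                raise SchemaError(
                    f"missing marker column {src!r} required by panel {panel!r}"
                )
            site_df[marker] = dialect.coerce_bool(raw.loc[group_idx, src], src)
        sites.append(
            TissueSite(
                patient_id=pid,
                region=region,
                core_index=int(core),
                panel_id=panel,
                df=site_df,
                extent=extent,
            )
        )
    return sites


def write_cell_table(sites: Sequence[TissueSite], path: Union[str, Path]) -> None:
    """Write sites back to the canonical per-cell CSV dialect."""
    frames = []
    for site in sites:
        out = pd.DataFrame(
            {
                "patient_id": site.patient_id,
                "region": site.region,
                "core": site.core_index,
                "panel": site.panel_id,
                "cell_id": site.df["cell_id"],
                "x_um": site.df["x"],
                "y_um": site.df["y"],
                "compartment": site.df["compartment"],
            }
        )
        for marker in ALL_MARKERS:
            out[marker] = site.df[marker].astype(int) if marker in site.df.columns else ""
        if site.df["phenotype"].notna().any():
            out["phenotype"] = site.df["phenotype"]
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clinical table I/O
# ---------------------------------------------------------------------------

_CLINICAL_FLOAT = ("age", "smoking_index", "tumor_diameter", "rfs_time")
_CLINICAL_STR = ("gender", "histology", "t_stage", "n_stage", "ajcc_stage")


def read_clinical_table(path: Union[str, Path]) -> list[PatientRecord]:
    """Read the one-row-per-patient clinical CSV.

    ``lnm`` is derived from ``n_stage`` when absent; an explicit ``lnm``
    inconsistent with ``n_stage`` is an error, as is a duplicated patient id.
    """
    raw = pd.read_csv(path)
    if "patient_id" not in raw.columns:
        raise SchemaError("missing mandatory column 'patient_id'")
    ids = raw["patient_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id: {dup.iloc[0]!r}")

    records = []
    for _, row in raw.iterrows():
        kwargs: dict = {"patient_id": str(row["patient_id"])}
        for col in _CLINICAL_FLOAT:
            if col in raw.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        for col in _CLINICAL_STR:
            if col in raw.columns and pd.notna(row[col]):
                kwargs[col] = str(row[col])
        if "ecog" in raw.columns and pd.notna(row["ecog"]):
            kwargs["ecog"] = int(row["ecog"])
        for col in ("lnm", "rfs_event"):
            if col in raw.columns and pd.notna(row[col]):
                v = row[col]
                kwargs[col] = bool(v) if isinstance(v, (bool, np.bool_, int, np.integer, float)) else str(v).strip().lower() in _DEFAULT_TRUTHY
        records.append(PatientRecord(**kwargs))
    return records


def clinical_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patient records as a DataFrame indexed by ``patient_id``."""
    rows = [vars(r).copy() for r in records]
    df = pd.DataFrame(rows).set_index("patient_id")
    return df


def write_clinical_table(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    clinical_frame(records).reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metric table round trip
# ---------------------------------------------------------------------------

METRIC_COLUMNS = (
    "patient_id", "region", "metric", "phenotype", "target", "radius", "value",
)


def write_metrics_table(metrics: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a tidy long metric table; undefined values become empty cells."""
    if metrics.empty:
        logger.warning("writing an empty metric table to %s", path)
    out = metrics.copy()
    for col in METRIC_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[[c for c in METRIC_COLUMNS if c in out.columns]
              + [c for c in out.columns if c not in METRIC_COLUMNS]]
    out.to_csv(path, index=False, na_rep="")


def read_metrics_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("phenotype", "target"):
        if col in df.columns:
            df[col] = df[col].astype("object").where(df[col].notna(), pd.NA)
    return df
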