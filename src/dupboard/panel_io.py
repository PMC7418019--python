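"""Quarterly indicator panels: reading, validation, filtering, summaries.

An :class:`IndicatorPanel` holds one drug category's duplicative-prescription
rates (in percent, as published quarterly by Taiwan's national insurer) as a
hospitals x quarters matrix together with hospital metadata (accreditation
type, region, coordinates). Missing quarters are explicit ``NaN`` cells —
never zero, since a 0% rate is legal data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DRUGS = ("antihypertension", "antihyperglycemia", "antihyperlipidemia")
HOSPITAL_TYPES = ("medical_center", "regional", "district")
REGIONS = ("Taipei", "North", "Central", "South", "Kao-Pin", "East")

#: metadata columns expected at the left of a panel CSV, in order
META_COLUMNS = ("id", "name", "htype", "region", "lat", "lon")


class PanelFormatError(ValueError):
    """Malformed panel file: bad header, bad quarter label, bad cell."""


class VocabularyError(ValueError):
    """A value outside a closed vocabulary (hospital type, region, drug)."""


@dataclass(frozen=True)
class Hospital:
    """One hospital's metadata row.

    ``lat``/``lon`` may be ``None`` for statistics-only runs; map export
    skips such hospitals with a warning.
    """

    id: str
    name: str
    htype: str
    region: str
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.htype not in HOSPITAL_TYPES:
            raise VocabularyError(
                f"unknown hospital type {self.htype!r}; expected one of {HOSPITAL_TYPES}"
            )
        if self.region not in REGIONS:
            raise VocabularyError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        for coord, label in ((self.lat, "lat"), (self.lon, "lon")):
            if coord is not None and not np.isfinite(coord):
                raise ValueError(f"{label} must be finite when present, got {coord}")

    @property
    def has_coordinates(self) -> bool:
        return self.lat is not None and self.lon is not None


def parse_quarter(label: str) -> pd.Period:
    """Parse a fiscal-quarter label ("2010Q3" or "2010-Q3") to a Period."""
    text = str(label).strip().upper().replace("-Q", "Q")
    try:
        period = pd.Period(text, freq="Q")
    except Exception as exc:  # pandas raises several parse error types
        raise PanelFormatError(f"cannot parse quarter label {label!r}") from exc
    if "Q" not in text:
        raise PanelFormatError(f"quarter label {label!r} lacks a quarter number")
    return period


def _normalize_quarters(labels) -> list[str]:
    periods = [parse_quarter(lab) for lab in labels]
    if len(set(periods)) != len(periods):
        raise PanelFormatError("duplicate quarter labels in header")
    return [str(p) for p in sorted(periods)]


@dataclass
class IndicatorPanel:
    """Hospitals x quarters rate matrix for one drug category.

    Parameters
    ----------
    drug : str
        One of :data:`DRUGS`.
    hospitals : list of Hospital
    rates : pandas.DataFrame
        Index = hospital ids (same order as ``hospitals``), columns =
        normalized quarter labels in increasing order, values = rates in
        percent with ``NaN`` marking missing quarters.
    """

    drug: str
    hospitals: list[Hospital]
    rates: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise VocabularyError(
                f"unknown drug {self.drug!r}; expected one of {DRUGS}"
            )
        ids = [h.id for h in self.hospitals]
        if len(set(ids)) != len(ids):
            raise PanelFormatError("duplicate hospital ids")
        if list(self.rates.index) != ids:
            raise PanelFormatError("rate-matrix index does not match hospital list")
        quarters = _normalize_quarters(self.rates.columns)
        if list(self.rates.columns) != quarters:
            self.rates = self.rates.copy()
            self.rates.columns = [str(parse_quarter(c)) for c in self.rates.columns]
            self.rates = self.rates[quarters]
        values = self.rates.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("rates must be non-negative percentages")

    @property
    def quarters(self) -> list[str]:
        return list(self.rates.columns)

    @property
    def n_hospitals(self) -> int:
        return len(self.hospitals)

    @property
    def n_quarters(self) -> int:
        return self.rates.shape[1]

    def hospital(self, hospital_id: str) -> Hospital:
        for h in self.hospitals:
            if h.id == hospital_id:
                return h
        raise KeyError(hospital_id)

    def metadata_frame(self) -> pd.DataFrame:
        """Hospital metadata as a DataFrame indexed by id."""
        return pd.DataFrame(
            {
                "name": [h.name for h in self.hospitals],
                "htype": [h.htype for h in self.hospitals],
                "region": [h.region for h in self.hospitals],
                "lat": [h.lat if h.lat is not None else np.nan for h in self.hospitals],
                "lon": [h.lon if h.lon is not None else np.nan for h in self.hospitals],
            },
            index=pd.Index([h.id for h in self.hospitals], name="id"),
        )

    def n_missing(self) -> int:
        return int(self.rates.isna().to_numpy().sum())


def read_panel(path, drug: str) -> IndicatorPanel:
    """Read a panel CSV (``id,name,htype,region,lat,lon,<quarter...>``).

    Empty cells and ``NA`` become missing; non-numeric rates raise a
    ``ValueError`` naming the offending row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    header = list(raw.columns)
    if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
        raise PanelFormatError(
            f"header must start with {','.join(META_COLUMNS)}; got {header[:6]}"
        )
    quarter_cols = header[len(META_COLUMNS):]
    if not quarter_cols:
        raise PanelFormatError("no quarter columns found")

    hospitals: list[Hospital] = []
    for _, row in raw.iterrows():
        lat = row["lat"].strip()
        lon = row["lon"].strip()
        hospitals.append(
            Hospital(
                id=row["id"].strip(),
                name=row["name"],
                htype=row["htype"].strip(),
                region=row["region"].strip(),
                lat=float(lat) if lat not in ("", "NA") else None,
                lon=float(lon) if lon not in ("", "NA") else None,
            )
        )

    matrix = np.full((len(raw), len(quarter_cols)), np.nan)
    for j, col in enumerate(quarter_cols):
        for i, cell in enumerate(raw[col]):
            text = str(cell).strip()
            if text in ("", "NA", "NaN", "nan"):
                continue
            try:
                matrix[i, j] = float(text)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric rate {text!r} at row {hospitals[i].id!r}, "
                    f"column {col!r}"
                ) from exc

    rates = pd.DataFrame(
        matrix,
        index=pd.Index([h.id for h in hospitals], name="id"),
        columns=quarter_cols,
    )
    return IndicatorPanel(drug=drug, hospitals=hospitals, rates=rates)


def write_panel(panel: IndicatorPanel, path) -> None:
    """Write a panel back to the CSV dialect :func:`read_panel` accepts.

    Finite cells round-trip bit-exactly (shortest-repr float formatting);
    missing cells are written as empty strings.
    """
    out = panel.metadata_frame().reset_index()
    out["lat"] = out["lat"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out["lon"] = out["lon"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    for q in panel.quarters:
        out[q] = [
            "" if pd.isna(v) else repr(float(v)) for v in panel.rates[q].to_numpy()
        ]
    out.to_csv(path, index=False)


def filter_complete(panel: IndicatorPanel, required_quarters: int = 25) -> IndicatorPanel:
    """Keep only hospitals fully observed over the last ``required_quarters``.

    Mirrors the study's exclusion criterion: incomplete ratio data over the
    25-quarter window drops the hospital. Ordering is preserved; the count
    excluded per hospital type is logged. An empty result is a warning, not
    an error.
    """
    if required_quarters > panel.n_quarters:
        raise ValueError(
            f"required_quarters={required_quarters} exceeds panel span {panel.n_quarters}"
        )
    window = panel.quarters[-required_quarters:]
    complete_mask = panel.rates[window].notna().all(axis=1)
    kept = [h for h, ok in zip(panel.hospitals, complete_mask) if ok]
    excluded = [h for h, ok in zip(panel.hospitals, complete_mask) if not ok]
    for htype in HOSPITAL_TYPES:
        n_excl = sum(1 for h in excluded if h.htype == htype)
        if n_excl:
            logger.info("filter_complete: excluded %d %s hospitals", n_excl, htype)
    if not kept:
        warnings.warn("filter_complete produced an empty panel", stacklevel=2)
    rates = panel.rates.loc[[h.id for h in kept]]
    return IndicatorPanel(drug=panel.drug, hospitals=kept, rates=rates)


def summarize_counts(panel: IndicatorPanel) -> pd.DataFrame:
    """Hospital-type x region counts with row percentages.

    Reproduces the layout of the study's descriptive table: one row per
    hospital type, one (count, row-%) pair per region, plus a total column.
    Rows with zero hospitals are retained with zero counts.
    """
    if panel.n_hospitals == 0:
        raise ValueError("cannot summarize an empty panel")
    meta = panel.metadata_frame()
    counts = (
        meta.groupby(["htype", "region"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=HOSPITAL_TYPES, columns=REGIONS, fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    pct = counts[list(REGIONS)].div(counts["total"].replace(0, np.nan), axis=0) * 100
    out = counts.copy().astype(float)
    for region in REGIONS:
        out[f"{region}_pct"] = pct[region].fillna(0.0)
    return out
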