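"""Reading, writing and normalising ROI time-series tables.

The central container is :class:`RoiTimeSeries`: a ``T x N`` matrix of
regional BOLD signals sampled every ``tr`` seconds, one column per region.
All downstream event detection assumes z-scored signals, so thresholds are
expressed in SD units.  z-scoring uses the population SD (divide by ``T``),
consistently across the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ZSCORE_TOL = 1e-10


@dataclass(frozen=True)
class RoiTimeSeries:
    """A ``T x N`` matrix of regional signals with acquisition metadata.

    Parameters
    ----------
    data :
        Real matrix, rows are time points, columns are regions.
    tr :
        Repetition time (sampling interval) in seconds, > 0.
    labels :
        Unique region names, one per column.
    zscored :
        True when every column has zero mean and unit population SD.
    """

    data: np.ndarray
    tr: float
    labels: tuple[str, ...]
    zscored: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D time x region matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        T, N = data.shape
        if T < 2:
            raise ValueError("T >= 2 required (need at least two time points)")
        if N < 1:
            raise ValueError("N >= 1 required (need at least one region)")
        if len(self.labels) != N:
            raise ValueError(f"{len(self.labels)} labels for {N} columns")
        if len(set(self.labels)) != N:
            raise ValueError("region labels must be unique")
        if not self.tr > 0:
            raise ValueError("tr must be > 0 seconds")
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contain non-finite values; "
                             "the method assumes complete scans")
        if self.zscored:
            mu = data.mean(axis=0)
            sd = data.std(axis=0)
            if np.abs(mu).max() > _ZSCORE_TOL or np.abs(sd - 1).max() > _ZSCORE_TOL:
                raise ValueError("zscored=True but columns are not standardised")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def column(self, label: str) -> np.ndarray:
        """Return the signal of one region by label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None
        return self.data[:, idx]


def zscore(series: RoiTimeSeries) -> RoiTimeSeries:
    """Standardise each column to zero mean and unit population SD.

    Idempotent: applying it to an already z-scored series is a no-op up to
    floating-point round-off.  Raises for constant columns, which have no
    defined SD units.
    """
    data = series.data
    sd = data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(series.labels[i] for i in bad)
        raise ValueError(f"cannot z-score constant column(s): {names}")
    out = (data - data.mean(axis=0)) / sd
    return replace(series, data=out, zscored=True)


def read_series_table(path, delimiter: str | None = None) -> RoiTimeSeries:
    """Read a header + numeric-rows table into a :class:`RoiTimeSeries`.

    The first row holds region labels; every following row is one time
    point.  ``delimiter=None`` sniffs tab vs comma from the header line.
    The TR is not stored in the table; callers supply it afterwards via
    :func:`with_tr` (a placeholder of 1.0 s is set here).
    """
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    if delimiter is None:
        delimiter = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged rows or malformed table: {exc}") from exc
    if df.shape[0] < 2:
        raise ValueError(f"{path}: T >= 2 required, got {df.shape[0]} data rows")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                # float() is correctly rounded, so shortest-repr values
                # written by write_series_table round-trip exactly
                values[i, j] = float(cell)
            except (ValueError, TypeError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, "
                    f"column {col!r}") from None
    return RoiTimeSeries(values, tr=1.0, labels=tuple(df.columns))


def with_tr(series: RoiTimeSeries, tr: float) -> RoiTimeSeries:
    """Return a copy of *series* with the repetition time set to *tr*."""
    return replace(series, tr=float(tr))


def write_series_table(series: RoiTimeSeries, path, delimiter: str = "\t") -> None:
    """Write the series as a delimited table with a label header.

    Uses shortest-repr floats so a write -> read round trip preserves
    values exactly.
    """
    df = pd.DataFrame(series.data, columns=list(series.labels))
    df.to_csv(path, sep=delimiter, index=False)


def extract_atlas_series(image_4d, atlas_labels, tr: float | None = None) -> RoiTimeSeries:
    """Average a 4-D image over each atlas label to get one series per parcel.

    Parameters
    ----------
    image_4d :
        A ``nibabel`` spatial image (X, Y, Z, T) or a 4-D array.
    atlas_labels :
        Integer-labelled volume on the same grid; 0 is background.
    tr :
        Repetition time in seconds.  An explicit value wins over the image
        header; a mismatch between the two logs a warning.

    Returns a series with one column per nonzero label, columns sorted by
    ascending label value and named ``roi_<label>``.
    """
    header_tr = None
    if hasattr(image_4d, "get_fdata"):
        try:
            zooms = image_4d.header.get_zooms()
            if len(zooms) >= 4 and zooms[3] > 0:
                header_tr = float(zooms[3])
        except Exception:  # pragma: no cover - malformed headers
            header_tr = None
        img = np.asarray(image_4d.get_fdata())
    else:
        img = np.asarray(image_4d, dtype=float)
    atlas = np.asarray(
        atlas_labels.get_fdata() if hasattr(atlas_labels, "get_fdata") else atlas_labels
    )
    if img.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if atlas.shape != img.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match image grid {img.shape[:3]}")
    if not np.allclose(atlas, np.round(atlas)):
        raise ValueError("atlas must be integer-valued")
    atlas = np.round(atlas).astype(int)
    label_values = np.unique(atlas)
    label_values = label_values[label_values != 0]
    if label_values.size == 0:
        raise ValueError("atlas contains no nonzero labels")

    if tr is not None and header_tr is not None and not np.isclose(tr, header_tr):
        logger.warning("explicit TR %.4g s overrides header TR %.4g s", tr, header_tr)
        warnings.warn(
            f"explicit TR {tr} s overrides header TR {header_tr} s", stacklevel=2)
    tr_out = tr if tr is not None else (header_tr if header_tr else 1.0)

    T = img.shape[3]
    flat = img.reshape(-1, T)
    atlas_flat = atlas.ravel()
    cols = np.column_stack(
        [flat[atlas_flat == lab].mean(axis=0) for lab in label_values])
    labels = tuple(f"roi_{lab}" for lab in label_values)
    return RoiTimeSeries(cols, tr=tr_out, labels=labels)
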