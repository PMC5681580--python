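"""Ring-width series I/O, pith correction and quality control.

Reads and writes the Tucson/RWL decadal format, estimates the unmeasured
radius of cores that missed the pith (geometric arc method), estimates the
corresponding number of missing rings, removes post-fire rings on plots
with a known fire history, and computes a simplified inter-series
correlation statistic for crossdating quality control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .robust import biweight_mean
from .smoothing import highpass_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "RingSeries",
    "ArcMeasurement",
    "read_rwl",
    "write_rwl",
    "attach_metadata",
    "estimate_missing_radius",
    "estimate_missing_rings",
    "correct_missing_pith",
    "apply_fire_filter",
    "interseries_correlation",
]

SPECIES = ("black_spruce", "white_spruce")
PLOT_TYPES = ("FIA", "AIRIS")


@dataclass
class RingSeries:
    """One tree's dated ring widths with pith-correction metadata.

    ``widths`` holds one ring width (mm) per consecutive calendar year
    starting at ``first_year``.  The cambial age of the ring formed in
    year ``y`` is ``(y - first_year + 1) + missing_rings``.
    """

    series_id: str
    first_year: int
    widths: np.ndarray
    tree_id: str = ""
    plot_id: str = ""
    species: str = "white_spruce"
    plot_type: str = "FIA"
    pith_present: bool = True
    missing_radius_mm: float | None = None
    missing_rings: int | None = None
    fire_year: int | None = None

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise ValueError(f"{self.series_id}: widths must be a nonempty 1-D array")
        if np.any(self.widths < 0):
            raise ValueError(f"{self.series_id}: negative ring width")
        if not self.tree_id:
            self.tree_id = self.series_id
        if self.pith_present:
            self.missing_radius_mm = 0.0
            self.missing_rings = 0

    @property
    def n_years(self) -> int:
        return self.widths.size

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_years - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def cambial_ages(self) -> np.ndarray:
        """Cambial age of each ring, including the missing-ring offset."""
        offset = self.missing_rings or 0
        return np.arange(1, self.n_years + 1) + offset

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.series_id)


@dataclass(frozen=True)
class ArcMeasurement:
    """Chord and height (mm) of the innermost complete ring arc on a core."""

    chord_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.chord_mm <= 0 or self.height_mm <= 0:
            raise ValueError("arc chord and height must be positive")
        if self.height_mm > self.chord_mm:
            raise ValueError("arc height exceeds chord: not a flat-to-semicircular arc")


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

_STOP_MARKERS = {999: 0.01, -9999: 0.001}


def read_rwl(path: str | Path) -> list[RingSeries]:
    """Read a Tucson/RWL decadal file into a list of :class:`RingSeries`.

    Each data line is ``<series id> <decade year> <values...>``.  A stop
    marker of 999 indicates 0.01 mm units, -9999 indicates 0.001 mm.
    """
    path = Path(path)
    order: list[str] = []
    raw: dict[str, list[int]] = {}
    first_year: dict[str, int] = {}
    finished: set[str] = set()
    previous_sid: str | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: malformed decade line: {line!r}")
            sid = tokens[0]
            try:
                year = int(tokens[1])
                values = [int(t) for t in tokens[2:]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed decade line: {line!r}"
                ) from exc
            if sid != previous_sid and previous_sid is not None:
                finished.add(previous_sid)
            previous_sid = sid
            if sid in finished:
                raise ValueError(f"{path}:{lineno}: duplicate series id {sid!r}")
            if sid not in raw:
                raw[sid] = []
                first_year[sid] = year
                order.append(sid)
            else:
                expected = first_year[sid] + len(raw[sid])
                if year != expected:
                    raise ValueError(
                        f"{path}:{lineno}: decade year {year} for {sid!r}, "
                        f"expected {expected}"
                    )
            raw[sid].extend(values)
    out = []
    for sid in order:
        values = raw[sid]
        # the stop marker is structurally the LAST value of a series: 999
        # earlier in the data is a legitimate 0.999 mm ring
        if values and values[-1] in _STOP_MARKERS:
            scale = _STOP_MARKERS[values[-1]]
            values = values[:-1]
        else:
            logger.warning("series %s has no stop marker; assuming 0.001 mm", sid)
            scale = 0.001
        if not values:
            raise ValueError(f"series {sid!r} has no ring widths")
        widths = np.asarray(values, dtype=float) * scale
        out.append(RingSeries(series_id=sid, first_year=first_year[sid], widths=widths))
    logger.info("read %d series from %s", len(out), path)
    return out


def write_rwl(series_list: Sequence[RingSeries], path: str | Path) -> None:
    """Write series in Tucson decadal layout at 0.001 mm precision."""
    path = Path(path)
    seen: set[str] = set()
    with path.open("w") as fh:
        for s in series_list:
            if s.series_id in seen:
                raise ValueError(f"duplicate series id {s.series_id!r}")
            seen.add(s.series_id)
            values = [int(round(w * 1000)) for w in s.widths] + [-9999]
            year = s.first_year
            pos = 0
            while pos < len(values):
                row_end = (year // 10) * 10 + 10  # first year of next decade
                take = min(row_end - year, len(values) - pos)
                chunk = values[pos : pos + take]
                fh.write(f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6d}" for v in chunk) + "\n")
                pos += take
                year += take
    logger.info("wrote %d series to %s", len(seen), path)


def attach_metadata(
    series_list: Iterable[RingSeries], metadata: pd.DataFrame
) -> list[RingSeries]:
    """Join a per-tree metadata table onto series read from an RWL file.

    Expected columns: ``series_id`` plus any of ``tree_id, plot_id, species,
    plot_type, pith_present, fire_year``.
    """
    meta = metadata.set_index("series_id")
    out = []
    for s in series_list:
        if s.series_id not in meta.index:
            logger.warning("no metadata for series %s; kept as-is", s.series_id)
            out.append(s)
            continue
        row = meta.loc[s.series_id]
        kwargs: dict = {}
        for col in ("tree_id", "plot_id", "species", "plot_type"):
            if col in row and pd.notna(row[col]):
                kwargs[col] = row[col]
        if "pith_present" in row and pd.notna(row["pith_present"]):
            kwargs["pith_present"] = bool(row["pith_present"])
        if "fire_year" in row and pd.notna(row["fire_year"]):
            kwargs["fire_year"] = int(row["fire_year"])
        out.append(replace(s, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Pith correction
# ---------------------------------------------------------------------------


def estimate_missing_radius(arc: ArcMeasurement) -> float:
    """Missing radius (mm) from the innermost complete arc, geometric method.

    The circle through an arc of chord ``c`` and height ``h`` has radius
    ``c^2 / (8 h) + h / 2``; that radius is the distance from the innermost
    measured ring to the pith.
    """
    c, h = arc.chord_mm, arc.height_mm
    return c * c / (8.0 * h) + h / 2.0


def estimate_missing_rings(series: RingSeries, missing_radius: float) -> int:
    """Number of unmeasured rings inside ``missing_radius``.

    Divides the mean width of the innermost ten measured rings into the
    missing radius; rounds half to even.  Requires at least ten rings.
    """
    if missing_radius < 0:
        raise ValueError("missing radius must be nonnegative")
    if series.n_years < 10:
        raise ValueError(
            f"{series.series_id}: need >= 10 rings to estimate missing rings "
            f"(have {series.n_years})"
        )
    mean10 = float(np.mean(series.widths[:10]))
    if mean10 <= 0:
        raise ValueError(f"{series.series_id}: first-10-ring mean width is zero")
    count = int(np.round(missing_radius / mean10))
    series.missing_rings = count
    series.missing_radius_mm = float(missing_radius)
    return count


def correct_missing_pith(
    series_list: Iterable[RingSeries], arcs: pd.DataFrame
) -> list[RingSeries]:
    """Estimate missing radius and ring count for cores that missed the pith.

    ``arcs`` is indexed by series id with columns ``chord_mm`` and
    ``height_mm`` (innermost complete arc).  Series without pith and
    without a usable arc are excluded, mirroring field practice.
    """
    out = []
    for s in series_list:
        if s.pith_present:
            out.append(s)
            continue
        if s.series_id not in arcs.index:
            logger.warning(
                "series %s lacks pith and arc measurement; excluded", s.series_id
            )
            continue
        arc = ArcMeasurement(
            chord_mm=float(arcs.loc[s.series_id, "chord_mm"]),
            height_mm=float(arcs.loc[s.series_id, "height_mm"]),
        )
        estimate_missing_rings(s, estimate_missing_radius(arc))
        out.append(s)
    return out


def apply_fire_filter(series: RingSeries) -> RingSeries | None:
    """Drop rings in and after the plot's fire year.

    Returns the (possibly shortened) series, or ``None`` with a logged
    warning when nothing pre-fire remains.
    """
    fy = series.fire_year
    if fy is None or fy > series.last_year:
        return series
    keep = fy - series.first_year  # rings strictly before the fire year
    if keep < 1:
        logger.warning(
            "series %s dropped: fire year %d leaves no pre-fire rings",
            series.series_id,
            fy,
        )
        return None
    return replace(series, widths=series.widths[:keep].copy())


# ---------------------------------------------------------------------------
# Inter-series correlation QC
# ---------------------------------------------------------------------------


def interseries_correlation(
    series_list: Sequence[RingSeries],
    detrend_window: float = 32.0,
    min_overlap: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Simplified crossdating QC statistic.

    Each series is high-pass filtered (ratio to a cubic smoothing spline
    with 50% cutoff ``detrend_window``) and correlated against the robust
    (biweight) mean of all other filtered series over their overlap.
    Series with under ``min_overlap`` years of overlap are flagged and
    excluded from the set mean.

    Returns a per-series table (``r``, ``n_overlap``, ``flagged``) and the
    arithmetic mean r over unflagged series.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two series")
    filtered = {
        s.series_id: pd.Series(
            highpass_ratio(s.widths, detrend_window), index=s.years
        )
        for s in series_list
    }
    frame = pd.DataFrame(filtered)
    rows = []
    for sid in frame.columns:
        others = frame.drop(columns=sid)
        target = frame[sid].dropna()
        ref = others.loc[target.index].apply(
            lambda row: biweight_mean(row.dropna().to_numpy())
            if row.notna().any()
            else np.nan,
            axis=1,
        )
        ok = ref.notna() & target.notna()
        n = int(ok.sum())
        if n < min_overlap:
            rows.append({"series_id": sid, "r": np.nan, "n_overlap": n, "flagged": True})
            logger.warning("series %s: only %d years of overlap; flagged", sid, n)
            continue
        x, y = target[ok].to_numpy(), ref[ok].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"series_id": sid, "r": r, "n_overlap": n, "flagged": False})
    table = pd.DataFrame(rows).set_index("series_id")
    mean_r = float(table.loc[~table["flagged"], "r"].mean())
    return table, mean_r
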