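"""Occurrence tables, stratigraphic bin schemes, and genus-by-bin incidence.

Fossil occurrences arrive as one row per (genus, collection) with an age
range in Ma (megaannum before present; ages decrease toward the present).
Capture-recapture treats each stratigraphic time bin as a sampling occasion
and each genus as an individual, so the central container here is the
genus x bin presence/absence matrix whose rows are capture histories.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeBin",
    "TimeBinScheme",
    "OccurrenceTable",
    "IncidenceMatrix",
    "SchemeError",
    "ColumnMapError",
    "read_occurrence_table",
    "read_bin_scheme",
    "bin_occurrences",
    "normalize_genus",
    "read_incidence_csv",
    "write_incidence_csv",
]


class SchemeError(ValueError):
    """Raised for malformed time-bin schemes (overlap, non-monotone bounds)."""


class ColumnMapError(KeyError):
    """Raised when a mapped column is missing from an input table."""


_SUBGENUS_RE = re.compile(r"\s*\([^)]*\)")
_WS_RE = re.compile(r"\s+")


def normalize_genus(name: str) -> str:
    """Normalize a genus name: strip subgenus parentheses and collapse whitespace.

    ``"Olenus  (Olenus) "`` -> ``"Olenus"``.  Matching afterwards is
    case-sensitive; no synonymization is attempted.
    """
    return _WS_RE.sub(" ", _SUBGENUS_RE.sub("", str(name))).strip()


@dataclass(frozen=True)
class TimeBin:
    """One stratigraphic interval, bounded in Ma, oldest bins first."""

    index: int
    name: str
    boundary_older: float
    boundary_younger: float

    def __post_init__(self) -> None:
        if not self.boundary_older > self.boundary_younger:
            raise SchemeError(
                f"bin {self.name!r}: older boundary ({self.boundary_older}) must "
                f"exceed younger boundary ({self.boundary_younger})"
            )

    @property
    def duration(self) -> float:
        """Bin length in Myr."""
        return self.boundary_older - self.boundary_younger

    @property
    def midpoint(self) -> float:
        """Bin midpoint age in Ma."""
        return 0.5 * (self.boundary_older + self.boundary_younger)


class TimeBinScheme:
    """An ordered, non-overlapping sequence of time bins (old -> young).

    Bins need not be contiguous, but may not overlap.  Index 0 is the oldest
    bin; "forward in time" means decreasing Ma.
    """

    def __init__(self, bins: Sequence[TimeBin]):
        bins = sorted(bins, key=lambda b: -b.boundary_older)
        bins = [
            TimeBin(i, b.name, b.boundary_older, b.boundary_younger)
            for i, b in enumerate(bins)
        ]
        for older, younger in zip(bins, bins[1:]):
            if younger.boundary_older > older.boundary_younger + 1e-9:
                raise SchemeError(
                    f"bins {older.name!r} and {younger.name!r} overlap"
                )
        if not bins:
            raise SchemeError("a bin scheme needs at least one bin")
        self.bins: list[TimeBin] = bins

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i: int) -> TimeBin:
        return self.bins[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TimeBinScheme) and [
            (b.name, b.boundary_older, b.boundary_younger) for b in self.bins
        ] == [(b.name, b.boundary_older, b.boundary_younger) for b in other.bins]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    @property
    def durations(self) -> np.ndarray:
        """Bin durations in Myr, old -> young."""
        return np.array([b.duration for b in self.bins])

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoints in Ma, old -> young (decreasing)."""
        return np.array([b.midpoint for b in self.bins])

    @property
    def transition_durations(self) -> np.ndarray:
        """Midpoint-to-midpoint spacing (Myr) for each of the K-1 transitions."""
        m = self.midpoints
        return m[:-1] - m[1:]

    def reversed(self) -> "TimeBinScheme":
        """The same bins mirrored in time (used for reversal-symmetry checks)."""
        pivot = self.bins[0].boundary_older + self.bins[-1].boundary_younger
        return TimeBinScheme(
            [
                TimeBin(0, b.name, pivot - b.boundary_younger, pivot - b.boundary_older)
                for b in self.bins
            ]
        )

    @classmethod
    def uniform(cls, k: int, duration: float = 2.3, oldest: float | None = None,
                prefix: str = "bin") -> "TimeBinScheme":
        """K contiguous equal-length bins; the default 2.3 Myr matches the
        average early-Palaeozoic bin length the analysis targets."""
        if k < 1:
            raise SchemeError("k must be >= 1")
        oldest = k * duration if oldest is None else oldest
        return cls(
            [
                TimeBin(i, f"{prefix}{i:02d}", oldest - i * duration,
                        oldest - (i + 1) * duration)
                for i in range(k)
            ]
        )


@dataclass
class OccurrenceTable:
    """Validated occurrence rows plus bookkeeping on rejected input rows."""

    data: pd.DataFrame  # columns: genus, collection_id, age_older, age_younger
    n_rejected: int = 0
    rejection_reasons: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


_DEFAULT_COLUMN_MAP = {
    "genus": "genus",
    "collection_id": "collection_no",
    "age_older": "max_ma",
    "age_younger": "min_ma",
}


def _read_delimited(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
        return pd.read_csv(source, sep=sep)
    return pd.read_csv(source)


def read_occurrence_table(
    source,
    column_map: Mapping[str, str] | None = None,
) -> OccurrenceTable:
    """Read a delimited occurrence file into a validated :class:`OccurrenceTable`.

    Parameters
    ----------
    source
        Path or text stream of a delimited table with a header row (TSV is
        autodetected from a ``.tsv``/``.tab`` extension; streams are assumed
        comma-separated).
    column_map
        Maps the internal field names (``genus``, ``collection_id``,
        ``age_older``, ``age_younger``) to the file's column names.  The
        default matches Paleobiology Database downloads
        (``genus, collection_no, max_ma, min_ma``).

    Rows are rejected (counted, not fatal) when ages are unparseable or
    negative, when ``age_younger > age_older``, or when the genus name is
    empty after normalization.  A missing mapped column raises
    :class:`ColumnMapError`.
    """
    raw = _read_delimited(source)
    cmap, missing = {}, []
    for field_name in _DEFAULT_COLUMN_MAP:
        if column_map and field_name in column_map:
            candidates = [column_map[field_name]]
        else:  # PBDB download header, else the internal name itself
            candidates = [_DEFAULT_COLUMN_MAP[field_name], field_name]
        hit = next((c for c in candidates if c in raw.columns), None)
        if hit is None:
            missing.append(candidates[0])
        cmap[field_name] = hit
    if missing:
        raise ColumnMapError(f"mapped column(s) not in input: {missing}")

    df = pd.DataFrame(
        {
            "genus": raw[cmap["genus"]].map(normalize_genus),
            "collection_id": raw[cmap["collection_id"]].astype(str),
            "age_older": pd.to_numeric(raw[cmap["age_older"]], errors="coerce"),
            "age_younger": pd.to_numeric(raw[cmap["age_younger"]], errors="coerce"),
        }
    )
    reasons: dict[str, int] = {}

    def _reject(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            reasons[reason] = reasons.get(reason, 0) + n
        return ~mask

    keep = _reject(df["age_older"].isna() | df["age_younger"].isna(), "unparseable age")
    keep &= _reject(keep & (df["age_younger"] < 0), "negative age")
    keep &= _reject(keep & (df["age_younger"] > df["age_older"]), "inverted age range")
    keep &= _reject(keep & (df["genus"] == ""), "empty genus")
    out = df[keep].reset_index(drop=True)
    return OccurrenceTable(out, n_rejected=len(df) - len(out), rejection_reasons=reasons)


def read_bin_scheme(source) -> TimeBinScheme:
    """Read a bin-scheme table (columns ``name``, ``boundary_older``,
    ``boundary_younger``; ``bin``/``max_ma``/``min_ma`` accepted as aliases).

    Bins are sorted old -> young and indices reassigned; overlapping or
    inverted bins raise :class:`SchemeError`.
    """
    raw = _read_delimited(source)
    cols = {c.lower(): c for c in raw.columns}
    name_c = cols.get("name") or cols.get("bin")
    old_c = cols.get("boundary_older") or cols.get("max_ma")
    yng_c = cols.get("boundary_younger") or cols.get("min_ma")
    if not (name_c and old_c and yng_c):
        raise ColumnMapError(
            "bin scheme needs name/bin, boundary_older/max_ma, boundary_younger/min_ma"
        )
    return TimeBinScheme(
        [
            TimeBin(i, str(r[name_c]), float(r[old_c]), float(r[yng_c]))
            for i, (_, r) in enumerate(raw.iterrows())
        ]
    )


class IncidenceMatrix:
    """Genus x bin presence/absence; each row is one genus's capture history."""

    def __init__(self, genera: Sequence[str], scheme: TimeBinScheme,
                 cells: np.ndarray):
        cells = np.asarray(cells, dtype=np.int8)
        if cells.shape != (len(genera), len(scheme)):
            raise ValueError(
                f"cells shape {cells.shape} != ({len(genera)}, {len(scheme)})"
            )
        if len(genera) and not (cells.sum(axis=1) >= 1).all():
            raise ValueError("every genus row must have at least one presence")
        self.genera = list(genera)
        self.scheme = scheme
        self.cells = cells

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    @property
    def n_bins(self) -> int:
        return len(self.scheme)

    @property
    def observed_richness(self) -> np.ndarray:
        """Sampled-in-bin genus counts (column sums)."""
        return self.cells.sum(axis=0).astype(int)

    def reversed(self) -> "IncidenceMatrix":
        """Time-mirrored matrix (bins young -> old), for symmetry checks."""
        return IncidenceMatrix(self.genera, self.scheme.reversed(),
                               self.cells[:, ::-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=pd.Index(self.genera, name="genus"),
                            columns=self.scheme.names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IncidenceMatrix)
            and self.genera == other.genera
            and self.scheme == other.scheme
            and np.array_equal(self.cells, other.cells)
        )


def bin_occurrences(
    table: OccurrenceTable,
    scheme: TimeBinScheme,
    policy: str = "strict",
) -> IncidenceMatrix:
    """Assign occurrences to time bins and build the incidence matrix.

    ``strict`` (default) assigns an occurrence to a bin only when its age
    range lies entirely inside the bin; range-spanning occurrences are
    dropped (and counted on the returned matrix as ``n_dropped``).
    ``majority`` assigns to the bin holding the largest fraction of the age
    range when that fraction exceeds 0.5.  A genus is present in a bin when
    at least one of its occurrences lands there; genera with no assigned
    occurrence are excluded.  Duplicate genus/bin assignments collapse to a
    single incidence.
    """
    if policy not in ("strict", "majority"):
        raise ValueError(f"unknown binning policy {policy!r}")
    df = table.data
    old = df["age_older"].to_numpy(float)
    yng = df["age_younger"].to_numpy(float)
    k = len(scheme)
    b_old = np.array([b.boundary_older for b in scheme])
    b_yng = np.array([b.boundary_younger for b in scheme])

    if policy == "strict":
        # containment: [yng, old] inside [b_yng, b_old]
        inside = (old[:, None] <= b_old[None, :] + 1e-9) & (
            yng[:, None] >= b_yng[None, :] - 1e-9
        )
        assigned = np.where(inside.any(axis=1), inside.argmax(axis=1), -1)
    else:
        span = np.maximum(old - yng, 1e-12)
        ov = np.maximum(
            0.0,
            np.minimum(old[:, None], b_old[None, :])
            - np.maximum(yng[:, None], b_yng[None, :]),
        )
        frac = ov / span[:, None]
        best = frac.argmax(axis=1)
        assigned = np.where(frac[np.arange(len(df)), best] > 0.5, best, -1)

    keep = assigned >= 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no binnable occurrences under the chosen policy")

    genera = sorted(df.loc[keep, "genus"].unique())
    gidx = {g: i for i, g in enumerate(genera)}
    cells = np.zeros((len(genera), k), dtype=np.int8)
    rows = df.loc[keep, "genus"].map(gidx).to_numpy()
    cells[rows, assigned[keep]] = 1
    mat = IncidenceMatrix(genera, scheme, cells)
    mat.n_dropped = n_dropped  # type: ignore[attr-defined]
    return mat


def write_incidence_csv(mat: IncidenceMatrix, path: str | Path | io.TextIOBase) -> None:
    """Wide CSV: genus row label + one 0/1 column per bin, old -> young."""
    mat.to_frame().to_csv(path)


def read_incidence_csv(path, scheme: TimeBinScheme) -> IncidenceMatrix:
    """Inverse of :func:`write_incidence_csv` (columns checked against *scheme*)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != scheme.names:
        raise SchemeError("incidence columns do not match the bin scheme")
    return IncidenceMatrix(list(df.index), scheme, df.to_numpy())
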