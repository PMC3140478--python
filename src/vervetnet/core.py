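"""Domain types and file I/O for behavioural event data.

The package works from three kinds of raw material: a *roster* describing
the individuals of a study group, timestamped *event logs* (scan-sampled
nearest-neighbour records and all-occurrence social interaction bouts) and
square *dyadic matrices* (association indices, interaction rates, attribute
similarity, genetic relatedness).  This module defines the in-memory
containers for each, plus readers/writers for the plain-text formats the
pipeline consumes, and the segmentation of a continuous observation stream
into behavioural bouts.

Conventions
-----------
* Timestamps are seconds from local midnight; dates are ISO-8601 strings.
* A *sampling period* is one calendar day by default: every record maps to
  exactly one period, indexed 0..T-1 in date order.
* Identity labels are opaque strings; nothing is ever parsed out of an id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Roster",
    "EventLog",
    "PresenceMatrix",
    "DyadicMatrix",
    "DyadicOccurrence",
    "BOUT_GAP_SECONDS",
    "SOCIAL_BEHAVIOURS",
    "AFFILIATIVE_BEHAVIOURS",
    "AGONISTIC_BEHAVIOURS",
    "read_roster",
    "write_roster",
    "read_event_log",
    "write_event_log",
    "segment_bouts",
    "read_matrix",
    "write_matrix",
    "write_graphml",
    "presence_from_log",
]

#: A behavioural bout ends when the behaviour ceases for five seconds or
#: more, is replaced by another behaviour, or the partner changes.
BOUT_GAP_SECONDS = 5.0

SOCIAL_BEHAVIOURS = frozenset(
    {
        "proximity",
        "allogroom",
        "contact_sit",
        "play",
        "aggression",
        "submission",
        "coop_attempt",
    }
)
AFFILIATIVE_BEHAVIOURS = frozenset({"allogroom", "contact_sit", "play"})
AGONISTIC_BEHAVIOURS = frozenset({"aggression", "submission"})

_EVENT_COLUMNS = [
    "date",
    "time_s",
    "kind",
    "behaviour",
    "actor",
    "recipient",
    "neighbour_distance_m",
    "feeder_distance_m",
    "sampling_period",
]
_MANDATORY_EVENT_COLUMNS = ["date", "time_s", "kind", "behaviour", "actor"]


class ValidationError(ValueError):
    """Raised when an input file or matrix violates a structural invariant."""


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------


@dataclass
class Roster:
    """Per-individual attributes of one or more study groups.

    Parameters
    ----------
    table
        DataFrame indexed by individual id with columns ``sex`` (``M``/``F``),
        ``age_class`` (``adult``/``juvenile``; ``infant`` rows are tolerated
        on input but flagged for exclusion), ``coop_class`` (``small``/
        ``large``), ``matriline`` (label or NA) and ``group``.
    siblings
        Mapping id -> frozenset of sibling ids (may be empty).
    """

    table: pd.DataFrame
    siblings: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicated ids in roster: {dupes}")
        self.table.index = self.table.index.astype(str)

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def infants(self) -> list[str]:
        if "age_class" not in self.table.columns:
            return []
        return list(self.table.index[self.table["age_class"] == "infant"])

    def coop_classes(self) -> tuple[list[str], list[str]]:
        """Return (small-class ids, large-class ids)."""
        small = list(self.table.index[self.table["coop_class"] == "small"])
        large = list(self.table.index[self.table["coop_class"] == "large"])
        return small, large

    def subset(self, ids: Sequence[str]) -> "Roster":
        ids = [i for i in ids if i in self.table.index]
        sibs = {i: self.siblings.get(i, frozenset()) for i in ids}
        return Roster(self.table.loc[ids].copy(), sibs)


def read_roster(path: str | Path) -> Roster:
    """Read a roster CSV (columns id, sex, age_class, coop_class, matriline,
    siblings, group; siblings semicolon-separated)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValidationError(f"roster file {path} lacks an 'id' column")
    df = df.set_index("id")
    siblings: dict[str, frozenset] = {}
    if "siblings" in df.columns:
        for ind, raw in df["siblings"].items():
            sibs = frozenset(s for s in str(raw).split(";") if s)
            siblings[ind] = sibs
        df = df.drop(columns=["siblings"])
    df = df.replace({"": pd.NA})
    return Roster(df, siblings)


def write_roster(roster: Roster, path: str | Path) -> None:
    df = roster.table.copy()
    df["siblings"] = [
        ";".join(sorted(roster.siblings.get(i, frozenset()))) for i in df.index
    ]
    df.index.name = "id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Event logs
# ---------------------------------------------------------------------------


@dataclass
class EventLog:
    """Timestamped behavioural records for one group.

    ``records`` is a DataFrame with columns ``date`` (ISO-8601 string),
    ``time_s`` (seconds from local midnight), ``kind`` (``scan``/``bout``),
    ``behaviour``, ``actor``, ``recipient`` (NA for solitary scans),
    ``neighbour_distance_m``, ``feeder_distance_m`` (NA when feeders absent)
    and ``sampling_period`` (int day index).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _EVENT_COLUMNS:
            if col not in self.records.columns:
                self.records[col] = pd.NA
        self.records = self.records[_EVENT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_periods(self) -> int:
        if len(self.records) == 0:
            return 0
        return int(self.records["sampling_period"].max()) + 1

    def scans(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "scan"]

    def bouts(self, behaviours: Iterable[str] | None = None) -> pd.DataFrame:
        out = self.records[self.records["kind"] == "bout"]
        if behaviours is not None:
            out = out[out["behaviour"].isin(set(behaviours))]
        return out

    def individuals(self) -> list[str]:
        ids = set(self.records["actor"].dropna()) | set(
            self.records["recipient"].dropna()
        )
        return sorted(ids)


def assign_sampling_periods(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each record its calendar-day index (0-based, in date order)."""
    records = records.copy()
    dates = sorted(records["date"].dropna().unique())
    lookup = {d: i for i, d in enumerate(dates)}
    records["sampling_period"] = records["date"].map(lookup).astype("Int64")
    return records


def read_event_log(
    path: str | Path,
    roster: Roster | None = None,
    drop_infants: bool = True,
) -> EventLog:
    """Read a delimited event-log file into a validated :class:`EventLog`.

    The file must be UTF-8 CSV with a header naming at least
    ``date,time_s,kind,behaviour,actor``.  Records are bucketed into
    sampling periods by calendar day.  If a roster is given, ids absent
    from it are reported as a warning and records of individuals flagged
    ``infant`` are dropped (the study design excludes infants).

    Raises
    ------
    ValidationError
        On a missing mandatory column, or on any record whose actor equals
        its recipient (the offending line numbers are listed).
    """
    df = pd.read_csv(path, dtype={"actor": str, "recipient": str, "date": str})
    missing = [c for c in _MANDATORY_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"event log {path} is missing mandatory column(s): {', '.join(missing)}"
        )
    # +2: header line, then 1-based data lines
    self_loops = df.index[
        df["recipient"].notna() & (df["actor"] == df["recipient"])
    ]
    if len(self_loops):
        lines = [int(i) + 2 for i in self_loops]
        raise ValidationError(
            f"event log {path}: actor equals recipient on line(s) {lines}"
        )
    if roster is not None:
        known = set(roster.ids)
        seen = set(df["actor"].dropna()) | set(df["recipient"].dropna())
        unknown = sorted(seen - known)
        if unknown:
            warnings.warn(
                f"event log {path} contains ids not in roster: {unknown}",
                stacklevel=2,
            )
        if drop_infants and roster.infants:
            infants = set(roster.infants)
            mask = df["actor"].isin(infants) | df["recipient"].isin(infants)
            if mask.any():
                warnings.warn(
                    f"dropping {int(mask.sum())} record(s) involving infants",
                    stacklevel=2,
                )
                df = df[~mask]
    df = assign_sampling_periods(df)
    return EventLog(df)


def write_event_log(log: EventLog, path: str | Path) -> None:
    log.records.to_csv(path, index=False)


def segment_bouts(stream: pd.DataFrame) -> pd.DataFrame:
    """Collapse a time-sorted observation stream into behavioural bouts.

    A bout is a maximal run of observations sharing (behaviour, actor,
    recipient) within one sampling day whose inter-observation gaps are all
    shorter than :data:`BOUT_GAP_SECONDS`.  A gap of five seconds or more,
    a change of behaviour, or a partner exchange starts a new bout.  Each
    bout keeps the starting time of its first observation, so downstream
    statistics work on bout *frequencies*, not durations.

    Parameters
    ----------
    stream
        DataFrame with at least ``date``, ``time_s``, ``behaviour``,
        ``actor``, ``recipient`` columns, time-sorted within each date.

    Returns
    -------
    DataFrame of bout records (``kind`` set to ``bout``), one row per bout.
    """
    if len(stream) == 0:
        out = stream.copy()
        out["kind"] = pd.Series(dtype=object)
        return out
    for date, sub in stream.groupby("date", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValidationError(
                f"observation stream not time-sorted within date {date}"
            )
    keys = ["date", "behaviour", "actor", "recipient"]
    stream = stream.copy()
    kv = stream[keys].astype(str)
    new_key = (kv != kv.shift()).any(axis=1)
    gap = stream["time_s"].diff().to_numpy()
    new_bout = new_key.to_numpy() | (gap >= BOUT_GAP_SECONDS)
    new_bout[0] = True
    bout_id = np.cumsum(new_bout)
    firsts = stream[new_bout].copy()
    firsts["kind"] = "bout"
    firsts["_bout_id"] = bout_id[new_bout]
    return firsts.drop(columns=["_bout_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Presence
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary individuals x sampling-periods availability.

    ``values[i, t] == 1`` means individual ``ids[i]`` was observed (hence
    available for dyadic statistics) in period ``t``.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValidationError("presence matrix shape does not match ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("presence matrix must be binary")
        self.values = self.values.astype(np.uint8)

    @property
    def n_periods(self) -> int:
        return self.values.shape[1]

    def joint_observability(self) -> np.ndarray:
        """d_ij = number of periods in which both members of a dyad were
        present; diagonal holds each individual's own period count."""
        p = self.values.astype(np.int64)
        return p @ p.T

    def mean_identified_per_period(self) -> float:
        return float(self.values.sum(axis=0).mean())


def presence_from_log(log: EventLog, ids: Sequence[str]) -> PresenceMatrix:
    """Score an individual present on each day it appears in any record."""
    n_periods = log.n_periods
    idx = {ind: i for i, ind in enumerate(ids)}
    values = np.zeros((len(ids), n_periods), dtype=np.uint8)
    rec = log.records
    for col in ("actor", "recipient"):
        sub = rec[rec[col].notna()]
        for ind, t in zip(sub[col], sub["sampling_period"]):
            if ind in idx and pd.notna(t):
                values[idx[ind], int(t)] = 1
    return PresenceMatrix(list(ids), values)


# ---------------------------------------------------------------------------
# Dyadic matrices
# ---------------------------------------------------------------------------

_SYMMETRIC_KINDS = {
    "association_index",
    "interaction_rate",
    "similarity",
    "relatedness",
    "distance",
}
_MATRIX_KINDS = _SYMMETRIC_KINDS | {"win_counts"}
_SYMMETRY_TOL = 1e-9


@dataclass
class DyadicMatrix:
    """Square labelled matrix over individuals, with an optional dyad mask.

    The diagonal is undefined and ignored throughout.  All kinds except
    ``win_counts`` (directed agonistic counts) must be symmetric to within
    1e-9.  ``mask[i, j] == 1`` marks a dyad as included in statistics; the
    mask, when present, is symmetric with a zero diagonal.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "similarity"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if self.kind not in _MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if self.kind in _SYMMETRIC_KINDS:
            _check_symmetry(self.values, self.ids)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != (n, n):
                raise ValidationError("mask shape does not match matrix")
            if not np.array_equal(self.mask, self.mask.T):
                raise ValidationError("mask must be symmetric")
            self.mask = self.mask.astype(np.uint8)
            np.fill_diagonal(self.mask, 0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def offdiag_mask(self) -> np.ndarray:
        """Boolean inclusion matrix: the explicit mask if set, else all
        off-diagonal finite cells."""
        out = np.ones((self.n, self.n), dtype=bool)
        np.fill_diagonal(out, False)
        if self.mask is not None:
            out &= self.mask.astype(bool)
        out &= np.isfinite(self.values)
        return out

    def reorder(self, ids: Sequence[str]) -> "DyadicMatrix":
        pos = {ind: i for i, ind in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise ValidationError(f"ids not in matrix: {missing}")
        idx = np.array([pos[i] for i in ids])
        mask = None if self.mask is None else self.mask[np.ix_(idx, idx)]
        return DyadicMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.kind, mask
        )


def _check_symmetry(values: np.ndarray, ids: Sequence[str]) -> None:
    with np.errstate(invalid="ignore"):
        asym = np.abs(values - values.T)
    asym = np.where(np.isnan(values) & np.isnan(values.T), 0.0, asym)
    if np.isnan(asym).any():
        bad = np.argwhere(np.isnan(asym))[0]
        raise ValidationError(
            f"matrix asymmetric: cell ({ids[bad[0]]}, {ids[bad[1]]}) "
            "is missing on one side only"
        )
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > _SYMMETRY_TOL:
        raise ValidationError(
            f"matrix asymmetric beyond tolerance at cell "
            f"({ids[worst[0]]}, {ids[worst[1]]}): "
            f"|{values[worst]} - {values[worst[::-1]]}| = {asym[worst]:g}"
        )


def write_matrix(m: DyadicMatrix, path: str | Path) -> None:
    """Write a labelled matrix as CSV (id header row, id first column).

    Values round-trip at full precision.  A mask, when present, is written
    alongside with the suffix ``.mask.csv``; the matrix kind is recorded in
    the index-header cell as ``id:<kind>``.
    """
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    df.index.name = f"id:{m.kind}"
    df.to_csv(path, float_format=None)
    if m.mask is not None:
        dm = pd.DataFrame(m.mask, index=m.ids, columns=m.ids)
        dm.index.name = "id"
        dm.to_csv(path.with_suffix(".mask.csv"))


def read_matrix(path: str | Path, kind: str | None = None) -> DyadicMatrix:
    """Read a labelled matrix CSV written by :func:`write_matrix`.

    Raises :class:`ValidationError` if the matrix is not square, or (for
    symmetric kinds) if any cell differs from its transpose by more than
    1e-9 — the worst-offending cell is named in the message.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    header = df.index.name or "id"
    if kind is None:
        kind = header.split(":", 1)[1] if ":" in header else "similarity"
    ids = [str(i) for i in df.index]
    if list(map(str, df.columns)) != ids:
        raise ValidationError(
            f"matrix {path} is not square-labelled: rows {ids} vs "
            f"columns {list(df.columns)}"
        )
    mask = None
    mask_path = path.with_suffix(".mask.csv")
    if mask_path.exists():
        mask = pd.read_csv(mask_path, index_col=0).to_numpy()
    return DyadicMatrix(ids, df.to_numpy(dtype=float), kind, mask)


def write_graphml(m: DyadicMatrix, path: str | Path) -> None:
    """Export as GraphML with a ``weight`` edge attribute (off-diagonal,
    nonzero, unmasked cells only) for external visualisation."""
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    inc = m.offdiag_mask()
    for i in range(m.n):
        for j in range(i + 1, m.n):
            if inc[i, j] and m.values[i, j] != 0:
                g.add_edge(m.ids[i], m.ids[j], weight=float(m.values[i, j]))
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# Dyadic occurrence
# ---------------------------------------------------------------------------


@dataclass
class DyadicOccurrence:
    """Per-period dyadic event layer underlying index-based statistics.

    ``x[t, i, j]`` counts events linking dyad (i, j) in sampling period t
    (binary for association data, integer counts for interaction data);
    symmetric in (i, j) with zero diagonal.  ``presence`` supplies the
    joint-observability denominators d_ij.
    """

    ids: list[str]
    x: np.ndarray
    presence: PresenceMatrix

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        n = len(self.ids)
        t = self.presence.n_periods
        if self.x.shape != (t, n, n):
            raise ValidationError(
                f"occurrence shape {self.x.shape} != (periods={t}, n={n}, n={n})"
            )
        if (self.x < 0).any():
            raise ValidationError("occurrence counts must be nonnegative")
        if not np.array_equal(self.x, np.swapaxes(self.x, 1, 2)):
            raise ValidationError("occurrence must be symmetric per period")
        joint = (
            self.presence.values.T[:, :, None] * self.presence.values.T[:, None, :]
        )
        if ((self.x > 0) & (joint == 0)).any():
            raise ValidationError(
                "occurrence records an event for a dyad not jointly present"
            )

    @property
    def n_periods(self) -> int:
        return self.x.shape[0]

    def totals(self) -> np.ndarray:
        """x_ij summed over periods."""
        return self.x.sum(axis=0)

    def joint_observability(self) -> np.ndarray:
        return self.presence.joint_observability()

    def association_index(self, method: str = "simple") -> np.ndarray:
        """Dyadic association index.

        ``simple`` (default): periods together / periods jointly
        observable — appropriate here because daily presence is tracked
        explicitly.  ``half_weight``: X / (X + Yab + (Ya + Yb)/2), which
        down-weights periods where only one member was identified, for
        comparability with analyses that cannot condition on presence.
        Undefined (NaN) for dyads never jointly observable; the
        per-period layer is binarised first so the index lies in [0, 1]
        even for count data.
        """
        together = (self.x > 0).sum(axis=0).astype(float)
        d = self.joint_observability().astype(float)
        if method == "simple":
            denom = d
        elif method == "half_weight":
            seen = self.presence.values.sum(axis=1).astype(float)
            apart = d - together  # both present, not associated
            alone = (seen[:, None] - d) + (seen[None, :] - d)
            denom = together + apart + alone / 2.0
        else:
            raise ValidationError(f"unknown association index {method!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(d > 0, together / np.where(denom > 0, denom, 1),
                             np.nan)
        np.fill_diagonal(alpha, np.nan)
        return alpha

    def subset_periods(self, idx: np.ndarray) -> "DyadicOccurrence":
        sub = PresenceMatrix(self.ids, self.presence.values[:, idx])
        return DyadicOccurrence(self.ids, self.x[idx], sub)
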