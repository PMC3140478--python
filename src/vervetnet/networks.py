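"""Per-condition dyadic networks and the between-class mask.

Three observation conditions are compared: proximity in space (scan-sampled
nearest neighbours away from the feeders), affiliative interaction
(allogrooming, contact sitting, social play bouts) and cooperation at the
joined feeders.  Each condition yields a :class:`ConditionNetwork` holding
the dyadic matrix, the per-period occurrence layer behind it and the event
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AFFILIATIVE_BEHAVIOURS,
    DyadicMatrix,
    DyadicOccurrence,
    EventLog,
    PresenceMatrix,
    Roster,
    ValidationError,
)

__all__ = [
    "ConditionNetwork",
    "proximity_association",
    "interaction_rate",
    "between_class_mask",
]

#: nearest-neighbour scans qualify within this distance (m)
DEFAULT_MAX_NN_M = 10.0
#: ...and only when both individuals are beyond this radius from the feeders
DEFAULT_MIN_FEEDER_M = 10.0


@dataclass
class ConditionNetwork:
    """A dyadic network for one observation condition."""

    condition: str
    matrix: DyadicMatrix
    occurrence: DyadicOccurrence
    n_periods: int
    n_events: int

    @property
    def ids(self) -> list[str]:
        return self.matrix.ids


def _dyad_index(ids) -> dict:
    return {ind: i for i, ind in enumerate(ids)}


def proximity_association(
    log: EventLog,
    presence: PresenceMatrix,
    max_nn_m: float = DEFAULT_MAX_NN_M,
    min_feeder_m: float = DEFAULT_MIN_FEEDER_M,
    mutual: bool = False,
    index_method: str = "simple",
) -> ConditionNetwork:
    """Daily nearest-neighbour association network from scan samples.

    A dyad is scored associated in period t if any scan that day links the
    two within ``max_nn_m`` metres with both further than ``min_feeder_m``
    from the feeders (scans without a feeder distance count as away from
    feeders).  The association index is the simple ratio
    alpha_ij = (periods associated) / (periods jointly observable); dyads
    never jointly observable are NaN and excluded downstream.

    Links are scored either-direction by default: A naming B as nearest
    neighbour associates the dyad regardless of B's own scan.  With
    ``mutual=True`` a dyad only counts on days when each named the other.
    The result is invariant to the order of records within a day.
    """
    ids = presence.ids
    idx = _dyad_index(ids)
    n, t_max = len(ids), presence.n_periods
    directed = np.zeros((t_max, n, n), dtype=np.int64)
    scans = log.scans()
    scans = scans[scans["recipient"].notna()]
    n_events = 0
    for row in scans.itertuples(index=False):
        if pd.isna(row.neighbour_distance_m) or row.neighbour_distance_m > max_nn_m:
            continue
        if pd.notna(row.feeder_distance_m) and row.feeder_distance_m <= min_feeder_m:
            continue
        a, b = idx.get(row.actor), idx.get(row.recipient)
        t = row.sampling_period
        if a is None or b is None or pd.isna(t):
            continue
        t = int(t)
        if not (presence.values[a, t] and presence.values[b, t]):
            continue
        directed[t, a, b] = 1
        n_events += 1
    if mutual:
        x = directed * np.swapaxes(directed, 1, 2)
    else:
        x = np.maximum(directed, np.swapaxes(directed, 1, 2))
    occ = DyadicOccurrence(ids, x, presence)
    matrix = DyadicMatrix(
        ids, occ.association_index(index_method), "association_index"
    )
    return ConditionNetwork("proximity", matrix, occ, t_max, n_events)


def interaction_rate(
    log: EventLog,
    behaviours: set[str] | frozenset[str] = AFFILIATIVE_BEHAVIOURS,
    presence: PresenceMatrix | None = None,
    condition: str | None = None,
) -> ConditionNetwork:
    """Bout-count network for a set of social behaviours.

    The matrix cell (i, j) is the number of bouts linking the dyad in
    either direction (frequencies, not durations; directions collapsed).
    The occurrence layer keeps per-period counts for index-based and
    permutation statistics.  Dyads never jointly observable are masked out
    of the matrix (NaN).
    """
    if not behaviours:
        raise ValidationError("behaviour set must be non-empty")
    bouts = log.bouts(behaviours)
    bouts = bouts[bouts["recipient"].notna()]
    if presence is None:
        from .core import presence_from_log

        ids = sorted(set(log.individuals()))
        presence = presence_from_log(log, ids)
    ids = presence.ids
    idx = _dyad_index(ids)
    n, t_max = len(ids), max(presence.n_periods, log.n_periods)
    if presence.n_periods < t_max:
        raise ValidationError("presence matrix covers fewer periods than log")
    x = np.zeros((t_max, n, n), dtype=np.int64)
    n_events = 0
    for row in bouts.itertuples(index=False):
        a, b = idx.get(row.actor), idx.get(row.recipient)
        t = row.sampling_period
        if a is None or b is None or pd.isna(t):
            continue
        t = int(t)
        if not (presence.values[a, t] and presence.values[b, t]):
            continue
        x[t, a, b] += 1
        x[t, b, a] += 1
        n_events += 1
    occ = DyadicOccurrence(ids, x, presence)
    counts = occ.totals().astype(float)
    d = occ.joint_observability()
    counts[d == 0] = np.nan
    np.fill_diagonal(counts, np.nan)
    matrix = DyadicMatrix(ids, counts, "interaction_rate")
    name = condition or (
        "cooperation" if behaviours == {"coop_attempt"} else "affiliative"
    )
    return ConditionNetwork(name, matrix, occ, t_max, n_events)


def between_class_mask(roster: Roster, ids: list[str] | None = None) -> np.ndarray:
    """Mask selecting dyads that pair a small-class with a large-class
    member.

    Partner-choice analyses run only on the market-relevant dyads: those
    crossing the cooperation-class boundary.  Same-class cells are zeroed
    so incidental same-class co-occurrences at the feeders cannot bias the
    matrix correlations.  The mask is symmetric with zero diagonal; the
    sum of its cells is 2 * n_small * n_large.
    """
    if ids is None:
        ids = roster.ids
    classes = roster.table["coop_class"]
    missing = [i for i in ids if i not in classes.index or pd.isna(classes.get(i))]
    if missing:
        raise ValidationError(f"missing coop_class for: {missing}")
    small = np.array([classes[i] == "small" for i in ids])
    mask = (small[:, None] != small[None, :]).astype(np.uint8)
    np.fill_diagonal(mask, 0)
    return mask
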