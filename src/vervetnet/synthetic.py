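"""Synthetic behavioural data with known ground truth.

No field data accompany the study design this package targets, so every
downstream stage is exercised against simulated groups whose structure is
known exactly: latent dyadic association probabilities with a controlled
coefficient of variation (the ground-truth social differentiation),
per-day presence/absence, a two-member "small" cooperation class facing a
larger class across joined feeders, rank-assortative partner choice of
controllable strength, a dominance hierarchy generating agonistic wins,
and matriline-structured relatedness.

All generators are pure functions of (config, seed): the same
:class:`SimConfig` always yields bit-identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DyadicMatrix,
    DyadicOccurrence,
    EventLog,
    PresenceMatrix,
    Roster,
    assign_sampling_periods,
)

__all__ = [
    "SimConfig",
    "beta_parameters",
    "make_roster",
    "simulate_presence",
    "simulate_association_data",
    "simulate_scan_events",
    "simulate_affiliative_events",
    "simulate_cooperation_events",
    "simulate_agonistic_matrix",
    "simulate_relatedness",
    "simulate_bundle",
]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated study group.

    Defaults emulate a single wild vervet group under the feeder
    experiment: fewer than twenty individuals observed over a few weeks of
    daily sessions, most (but not all) of the group identified each day,
    and exactly two individuals in the small cooperation class.

    Parameters
    ----------
    n_individuals
        Group size excluding infants (the study groups held 7-19).
    n_small_class
        Size of the small cooperation class (the design uses 2).
    n_periods
        Number of daily sampling periods (the study spans 13-51 days
        per group and condition).
    presence_prob
        Per-individual, per-day probability of being observable near the
        feeders.  0.9 matches the "mean individuals identified per
        sampling period" sitting somewhat below group size.
    scans_per_period
        Scan samples per day (10-minute intervals over an 8-hour
        observation day give 48).
    events_per_period
        Cooperation attempts recorded per day during the cooperation
        phase (daily all-occurrence record counts of order 20-40).
    true_assoc_mean, true_assoc_cv
        Mean and coefficient of variation of the latent dyadic
        association probabilities; the CV is the ground-truth social
        differentiation S.
    rank_scores
        Ground-truth dominance scores, one per individual (higher wins).
    rank_assortment
        Strength beta >= 0 of the preference for similar-rank cooperation
        partners; 0 gives uniform choice among present partners.
    partner_map
        Optional planted exclusive partnerships: mapping from small-class
        index to large-class index.  With probability
        ``partner_fidelity`` an event goes to the planted partner.
    community_partition
        Optional ground-truth community label per individual.
    matriline_sizes
        Sizes of maternal families; relatedness is 0.5 for mother/offspring
        and full siblings, 0.25 within a matriline otherwise, 0 across.
    seed
        RNG seed; every generator derives its stream from it.
    """

    n_individuals: int = 12
    n_small_class: int = 2
    n_periods: int = 25
    presence_prob: float = 0.9
    scans_per_period: int = 48
    events_per_period: int = 30
    true_assoc_mean: float = 0.2
    true_assoc_cv: float = 0.5
    rank_scores: tuple[float, ...] | None = None
    rank_assortment: float = 0.0
    partner_map: Mapping[int, int] | None = None
    partner_fidelity: float = 0.9
    community_partition: tuple[int, ...] | None = None
    matriline_sizes: tuple[int, ...] | None = None
    matrilines_rank_aligned: bool = False
    relatedness_noise_sd: float = 0.05
    relatedness_missing: tuple[int, ...] = ()
    affiliative_assoc_cv: float | None = None
    affiliative_bouts_per_day: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_small_class < self.n_individuals):
            raise ValueError("need 0 < n_small_class < n_individuals")
        if not (0 < self.presence_prob <= 1):
            raise ValueError("presence_prob must be in (0, 1]")
        if self.true_assoc_cv < 0:
            raise ValueError("true_assoc_cv must be nonnegative")
        if self.rank_scores is not None and len(self.rank_scores) != self.n_individuals:
            raise ValueError("rank_scores length must equal n_individuals")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent substream, deterministic in (seed, stream)."""
        h = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, h]))

    def ids(self) -> list[str]:
        width = len(str(self.n_individuals))
        return [f"ID{str(i + 1).zfill(width)}" for i in range(self.n_individuals)]

    def default_ranks(self) -> np.ndarray:
        """Ground-truth dominance scores, top rank first.

        Default is a steep linear hierarchy with unit spacing — adjacent
        individuals settle agonistic encounters about 73:27 — matching the
        decisive dyadic outcomes of despotic cercopithecine hierarchies.
        """
        if self.rank_scores is not None:
            return np.asarray(self.rank_scores, dtype=float)
        return np.linspace(float(self.n_individuals - 1), 0.0, self.n_individuals)


def beta_parameters(mean: float, cv: float) -> tuple[float, float]:
    """Beta(a, b) shape parameters with the given mean and CV.

    The CV of a Beta on [0, 1] with mean mu is bounded above by
    sqrt((1 - mu)/mu); outside that region no Beta (indeed no distribution
    on [0, 1]) exists with those two moments.
    """
    if not (0 < mean < 1):
        raise ValueError("mean must be in (0, 1)")
    bound = math.sqrt((1 - mean) / mean)
    if cv >= bound:
        raise ValueError(
            f"CV {cv:g} infeasible for mean {mean:g}: a [0,1] variable with "
            f"this mean has CV < sqrt((1-mean)/mean) = {bound:g}"
        )
    var = (mean * cv) ** 2
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def make_roster(cfg: SimConfig, group: str = "SIM") -> Roster:
    """Roster with the experimental class structure.

    The two small-class members mirror the design: one male and one
    female, one adult and one juvenile, one high- and one low-ranking
    (rank positions 0 and n-1 of the ground-truth hierarchy).  Remaining
    attributes are assigned deterministically from the seed.
    """
    rng = cfg.rng("roster")
    ids = cfg.ids()
    n = cfg.n_individuals
    sex = list(rng.choice(["M", "F"], size=n))
    age = list(rng.choice(["adult", "juvenile"], size=n))
    coop = ["large"] * n
    small_idx = _small_indices(cfg)
    for k, i in enumerate(small_idx):
        coop[i] = "small"
        sex[i] = "M" if k == 0 else "F"
        age[i] = "adult" if k == 0 else "juvenile"
    matriline = [pd.NA] * n
    siblings: dict[str, frozenset] = {i: frozenset() for i in ids}
    if cfg.matriline_sizes is not None:
        if sum(cfg.matriline_sizes) != n:
            raise ValueError("matriline_sizes must sum to n_individuals")
        labels, sib_pairs = _kin_labels(cfg)
        matriline = labels
        for a, b in sib_pairs:
            siblings[ids[a]] = siblings[ids[a]] | {ids[b]}
            siblings[ids[b]] = siblings[ids[b]] | {ids[a]}
    table = pd.DataFrame(
        {
            "sex": sex,
            "age_class": age,
            "coop_class": coop,
            "matriline": matriline,
            "group": group,
        },
        index=pd.Index(ids, name="id"),
    )
    return Roster(table, siblings)


def _small_indices(cfg: SimConfig) -> list[int]:
    """Small-class members sit at the rank extremes (design: one high, one
    low); extra members, if configured, fill in from the top."""
    if cfg.n_small_class == 1:
        return [0]
    extras = list(range(1, cfg.n_small_class - 1))
    return [0, *extras, cfg.n_individuals - 1]


def _kin_labels(cfg: SimConfig):
    """Matriline membership and one full-sibling pair per matriline.

    Membership is a seeded random assignment by default, keeping kinship
    independent of the rank hierarchy; ``matrilines_rank_aligned`` instead
    fills matrilines with rank-adjacent individuals, emulating the
    rank-inheritance structure of matrilineal societies.
    """
    n = cfg.n_individuals
    if cfg.matrilines_rank_aligned:
        order = list(range(n))
    else:
        order = list(cfg.rng("kin").permutation(n))
    labels: list[str] = [""] * n
    sib_pairs: list[tuple[int, int]] = []
    start = 0
    for m, size in enumerate(cfg.matriline_sizes or ()):
        name = f"MAT{m + 1}"
        members = [order[k] for k in range(start, start + size)]
        for i in members:
            labels[i] = name
        if size >= 2:
            sib_pairs.append((members[0], members[1]))
        start += size
    return labels, sib_pairs


def simulate_presence(cfg: SimConfig) -> PresenceMatrix:
    """i.i.d. Bernoulli presence per individual-day."""
    rng = cfg.rng("presence")
    values = (
        rng.random((cfg.n_individuals, cfg.n_periods)) < cfg.presence_prob
    ).astype(np.uint8)
    return PresenceMatrix(cfg.ids(), values)


def simulate_association_data(
    cfg: SimConfig,
) -> tuple[PresenceMatrix, DyadicOccurrence, DyadicMatrix]:
    """Draw latent dyadic association probabilities and realise daily
    association events.

    alpha_ij ~ Beta with mean ``true_assoc_mean`` and CV ``true_assoc_cv``
    (all alpha equal to the mean when the CV is zero); each day, each
    jointly-present dyad associates with probability alpha_ij.  Returns
    the presence matrix, the realised occurrence layer and the ground-truth
    alpha matrix for recovery tests.
    """
    n = cfg.n_individuals
    rng = cfg.rng("association")
    if cfg.true_assoc_cv == 0:
        alpha = np.full((n, n), cfg.true_assoc_mean)
    else:
        a, b = beta_parameters(cfg.true_assoc_mean, cfg.true_assoc_cv)
        tri = rng.beta(a, b, size=n * (n - 1) // 2)
        alpha = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        alpha[iu] = tri
        alpha = alpha + alpha.T
    np.fill_diagonal(alpha, 0.0)

    presence = simulate_presence(cfg)
    p = presence.values
    joint = p.T[:, :, None] * p.T[:, None, :]  # (T, n, n)
    draws = rng.random((cfg.n_periods, n, n))
    draws = np.triu(draws, 1)
    draws = draws + np.swapaxes(draws, 1, 2)  # symmetric uniforms
    x = ((draws < alpha[None]) & (joint > 0)).astype(np.int64)
    occ = DyadicOccurrence(cfg.ids(), x, presence)
    truth = DyadicMatrix(cfg.ids(), alpha, "association_index")
    return presence, occ, truth


def simulate_cooperation_events(
    cfg: SimConfig, presence: PresenceMatrix | None = None
) -> EventLog:
    """Cooperation-phase event log: attempts pair one small-class member
    with one large-class member at the joined feeders.

    Partner choice for small-class member s among the large-class members
    present that day is proportional to
    ``exp(-beta * |rank_s - rank_l| / range(rank))`` with
    beta = ``rank_assortment``; beta = 0 gives uniform choice.  If
    ``partner_map`` plants exclusive partnerships, each event goes to the
    planted partner with probability ``partner_fidelity`` and is drawn
    from the kernel otherwise.  Days on which either class is entirely
    absent yield no events.
    """
    rng = cfg.rng("cooperation")
    ids = cfg.ids()
    ranks = cfg.default_ranks()
    rank_range = max(ranks.max() - ranks.min(), 1e-12)
    small = _small_indices(cfg)
    large = [i for i in range(cfg.n_individuals) if i not in small]
    if presence is None:
        presence = simulate_presence(cfg)
    rows = []
    for t in range(cfg.n_periods):
        present = presence.values[:, t].astype(bool)
        s_here = [i for i in small if present[i]]
        l_here = [i for i in large if present[i]]
        if not s_here or not l_here:
            continue
        date = _period_date(t)
        times = np.sort(rng.uniform(7 * 3600, 15 * 3600, cfg.events_per_period))
        for time_s in times:
            s = s_here[rng.integers(len(s_here))]
            planted = (cfg.partner_map or {}).get(s)
            if (
                planted is not None
                and present[planted]
                and rng.random() < cfg.partner_fidelity
            ):
                l = planted
            else:
                w = np.exp(
                    -cfg.rank_assortment
                    * np.abs(ranks[l_here] - ranks[s])
                    / rank_range
                )
                l = l_here[rng.choice(len(l_here), p=w / w.sum())]
            rows.append(
                {
                    "date": date,
                    "time_s": float(time_s),
                    "kind": "bout",
                    "behaviour": "coop_attempt",
                    "actor": ids[s],
                    "recipient": ids[l],
                    "neighbour_distance_m": np.nan,
                    "feeder_distance_m": 0.0,
                }
            )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        df = pd.DataFrame(
            columns=[
                "date",
                "time_s",
                "kind",
                "behaviour",
                "actor",
                "recipient",
                "neighbour_distance_m",
                "feeder_distance_m",
            ]
        )
    df = assign_sampling_periods(df)
    return EventLog(df)


def simulate_scan_events(
    cfg: SimConfig,
    presence: PresenceMatrix | None = None,
    occ: DyadicOccurrence | None = None,
) -> EventLog:
    """Scan-sample nearest-neighbour log consistent with an association
    occurrence layer: each day, each associated dyad is recorded once as a
    nearest-neighbour scan away from the feeders."""
    rng = cfg.rng("scans")
    ids = cfg.ids()
    if occ is None:
        presence, occ, _ = simulate_association_data(cfg)
    rows = []
    for t in range(cfg.n_periods):
        date = _period_date(t)
        pairs = np.argwhere(np.triu(occ.x[t], 1) > 0)
        for i, j in pairs:
            rows.append(
                {
                    "date": date,
                    "time_s": float(rng.uniform(7 * 3600, 15 * 3600)),
                    "kind": "scan",
                    "behaviour": "proximity",
                    "actor": ids[i],
                    "recipient": ids[j],
                    "neighbour_distance_m": float(rng.uniform(0.5, 9.5)),
                    "feeder_distance_m": float(rng.uniform(11, 200)),
                }
            )
        # lone scans for present individuals keep daily presence observable
        for i in np.flatnonzero(occ.presence.values[:, t]):
            rows.append(
                {
                    "date": date,
                    "time_s": float(rng.uniform(7 * 3600, 15 * 3600)),
                    "kind": "scan",
                    "behaviour": "proximity",
                    "actor": ids[i],
                    "recipient": pd.NA,
                    "neighbour_distance_m": np.nan,
                    "feeder_distance_m": float(rng.uniform(11, 200)),
                }
            )
    df = assign_sampling_periods(pd.DataFrame(rows).sort_values(["date", "time_s"]))
    return EventLog(df)


def simulate_agonistic_matrix(
    cfg: SimConfig, encounters_per_dyad: int = 10
) -> DyadicMatrix:
    """Directed win counts: i beats j with probability
    logistic(rank_i - rank_j) in each of ``encounters_per_dyad``
    encounters.  Equal ranks give 50/50; an infinite rank gap gives a
    clean sweep."""
    rng = cfg.rng("agonism")
    ranks = cfg.default_ranks()
    n = cfg.n_individuals
    wins = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            with np.errstate(over="ignore"):
                p_i = 1.0 / (1.0 + np.exp(-(ranks[i] - ranks[j])))
            w = rng.binomial(encounters_per_dyad, p_i)
            wins[i, j] = w
            wins[j, i] = encounters_per_dyad - w
    return DyadicMatrix(cfg.ids(), wins, "win_counts")


def simulate_relatedness(cfg: SimConfig, roster: Roster | None = None) -> DyadicMatrix:
    """Marker-estimate-like relatedness from the matriline structure.

    Pedigree values — 0.5 for the designated full-sibling pair of each
    matriline, 0.25 for other same-matriline dyads, 0 across matrilines —
    are perturbed by Gaussian estimation noise
    (``relatedness_noise_sd``), clipped to [-1, 1], mimicking coefficients
    estimated from a finite marker panel (which can even dip below zero).
    Individuals listed in ``relatedness_missing`` get NaN coefficients,
    like subjects whose genotypes could not be reliably extracted.
    """
    if cfg.matriline_sizes is None:
        raise ValueError("config has no matriline structure")
    if roster is None:
        roster = make_roster(cfg)
    ids = cfg.ids()
    n = len(ids)
    mat = roster.table["matriline"]
    r = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if pd.isna(mat.iloc[i]) or mat.iloc[i] != mat.iloc[j]:
                continue
            if ids[j] in roster.siblings.get(ids[i], frozenset()):
                r[i, j] = r[j, i] = 0.5
            else:
                r[i, j] = r[j, i] = 0.25
    if cfg.relatedness_noise_sd > 0:
        rng = cfg.rng("relatedness")
        noise = rng.normal(0, cfg.relatedness_noise_sd, size=(n, n))
        noise = np.triu(noise, 1)
        r = np.clip(r + noise + noise.T, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    for i in cfg.relatedness_missing:
        r[i, :] = np.nan
        r[:, i] = np.nan
    return DyadicMatrix(ids, r, "relatedness")


def simulate_affiliative_events(
    cfg: SimConfig, presence: PresenceMatrix | None = None
) -> EventLog:
    """Affiliative bout log (allogrooming, contact sitting, social play).

    Dyadic affiliation probabilities are an independent Beta draw with
    mean ``true_assoc_mean`` and CV ``affiliative_assoc_cv`` (defaulting
    to ``true_assoc_cv``).  A jointly-present dyad interacts on a day with
    its affiliation probability — so the binarised daily layer recovers
    that CV exactly — and an interacting day carries 1 + Poisson
    (``affiliative_bouts_per_day``) bouts of behaviours drawn uniformly
    from the affiliative set.
    """
    rng = cfg.rng("affiliative")
    ids = cfg.ids()
    n = cfg.n_individuals
    cv = (
        cfg.affiliative_assoc_cv
        if cfg.affiliative_assoc_cv is not None
        else cfg.true_assoc_cv
    )
    if cv == 0:
        alpha = np.full((n, n), cfg.true_assoc_mean)
    else:
        a, b = beta_parameters(cfg.true_assoc_mean, cv)
        tri = rng.beta(a, b, size=n * (n - 1) // 2)
        alpha = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        alpha[iu] = tri
        alpha = alpha + alpha.T
    np.fill_diagonal(alpha, 0.0)
    if presence is None:
        presence = simulate_presence(cfg)
    behaviours = sorted({"allogroom", "contact_sit", "play"})
    rows = []
    for t in range(cfg.n_periods):
        present = presence.values[:, t].astype(bool)
        date = _period_date(t)
        for i in range(n):
            for j in range(i + 1, n):
                if not (present[i] and present[j]):
                    continue
                if rng.random() >= alpha[i, j]:
                    continue
                n_bouts = 1 + rng.poisson(cfg.affiliative_bouts_per_day)
                for _ in range(int(n_bouts)):
                    rows.append(
                        {
                            "date": date,
                            "time_s": float(rng.uniform(7 * 3600, 15 * 3600)),
                            "kind": "bout",
                            "behaviour": behaviours[rng.integers(3)],
                            "actor": ids[i],
                            "recipient": ids[j],
                            "neighbour_distance_m": np.nan,
                            "feeder_distance_m": np.nan,
                        }
                    )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        df = pd.DataFrame(columns=[
            "date", "time_s", "kind", "behaviour", "actor", "recipient",
            "neighbour_distance_m", "feeder_distance_m",
        ])
    return EventLog(assign_sampling_periods(df))


def simulate_bundle(cfg: SimConfig) -> dict:
    """Full synthetic study bundle for one group: roster, presence, scan
    and cooperation event logs, agonistic wins, relatedness (when kin
    structure is configured) and the ground truth."""
    roster = make_roster(cfg)
    presence, occ, truth = simulate_association_data(cfg)
    scans = simulate_scan_events(cfg, presence, occ)
    affil = simulate_affiliative_events(cfg, presence)
    coop = simulate_cooperation_events(cfg, presence)
    events = EventLog(
        pd.concat(
            [scans.records, affil.records, coop.records], ignore_index=True
        ).sort_values(["date", "time_s"], kind="stable")
    )
    out = {
        "roster": roster,
        "presence": presence,
        "occurrence": occ,
        "true_association": truth,
        "events": events,
        "agonistic": simulate_agonistic_matrix(cfg),
        "truth": {
            "true_assoc_mean": cfg.true_assoc_mean,
            "true_assoc_cv": cfg.true_assoc_cv,
            "rank_scores": list(map(float, cfg.default_ranks())),
            "rank_assortment": cfg.rank_assortment,
        },
    }
    if cfg.matriline_sizes is not None:
        out["relatedness"] = simulate_relatedness(cfg, roster)
    return out


def _period_date(t: int) -> str:
    base = pd.Timestamp("2008-06-01")
    return (base + pd.Timedelta(days=t)).date().isoformat()
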