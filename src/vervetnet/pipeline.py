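"""One-command reproduction of the full analysis on a dataset.

Given a config naming a roster and event logs (or the parameters of a
synthetic group), the pipeline runs every stage in order — condition
networks, social differentiation with bootstrap SEs, the
presence-constrained preferred-association test, the masked Mantel grid
of partner-choice drivers, David's Scores, and Ward/modularity structure
— and writes ``report.json`` plus flat per-condition (``table1.csv``)
and per-test (``table2.csv``) summary tables.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AFFILIATIVE_BEHAVIOURS,
    DyadicMatrix,
    DyadicOccurrence,
    EventLog,
    PresenceMatrix,
    Roster,
    ValidationError,
    presence_from_log,
    read_event_log,
    read_matrix,
    read_roster,
    write_graphml,
)
from .networks import (
    ConditionNetwork,
    between_class_mask,
    interaction_rate,
    proximity_association,
)
from .stats import (
    differentiation_estimate,
    indicator_similarity,
    mantel_test,
    partial_mantel_test,
    preferred_association_test,
    rank_similarity,
)
from .structure import (
    cophenetic_coefficient,
    davids_score,
    newman_communities,
    profile_distances,
    ward_dendrogram,
)
from . import synthetic

logger = logging.getLogger("vervetnet")

__all__ = ["run_pipeline", "validate_inputs", "load_config"]

DEFAULT_CONFIG = {
    "group": "GROUP",
    "seed": 0,
    "n_perm": 10_000,
    "n_boot": 10_000,
    "thresholds": {
        "max_nn_m": 10.0,
        "min_feeder_m": 10.0,
        "max_feeder_agonism_m": 5.0,
    },
    "permtest_statistic": "count",
    "mantel_tail": "greater",
}

MANTEL_IDENTITIES = [
    "sex",
    "age",
    "rank",
    "relatedness",
    "relatedness_controlling_matriline_siblings",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence(
            [int(master), zlib.crc32(stage.encode()) % (2**31)]
        ).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------


def _load_inputs(config: dict) -> dict:
    """Resolve config to (roster, events, presence, relatedness, wins)."""
    if "synthetic" in config:
        sim_kwargs = dict(config["synthetic"])
        sim_kwargs.setdefault("seed", config.get("seed", 0))
        if "matriline_sizes" in sim_kwargs and sim_kwargs["matriline_sizes"]:
            sim_kwargs["matriline_sizes"] = tuple(sim_kwargs["matriline_sizes"])
        if sim_kwargs.get("rank_scores"):
            sim_kwargs["rank_scores"] = tuple(sim_kwargs["rank_scores"])
        cfg = synthetic.SimConfig(**sim_kwargs)
        bundle = synthetic.simulate_bundle(cfg)
        return {
            "roster": bundle["roster"],
            "events": bundle["events"],
            "relatedness": bundle.get("relatedness"),
            "wins": bundle["agonistic"],
            "truth": bundle["truth"],
        }
    files = config.get("files", {})
    if "roster" not in files or "events" not in files:
        raise ValidationError("config must provide synthetic: or files.roster/events")
    roster = read_roster(files["roster"])
    events = read_event_log(files["events"], roster=roster)
    relatedness = (
        read_matrix(files["relatedness"], kind="relatedness")
        if files.get("relatedness")
        else None
    )
    wins = (
        read_matrix(files["agonistic"], kind="win_counts")
        if files.get("agonistic")
        else None
    )
    return {
        "roster": roster,
        "events": events,
        "relatedness": relatedness,
        "wins": wins,
        "truth": None,
    }


def _trim_condition(net: ConditionNetwork, kinds: set[str]) -> ConditionNetwork:
    """Restrict a condition network to its active sampling days and the
    individuals present on at least one of them.

    A day counts toward a condition only if the condition was observable
    at all that day (at least one record of its kind exists); individuals
    never present on such a day contribute no dyads.
    """
    occ = net.occurrence
    active = np.flatnonzero(occ.x.sum(axis=(1, 2)) > 0)
    if len(active) == 0:
        return net
    sub_presence = occ.presence.values[:, active]
    keep = np.flatnonzero(sub_presence.sum(axis=1) > 0)
    ids = [occ.ids[i] for i in keep]
    presence = PresenceMatrix(ids, sub_presence[keep])
    x = occ.x[np.ix_(active, keep, keep)]
    occ2 = DyadicOccurrence(ids, x, presence)
    if net.matrix.kind == "association_index":
        values = occ2.association_index()
    else:
        values = occ2.totals().astype(float)
        d = occ2.joint_observability()
        values[d == 0] = np.nan
        np.fill_diagonal(values, np.nan)
    matrix = DyadicMatrix(ids, values, net.matrix.kind)
    return ConditionNetwork(net.condition, matrix, occ2, len(active), net.n_events)


def _wins_from_log(
    events: EventLog, roster: Roster, max_feeder_m: float
) -> DyadicMatrix | None:
    """Directed win counts from agonistic bouts started within
    ``max_feeder_m`` of the feeders: the aggressor wins an aggression
    bout, the target of a submission bout wins it."""
    bouts = events.bouts({"aggression", "submission"})
    bouts = bouts[
        bouts["recipient"].notna()
        & bouts["feeder_distance_m"].notna()
        & (bouts["feeder_distance_m"] <= max_feeder_m)
    ]
    if len(bouts) == 0:
        return None
    ids = roster.ids
    idx = {ind: i for i, ind in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for row in bouts.itertuples(index=False):
        a, b = idx.get(row.actor), idx.get(row.recipient)
        if a is None or b is None:
            continue
        if row.behaviour == "aggression":
            w[a, b] += 1
        else:
            w[b, a] += 1
    return DyadicMatrix(ids, w, "win_counts")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_inputs(config: dict) -> dict:
    """Cross-check roster, event ids, class design and relatedness
    coverage before running.

    Fatal problems (duplicated ids, unreadable files) raise; design
    deviations — a small class that is not exactly two individuals,
    relatedness coefficients missing for some ids — are returned as
    warnings and the run is permitted.
    """
    inputs = _load_inputs(config)
    roster: Roster = inputs["roster"]
    events: EventLog = inputs["events"]
    notes: list[str] = []
    small, large = roster.coop_classes()
    if len(small) != 2:
        notes.append(
            f"small cooperation class has {len(small)} members (design is 2)"
        )
    unknown = sorted(set(events.individuals()) - set(roster.ids))
    if unknown:
        notes.append(f"event ids missing from roster: {unknown}")
    rel = inputs.get("relatedness")
    if rel is not None:
        missing_ids = sorted(set(roster.ids) - set(rel.ids))
        nan_ids = [
            rel.ids[i]
            for i in range(rel.n)
            if np.isnan(np.delete(rel.values[i], i)).all()
        ]
        dropped = sorted(set(missing_ids) | set(nan_ids))
        if dropped:
            notes.append(
                "relatedness coefficients unavailable for: "
                f"{dropped}; their dyads are excluded from relatedness tests"
            )
    return {"warnings": notes, "n_individuals": len(roster.ids), "n_events": len(events)}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) the
    report.

    Stages: condition networks -> differentiation (+bootstrap SE) ->
    preferred-association permutation test -> Mantel grid -> David's
    Scores -> Ward clustering with cophenetic validation and Newman
    communities.  Per-stage failures are collected and reported with the
    stage name; the run raises at the end if any stage failed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", 10_000))
    n_boot = int(config.get("n_boot", 10_000))
    thresholds = config.get("thresholds", DEFAULT_CONFIG["thresholds"])
    group = config.get("group", "GROUP")

    inputs = _load_inputs(config)
    roster: Roster = inputs["roster"]
    events: EventLog = inputs["events"]
    presence = presence_from_log(events, roster.ids)
    report: dict = {
        "group": group,
        "seed": seed,
        "n_perm": n_perm,
        "n_boot": n_boot,
        "config_hash": _config_hash(config),
        "validation": validate_inputs(config),
        "conditions": {},
        "preferred_association": {},
        "mantel": [],
        "dominance": None,
        "structure": {},
        "errors": [],
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except ValidationError as exc:
                logger.warning("stage %s failed: %s", name, exc)
                report["errors"].append({"stage": name, "error": str(exc)})
        return deco

    # --- condition networks ------------------------------------------------
    networks: dict[str, ConditionNetwork] = {}

    @stage("networks")
    def _networks():
        prox = proximity_association(
            events,
            presence,
            max_nn_m=thresholds.get("max_nn_m", 10.0),
            min_feeder_m=thresholds.get("min_feeder_m", 10.0),
        )
        networks["proximity"] = _trim_condition(prox, {"scan"})
        aff = interaction_rate(events, AFFILIATIVE_BEHAVIOURS, presence)
        if aff.n_events:
            networks["affiliative"] = _trim_condition(aff, {"bout"})
        coop = interaction_rate(
            events, {"coop_attempt"}, presence, condition="cooperation"
        )
        if coop.n_events:
            networks["cooperation"] = _trim_condition(coop, {"bout"})

    # --- differentiation ---------------------------------------------------
    @stage("differentiation")
    def _differentiation():
        for name, net in networks.items():
            est = differentiation_estimate(
                net.occurrence,
                condition=name,
                n_events=net.n_events,
                n_boot=n_boot,
                seed=_stage_seed(seed, f"boot:{name}"),
            )
            report["conditions"][name] = asdict(est)

    # --- preferred association test ---------------------------------------
    @stage("preferred_association")
    def _permtest():
        for name in ("cooperation",):
            net = networks.get(name)
            if net is None:
                continue
            small, large = roster.coop_classes()
            res = preferred_association_test(
                net.occurrence,
                n_perm=n_perm,
                seed=_stage_seed(seed, f"perm:{name}"),
                statistic=config.get("permtest_statistic", "count"),
                groups=[small, large],
            )
            report["preferred_association"][name] = {
                "mean_test": asdict(res.mean_test),
                "sd_test": asdict(res.sd_test),
                "n_perm": res.n_perm,
                "statistic": res.statistic,
            }

    # --- dominance ---------------------------------------------------------
    dominance = {}

    @stage("dominance")
    def _dominance():
        wins = inputs.get("wins")
        if wins is None:
            wins = _wins_from_log(
                events, roster, thresholds.get("max_feeder_agonism_m", 5.0)
            )
        if wins is None:
            return
        dom = davids_score(wins)
        dominance["result"] = dom
        report["dominance"] = {
            "ids": dom.ids,
            "ds": [float(v) for v in dom.ds],
            "normalized_ds": [float(v) for v in dom.normalized_ds],
            "n_interactions": dom.n_interactions,
            "method": dom.method,
        }

    # --- Mantel grid -------------------------------------------------------
    @stage("mantel")
    def _mantel():
        rel = inputs.get("relatedness")
        small_all, _ = roster.coop_classes()
        for cond in ("proximity", "cooperation"):
            net = networks.get(cond)
            if net is None:
                continue
            for identity in MANTEL_IDENTITIES:
                row = _mantel_row(
                    identity,
                    net,
                    roster,
                    rel,
                    dominance.get("result"),
                    n_perm=n_perm,
                    seed=_stage_seed(seed, f"mantel:{cond}:{identity}"),
                    tail=config.get("mantel_tail", "greater"),
                )
                if row is not None:
                    row["condition"] = cond
                    row["group"] = group
                    report["mantel"].append(row)

    # --- structure ---------------------------------------------------------
    @stage("structure")
    def _structure():
        for cond in ("proximity", "cooperation"):
            net = networks.get(cond)
            if net is None or net.matrix.n < 2:
                continue
            dend = ward_dendrogram(net.matrix)
            coph = cophenetic_coefficient(dend, profile_distances(net.matrix))
            comm = newman_communities(net.matrix)
            report["structure"][cond] = {
                "newick": dend.to_newick(),
                "cophenetic_coefficient": coph,
                "communities": {
                    ind: int(c) for ind, c in zip(comm.ids, comm.assignment)
                },
                "modularity_Q": comm.Q,
            }

    if report["errors"]:
        raise ValidationError(f"pipeline stages failed: {report['errors']}")

    if out_dir is not None:
        _write_outputs(report, networks, out_dir)
    return report


def _mantel_row(identity, net, roster, rel, dominance, n_perm, seed, tail):
    ids = net.ids
    table = roster.table
    small = [i for i in ids if table.loc[i, "coop_class"] == "small"]
    large = [i for i in ids if table.loc[i, "coop_class"] == "large"]
    groups = [small, large]
    a = net.matrix
    controls = None
    if identity == "sex":
        b = indicator_similarity(ids, [table.loc[i, "sex"] for i in ids])
    elif identity == "age":
        b = indicator_similarity(ids, [table.loc[i, "age_class"] for i in ids])
    elif identity == "rank":
        if dominance is None:
            return None
        pos = {ind: k for k, ind in enumerate(dominance.ids)}
        if any(i not in pos for i in ids):
            return None
        b = rank_similarity(ids, [dominance.ds[pos[i]] for i in ids])
    elif identity.startswith("relatedness"):
        if rel is None:
            return None
        known = set(rel.ids)
        keep = [
            i
            for i in ids
            if i in known
            and not np.isnan(
                np.delete(rel.values[rel.ids.index(i)], rel.ids.index(i))
            ).all()
        ]
        if len(keep) < len(ids):
            a = _restrict(net, keep)
            ids = keep
            small = [i for i in ids if table.loc[i, "coop_class"] == "small"]
            large = [i for i in ids if table.loc[i, "coop_class"] == "large"]
            groups = [small, large]
        if len(small) < 1 or len(large) < 2:
            return None
        b = rel.reorder(ids)
        if identity == "relatedness_controlling_matriline_siblings":
            mat = indicator_similarity(
                ids, [table.loc[i, "matriline"] for i in ids]
            )
            sib = _sibling_indicator(roster, ids)
            controls = ([mat, sib], ["matriline", "siblings"])
    else:
        raise ValidationError(f"unknown identity {identity!r}")
    mask = between_class_mask(roster, ids)
    try:
        if controls is None:
            res = mantel_test(
                a, b, mask=mask, n_perm=n_perm, seed=seed, tail=tail, groups=groups
            )
        else:
            res = partial_mantel_test(
                a, b, controls[0], mask=mask, n_perm=n_perm, seed=seed,
                tail=tail, groups=groups, control_names=controls[1],
            )
    except ValidationError as exc:
        return {
            "identity": identity,
            "class_sizes": f"{len(small)}/{len(large)}",
            "error": str(exc),
        }
    return {
        "identity": identity,
        "class_sizes": f"{len(small)}/{len(large)}",
        "p": res.p,
        "mcc": res.mcc,
        "z": res.z,
        "n_perm": res.n_perm,
        "masked_dyads": res.masked_dyads,
        "partial_controls": res.partial_controls,
    }


def _restrict(net: ConditionNetwork, keep: list[str]) -> DyadicMatrix:
    return net.matrix.reorder(keep)


def _sibling_indicator(roster: Roster, ids: list[str]) -> DyadicMatrix:
    n = len(ids)
    sim = np.zeros((n, n))
    for i, a in enumerate(ids):
        sibs = roster.siblings.get(a, frozenset())
        for j, b in enumerate(ids):
            if i != j and b in sibs:
                sim[i, j] = 1.0
    sim = np.maximum(sim, sim.T)
    return DyadicMatrix(ids, sim, "similarity")


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_outputs(report: dict, networks: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonify(report), fh, sort_keys=True, indent=2)
        fh.write("\n")

    rows = []
    for cond, est in report["conditions"].items():
        rows.append(
            {
                "group": report["group"],
                "condition": cond,
                "individuals": est["n_individuals"],
                "mean_identified_per_period": est["mean_identified"],
                "sampling_periods": est["n_periods"],
                "n_associations_or_interactions": est["n_events"],
                "social_differentiation": est["S"],
                "se": est["se"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "table1.csv", index=False)

    grid: dict[tuple, dict] = {}
    for row in report["mantel"]:
        key = (row["group"], row["identity"], row["class_sizes"])
        entry = grid.setdefault(
            key,
            {
                "group": row["group"],
                "identity": row["identity"],
                "class_sizes": row["class_sizes"],
            },
        )
        cond = row.get("condition", "")
        entry[f"{cond}_p"] = row.get("p")
        entry[f"{cond}_mcc"] = row.get("mcc")
    pd.DataFrame(list(grid.values())).to_csv(out / "table2.csv", index=False)

    for cond, net in networks.items():
        write_graphml(net.matrix, out / f"network_{cond}.graphml")
    for cond, info in report["structure"].items():
        with open(out / f"dendrogram_{cond}.nwk", "w") as fh:
            fh.write(info["newick"] + "\n")
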