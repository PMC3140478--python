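"""Inferential engines: social differentiation, presence-constrained
permutation tests of preferred association, and masked (partial) Mantel
tests.

Social differentiation
----------------------
The observed association index alpha_hat_ij = x_ij / d_ij mixes two
sources of variation: real heterogeneity of the latent dyadic association
probabilities, and binomial sampling noise from observing each dyad on
only d_ij days.  The differentiation S estimates the coefficient of
variation of the *latent* probabilities by subtracting an estimate of the
sampling variance from the observed variance of the indices
(method-of-moments):

    S^2 = max(0, Var_w[alpha_hat] - E[alpha_hat (1 - alpha_hat) / d]) / mean_w[alpha_hat]^2

with d_ij-weighted mean and variance.  As a rule of thumb, S < 0.3 marks
a rather homogeneous society, 0.5-2.0 a well differentiated one, and
S > 2.0 an extremely differentiated one.

Permutation nulls
-----------------
Both permutation engines respect daily presence: identities are
reshuffled only among the individuals observable on a given sampling day
("semi-random" permutations), and optionally only within exchangeable
classes (e.g. within the small and within the large cooperation class,
preserving the matching-market structure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Callable, Sequence

import numpy as np

from .core import DyadicMatrix, DyadicOccurrence, PresenceMatrix, ValidationError

__all__ = [
    "DifferentiationEstimate",
    "PermTestResult",
    "PreferredAssociationResult",
    "MantelResult",
    "social_differentiation",
    "classify_differentiation",
    "differentiation_estimate",
    "bootstrap_se",
    "preferred_association_test",
    "mantel_test",
    "partial_mantel_test",
    "exhaustive_mantel_p",
    "indicator_similarity",
    "rank_similarity",
]


# ---------------------------------------------------------------------------
# Social differentiation
# ---------------------------------------------------------------------------


@dataclass
class DifferentiationEstimate:
    """Sampling-variance-corrected social differentiation for one
    condition, with its bootstrap standard error."""

    S: float
    se: float
    n_boot: int
    condition: str = ""
    n_individuals: int = 0
    n_periods: int = 0
    n_events: int = 0
    mean_identified: float = float("nan")
    classification: str = ""


def social_differentiation(occ: DyadicOccurrence) -> float:
    """Estimate the CV of the latent dyadic association probabilities.

    Uses the per-period binarised layer: alpha_hat_ij is the proportion of
    jointly-observable periods in which the dyad was recorded together.
    The d_ij-weighted variance of alpha_hat is corrected by the mean
    estimated binomial sampling variance alpha_hat(1-alpha_hat)/d; the
    corrected variance is truncated at zero before taking the square root.

    Raises
    ------
    ValidationError
        If fewer than two dyads were ever jointly observable, or if no
        association was observed at all (mean index zero).
    """
    d = occ.joint_observability().astype(float)
    together = (occ.x > 0).sum(axis=0).astype(float)
    iu = np.triu_indices(len(occ.ids), 1)
    w = d[iu]
    x = together[iu]
    defined = w >= 1
    if defined.sum() < 2:
        raise ValidationError(
            "social differentiation needs at least two dyads with d_ij >= 1"
        )
    w, x = w[defined], x[defined]
    alpha = x / w
    abar = float(np.sum(w * alpha) / np.sum(w))
    if abar == 0:
        raise ValidationError("no associations observed; differentiation undefined")
    var_w = float(np.sum(w * (alpha - abar) ** 2) / np.sum(w))
    sampling = float(np.mean(alpha * (1 - alpha) / w))
    s2 = max(0.0, var_w - sampling) / abar**2
    return float(np.sqrt(s2))


def classify_differentiation(s: float) -> str:
    """Rule-of-thumb reading of a differentiation value."""
    if s < 0.3:
        return "homogeneous"
    if s < 0.5:
        return "intermediate"
    if s <= 2.0:
        return "well_differentiated"
    return "extreme"


def differentiation_estimate(
    occ: DyadicOccurrence,
    condition: str = "",
    n_events: int = 0,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> DifferentiationEstimate:
    """Differentiation plus bootstrap SE and the descriptive columns of a
    per-condition summary row."""
    s = social_differentiation(occ)
    se = bootstrap_se(occ, social_differentiation, n_boot=n_boot, seed=seed)
    return DifferentiationEstimate(
        S=s,
        se=se,
        n_boot=n_boot,
        condition=condition,
        n_individuals=len(occ.ids),
        n_periods=occ.n_periods,
        n_events=n_events,
        mean_identified=occ.presence.mean_identified_per_period(),
        classification=classify_differentiation(s),
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_se(
    occ: DyadicOccurrence,
    statistic: Callable[[DyadicOccurrence], float],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE of a statistic by resampling sampling periods.

    Periods (days) are the independent replication unit, so whole columns
    of the occurrence and presence layers are resampled with replacement;
    the statistic is recomputed on each replicate and the SE is the SD
    across replicates.  Replicates on which the statistic is undefined are
    dropped; more than 50% undefined is an error (more data needed).
    """
    t = occ.n_periods
    if t < 2:
        raise ValidationError("bootstrap needs at least two sampling periods")
    rng = np.random.default_rng(seed)
    values = []
    n_undefined = 0
    for _ in range(n_boot):
        idx = rng.integers(0, t, size=t)
        try:
            v = statistic(occ.subset_periods(idx))
        except (ValidationError, ZeroDivisionError, FloatingPointError):
            v = float("nan")
        if np.isfinite(v):
            values.append(v)
        else:
            n_undefined += 1
    if n_undefined > n_boot / 2:
        raise ValidationError(
            f"statistic undefined on {n_undefined}/{n_boot} bootstrap "
            "replicates; collect more sampling periods"
        )
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


# ---------------------------------------------------------------------------
# Preferred / avoided association test
# ---------------------------------------------------------------------------


@dataclass
class PermTestResult:
    """One permutation test: the real statistic against its null."""

    stat_real: float
    stat_null_mean: float
    stat_null_sd: float
    p: float
    n_perm: int
    statistic_name: str


@dataclass
class PreferredAssociationResult:
    """Paired outputs of the preferred/avoided association test.

    ``mean_test`` asks whether the mean dyadic value is *lower* than
    expected (fewer partners used), ``sd_test`` whether the spread across
    dyads is *higher* than expected (stronger preferred partnerships).
    The headline ``p`` is the SD test's.
    """

    mean_test: PermTestResult
    sd_test: PermTestResult
    n_perm: int
    statistic: str

    @property
    def p(self) -> float:
        return self.sd_test.p


def _exchangeable_groups(
    ids: Sequence[str], groups: Sequence[Sequence[str]] | None
) -> list[np.ndarray]:
    pos = {ind: i for i, ind in enumerate(ids)}
    if groups is None:
        return [np.arange(len(ids))]
    out = []
    seen: set[int] = set()
    for g in groups:
        idx = np.array(sorted(pos[i] for i in g if i in pos), dtype=np.int64)
        if len(set(idx) & seen):
            raise ValidationError("exchangeable groups must be disjoint")
        seen |= set(idx)
        if len(idx):
            out.append(idx)
    return out


def preferred_association_test(
    occ: DyadicOccurrence,
    presence: PresenceMatrix | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "index",
    groups: Sequence[Sequence[str]] | None = None,
) -> PreferredAssociationResult:
    """Presence-constrained permutation test for preferred/avoided
    associations.

    The null reshuffles identities *within each sampling day*, and only
    among the individuals present that day — an individual not found in
    the surroundings on a day never enters that day's permuted matrix.
    Each day's event structure (who-with-whom slots and the number of
    individuals involved) is preserved; only the identities are
    reallocated.  With ``groups`` given (e.g. the two cooperation
    classes), identities additionally permute only within their class,
    preserving the matching-market structure.

    Two statistics are evaluated over dyads ever jointly observable: the
    mean dyadic value and the SD of dyadic values, where the value is the
    association index (``statistic="index"``) or the total event count
    (``statistic="count"``).  Preferred partnerships concentrate events on
    few dyads, depressing the mean and inflating the SD, so the p-values
    are P(null mean <= real mean) and P(null SD >= real SD), floored at
    1/(n_perm + 1).
    """
    if presence is None:
        presence = occ.presence
    if statistic not in ("index", "count"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    n = len(occ.ids)
    t_max = occ.n_periods
    d = occ.joint_observability().astype(float)
    iu = np.triu_indices(n, 1)
    defined = d[iu] > 0
    if defined.sum() < 2:
        raise ValidationError("need at least two jointly-observable dyads")
    g_idx = _exchangeable_groups(occ.ids, groups)

    def dyad_values(tot: np.ndarray) -> np.ndarray:
        v = tot[..., iu[0], iu[1]][..., defined].astype(float)
        if statistic == "index":
            v = v / d[iu][defined]
        return v

    skipped = [
        t for t in range(t_max) if int(presence.values[:, t].sum()) < 2
    ]
    if skipped:
        warnings.warn(
            f"periods with fewer than 2 present individuals skipped: {skipped}",
            stacklevel=2,
        )

    tot_perm = np.zeros((n_perm, n, n), dtype=np.int64)
    for t in range(t_max):
        xt = occ.x[t]
        if t in skipped or not xt.any():
            tot_perm += xt[None]
            continue
        pi = np.tile(np.arange(n), (n_perm, 1))
        for gi in g_idx:
            here = gi[presence.values[gi, t].astype(bool)]
            if len(here) < 2:
                continue
            order = np.argsort(rng.random((n_perm, len(here))), axis=1)
            pi[:, here] = here[order]
        tot_perm += xt[pi[:, :, None], pi[:, None, :]]

    real = dyad_values(occ.x.sum(axis=0))
    null = dyad_values(tot_perm)
    real_mean, real_sd = float(real.mean()), float(real.std())
    null_means, null_sds = null.mean(axis=1), null.std(axis=1)
    p_mean = (1 + int((null_means <= real_mean).sum())) / (n_perm + 1)
    p_sd = (1 + int((null_sds >= real_sd).sum())) / (n_perm + 1)
    label = "association index" if statistic == "index" else "dyadic event count"
    return PreferredAssociationResult(
        mean_test=PermTestResult(
            real_mean, float(null_means.mean()), float(null_means.std()),
            p_mean, n_perm, f"mean {label}",
        ),
        sd_test=PermTestResult(
            real_sd, float(null_sds.mean()), float(null_sds.std()),
            p_sd, n_perm, f"SD of {label}",
        ),
        n_perm=n_perm,
        statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    """Mantel Z-test outcome: cross-product statistic, matrix correlation
    coefficient, permutation p-value."""

    z: float
    mcc: float
    p: float
    n_perm: int
    masked_dyads: int
    tail: str = "greater"
    partial_controls: list[str] = field(default_factory=list)


def _mantel_cells(A: DyadicMatrix, B: DyadicMatrix, mask: np.ndarray | None):
    if A.ids != B.ids:
        B = B.reorder(A.ids)
    n = A.n
    inc = np.ones((n, n), dtype=bool)
    np.fill_diagonal(inc, False)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != (n, n):
            raise ValidationError("mask shape does not match matrices")
        inc &= mask.astype(bool)
    if A.mask is not None:
        inc &= A.mask.astype(bool)
    inc &= np.isfinite(A.values)
    if not np.isfinite(B.values[inc]).all():
        raise ValidationError(
            "attribute matrix has missing values on included dyads; drop "
            "those individuals or mask their dyads first"
        )
    if inc.sum() < 3 or len(np.unique(np.nonzero(inc)[0])) < 3:
        raise ValidationError("need at least 3 individuals' worth of unmasked dyads")
    return B, inc


def _mcc(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(b) == 0 or np.ptp(a) == 0:
        raise ValidationError(
            "degenerate attribute matrix: constant on unmasked cells"
        )
    return float(np.corrcoef(a, b)[0, 1])


def mantel_test(
    A: DyadicMatrix,
    B: DyadicMatrix,
    mask: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
    groups: Sequence[Sequence[str]] | None = None,
) -> MantelResult:
    """Mantel Z-test of matrix association with optional dyad mask and
    class-constrained label permutations.

    Z is the sum of A_ij * B_ij over unmasked off-diagonal cells and the
    MCC the Pearson correlation over the same cells.  The null permutes
    the individual labels of B simultaneously for rows and columns; with
    ``groups`` (e.g. small-class and large-class ids) labels permute only
    within their group, so the between-class mask is preserved exactly
    under every permutation.  p is the proportion of permuted Z at least
    as extreme as observed in the chosen ``tail`` (greater/less/two-sided),
    floored at 1/(n_perm + 1).
    """
    B, inc = _mantel_cells(A, B, mask)
    Av = np.where(inc, np.nan_to_num(A.values), 0.0)
    z_obs = float((Av * B.values)[inc].sum())
    iu = np.triu_indices(A.n, 1)
    cells = inc[iu]
    mcc = _mcc(A.values[iu][cells], B.values[iu][cells])

    rng = np.random.default_rng(seed)
    g_idx = _exchangeable_groups(A.ids, groups)
    pi = np.tile(np.arange(A.n), (n_perm, 1))
    for gi in g_idx:
        if len(gi) < 2:
            continue
        order = np.argsort(rng.random((n_perm, len(gi))), axis=1)
        pi[:, gi] = gi[order]
    b_perm = B.values[pi[:, :, None], pi[:, None, :]]
    z_perm = np.einsum("ij,bij->b", Av, b_perm)
    p = _tail_p(z_perm, z_obs, tail, n_perm)
    return MantelResult(
        z=z_obs,
        mcc=mcc,
        p=p,
        n_perm=n_perm,
        masked_dyads=int(cells.sum()),
        tail=tail,
    )


def _tail_p(z_perm: np.ndarray, z_obs: float, tail: str, n_perm: int) -> float:
    if tail == "greater":
        k = int((z_perm >= z_obs).sum())
    elif tail == "less":
        k = int((z_perm <= z_obs).sum())
    elif tail == "two-sided":
        mu = float(z_perm.mean())
        k = int((np.abs(z_perm - mu) >= abs(z_obs - mu)).sum())
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (1 + k) / (n_perm + 1)


def exhaustive_mantel_p(
    A: DyadicMatrix,
    B: DyadicMatrix,
    mask: np.ndarray | None = None,
    tail: str = "greater",
    groups: Sequence[Sequence[str]] | None = None,
) -> float:
    """Exact Mantel p by enumerating every (group-constrained) label
    permutation.  Feasible for small groups only; used as the oracle for
    the sampled test."""
    B, inc = _mantel_cells(A, B, mask)
    Av = np.where(inc, np.nan_to_num(A.values), 0.0)
    z_obs = float((Av * B.values)[inc].sum())
    g_idx = _exchangeable_groups(A.ids, groups)
    zs = []
    for pi in _product_permutations(A.n, g_idx):
        zs.append(float((Av * B.values[np.ix_(pi, pi)])[inc].sum()))
    zs = np.asarray(zs)
    if tail == "greater":
        k = int((zs >= z_obs - 1e-12).sum())
    elif tail == "less":
        k = int((zs <= z_obs + 1e-12).sum())
    else:
        mu = float(zs.mean())
        k = int((np.abs(zs - mu) >= abs(z_obs - mu) - 1e-12).sum())
    return k / len(zs)


def _product_permutations(n: int, g_idx: list[np.ndarray]):
    base = np.arange(n)

    def rec(k: int, current: np.ndarray):
        if k == len(g_idx):
            yield current.copy()
            return
        gi = g_idx[k]
        for perm in _iter_permutations(gi):
            current[gi] = perm
            yield from rec(k + 1, current)
        current[gi] = gi

    yield from rec(0, base.copy())


def partial_mantel_test(
    A: DyadicMatrix,
    B: DyadicMatrix,
    controls: Sequence[DyadicMatrix],
    mask: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "greater",
    groups: Sequence[Sequence[str]] | None = None,
    control_names: Sequence[str] | None = None,
) -> MantelResult:
    """Partial Mantel test: Mantel machinery on OLS residuals.

    Both A and B are regressed (with intercept) on the vectorised control
    matrices over the unmasked cells; the residuals are written back into
    symmetric matrices and tested with the same constrained permutation
    scheme.  Controls that leave B with (numerically) no residual
    variation — e.g. a control equal to B — raise the degenerate-matrix
    error.
    """
    B, inc = _mantel_cells(A, B, mask)
    ctrl = [c.reorder(A.ids) if c.ids != A.ids else c for c in controls]
    iu = np.triu_indices(A.n, 1)
    cells = inc[iu]
    design = np.column_stack(
        [np.ones(int(cells.sum()))] + [c.values[iu][cells] for c in ctrl]
    )
    if not np.isfinite(design).all():
        raise ValidationError("control matrix has missing values on included dyads")

    def residual_matrix(m: DyadicMatrix) -> DyadicMatrix:
        y = m.values[iu][cells]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        out = np.zeros((A.n, A.n))
        rows, cols = iu[0][cells], iu[1][cells]
        out[rows, cols] = resid
        out[cols, rows] = resid
        return DyadicMatrix(A.ids, out, "similarity")

    resid_b = residual_matrix(B)
    if np.ptp(resid_b.values[iu][cells]) < 1e-12 * max(
        1.0, float(np.abs(B.values[iu][cells]).max())
    ):
        raise ValidationError(
            "degenerate attribute matrix: controls absorb all variation in B"
        )
    res = mantel_test(
        residual_matrix(A),
        resid_b,
        mask=inc.astype(np.uint8),
        n_perm=n_perm,
        seed=seed,
        tail=tail,
        groups=groups,
    )
    res.partial_controls = list(
        control_names
        if control_names is not None
        else [c.kind for c in controls]
    )
    return res


# ---------------------------------------------------------------------------
# Attribute similarity encodings
# ---------------------------------------------------------------------------


def indicator_similarity(ids: Sequence[str], labels: Sequence) -> DyadicMatrix:
    """Same-class indicator similarity: 1 if two individuals share the
    label (sex, age class, ...), else 0."""
    lab = np.asarray(labels, dtype=object)
    sim = (lab[:, None] == lab[None, :]).astype(float)
    np.fill_diagonal(sim, 0.0)
    return DyadicMatrix(list(ids), sim, "similarity")


def rank_similarity(ids: Sequence[str], scores: Sequence[float]) -> DyadicMatrix:
    """Rank similarity: negative absolute score difference rescaled to
    [0, 1] (1 = identical scores)."""
    s = np.asarray(scores, dtype=float)
    diff = np.abs(s[:, None] - s[None, :])
    rng = diff.max()
    sim = 1.0 - (diff / rng if rng > 0 else diff)
    np.fill_diagonal(sim, 0.0)
    return DyadicMatrix(list(ids), sim, "similarity")
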