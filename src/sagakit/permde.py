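"""Paired-difference permutation test for leader/follower differential expression.

The design has four groups of n replicates (default n=3): leader and
follower cells, plus two controls that calibrate the photoconversion
artifact — invasive cells that were photoconverted (``ctrl_photo``, "IR")
and invasive cells that were not (``ctrl_nonphoto``, "NG").

For each gene and direction, all n*n pairwise differences are formed
between treatment groups (leader_i - follower_j, or reversed) and between
the controls (ctrl_photo_i - ctrl_nonphoto_j).  Two statistics are
computed from these difference sets:

* ``t_one`` — one-sample t of the treatment differences against zero
  (is the leader/follower shift non-zero?);
* ``t_two`` — pooled-variance two-sample t of the treatment differences
  against the ABSOLUTE control differences (is the shift larger than the
  photoconversion artifact?).

The permutation null (default ``regroup`` scheme) reassigns which samples
of the minuend sextet (leader + photoconverted control) and of the
subtrahend sextet (follower + non-photoconverted control) form the
treatment grid versus the control grid — C(6,3)^2 = 400 assignments at
n=3, enumerated exhaustively.  Regrouping whole samples preserves the
cross-pair dependence inside each difference grid, which a direct
reshuffle of the 18 difference values destroys.  For every assignment the
joint-exceedance count N(a) = #{b : both permuted statistics of b meet or
exceed those of a} is computed, and the p-value is the rank of the
identity's count within its own permutation distribution — an exact test
under exchangeability.  A photoconversion-artifact gene (equal shift in
leader and photoconverted-control samples) is invariant under these
regroupings, so its p-value is uniform and it is selected only at the
nominal rate, which is the point of the construction.  The literal
difference-pool reassignment is retained as scheme ``pool`` for
sampling-accuracy checks; it does not control the type-I error.

Normalisation utilities (quantile normalisation, log2 transform, mean
probeset summarisation) reproduce the preprocessing this test presupposes.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb

GROUPS = ("leader", "follower", "ctrl_photo", "ctrl_nonphoto")

__all__ = [
    "PermParams",
    "DifferencePairs",
    "quantile_normalize",
    "log2_transform",
    "summarize_probesets",
    "make_difference_pairs",
    "gene_stats",
    "permutation_p",
    "run_de",
]


# ---------------------------------------------------------------------------
# Normalisation utilities
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common rank-mean distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values at each rank; ties within a column receive the mean of
    their ranks' means.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        # tied values receive the mean of their ranks' rank-means
        codes = np.unique(col, return_inverse=True)[1]
        sums = np.bincount(codes[order], weights=rank_means)
        counts = np.bincount(codes)
        out[:, j] = (sums / counts)[codes]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise log2(value + offset)."""
    shifted = matrix + offset
    bad = (shifted <= 0).any(axis=1)
    if bad.any():
        names = list(matrix.index[bad][:10])
        raise ValueError(
            f"log2 transform undefined for {int(bad.sum())} genes with "
            f"non-positive values (e.g. {names}); increase the offset"
        )
    return np.log2(shifted)


def summarize_probesets(matrix: pd.DataFrame,
                        probe_to_gene: pd.Series | dict) -> pd.DataFrame:
    """Mean of probe rows per gene; unmapped probes are dropped (counted in attrs)."""
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")
    mapped = matrix.index.intersection(mapping.index)
    dropped = len(matrix) - len(mapped)
    genes = matrix.loc[mapped].groupby(mapping.loc[mapped]).mean()
    genes.index.name = "gene_id"
    genes.attrs["unmapped_probes"] = int(dropped)
    return genes


# ---------------------------------------------------------------------------
# Difference pairs and statistics
# ---------------------------------------------------------------------------

def _group_columns(design: pd.DataFrame, group: str) -> list:
    sub = design[design.group == group].sort_values("replicate")
    if sub.empty:
        raise ValueError(f"design is missing group {group!r}")
    return list(sub.sample_id)


def validate_design(design: pd.DataFrame, n_reps: int | None = None) -> int:
    """Check the 4-group design is complete and balanced; return n replicates."""
    counts = {g: len(design[design.group == g]) for g in GROUPS}
    missing = [g for g, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"design is missing groups: {missing}")
    sizes = set(counts.values())
    if len(sizes) != 1:
        raise ValueError(f"unbalanced design: {counts}")
    n = sizes.pop()
    if n_reps is not None and n != n_reps:
        raise ValueError(f"expected {n_reps} replicates per group, found {n}")
    if n < 2:
        raise ValueError("need >= 2 replicates per group")
    return n


@dataclass(frozen=True)
class DifferencePairs:
    """All n*n cross-group differences per gene, stored signed.

    ``treatment`` holds leader_i - follower_j (or the reverse for the
    follower direction); ``control`` holds ctrl_photo_i - ctrl_nonphoto_j.
    Absolute values of the control set are taken at statistic time.
    """

    gene_ids: pd.Index
    treatment: np.ndarray  # (genes, n*n), signed
    control: np.ndarray    # (genes, n*n), signed
    direction: str
    # the underlying sample values, needed by the regrouping permutation:
    # minuend side [treatment first n cols | control last n cols] and
    # subtrahend side likewise; None when built from bare difference sets
    top: np.ndarray | None = None     # (genes, 2n)
    bottom: np.ndarray | None = None  # (genes, 2n)

    @property
    def n_pairs(self) -> int:
        return self.treatment.shape[1]

    @property
    def n_reps(self) -> int:
        return int(round(math.sqrt(self.n_pairs)))


def make_difference_pairs(matrix: pd.DataFrame, design: pd.DataFrame,
                          direction: str = "leader") -> DifferencePairs:
    """Form the n*n treatment and control difference sets for every gene."""
    if direction not in ("leader", "follower"):
        raise ValueError("direction must be 'leader' or 'follower'")
    validate_design(design)
    leader = matrix[_group_columns(design, "leader")].to_numpy(dtype=float)
    follower = matrix[_group_columns(design, "follower")].to_numpy(dtype=float)
    photo = matrix[_group_columns(design, "ctrl_photo")].to_numpy(dtype=float)
    nonphoto = matrix[_group_columns(design, "ctrl_nonphoto")].to_numpy(dtype=float)

    def cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a[:, :, None] - b[:, None, :]).reshape(len(a), -1)

    if direction == "leader":
        treatment = cross(leader, follower)
        top = np.concatenate([leader, photo], axis=1)
        bottom = np.concatenate([follower, nonphoto], axis=1)
    else:
        treatment = cross(follower, leader)
        top = np.concatenate([follower, nonphoto], axis=1)
        bottom = np.concatenate([leader, photo], axis=1)
    control = cross(photo, nonphoto)
    return DifferencePairs(matrix.index, treatment, control, direction,
                           top=top, bottom=bottom)


def _degenerate_t(numerator: np.ndarray) -> np.ndarray:
    """Zero-variance convention: +/-inf by the numerator's sign, 0 at 0."""
    return np.where(numerator > 0, np.inf, np.where(numerator < 0, -np.inf, 0.0))


def _t_one(values: np.ndarray) -> np.ndarray:
    """One-sample t against 0 along the last axis, with the zero-variance
    convention: +/-inf by the sign of the mean, 0 when the mean is 0."""
    m = values.shape[-1]
    mean = values.mean(axis=-1)
    sd = values.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(m))
    return np.where(sd == 0, _degenerate_t(mean), t)


def _t_two_pooled(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (a vs b) along the last axis, same
    zero-variance convention on the mean difference."""
    na, nb = a.shape[-1], b.shape[-1]
    diff = a.mean(axis=-1) - b.mean(axis=-1)
    va = a.var(axis=-1, ddof=1)
    vb = b.var(axis=-1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    return np.where(denom == 0, _degenerate_t(diff), t)


def _t_two_welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[-1], b.shape[-1]
    diff = a.mean(axis=-1) - b.mean(axis=-1)
    denom = np.sqrt(a.var(axis=-1, ddof=1) / na + b.var(axis=-1, ddof=1) / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    return np.where(denom == 0, _degenerate_t(diff), t)


def gene_stats(pairs: DifferencePairs, welch: bool = False) -> pd.DataFrame:
    """Observed statistics per gene: columns ``t_one``, ``t_two``."""
    t_two = _t_two_welch if welch else _t_two_pooled
    return pd.DataFrame(
        {
            "t_one": _t_one(pairs.treatment),
            "t_two": t_two(pairs.treatment, np.abs(pairs.control)),
        },
        index=pairs.gene_ids,
    )


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermParams:
    """Permutation-test configuration.

    B
        Number of permutations (the study default is 500).  When the full
        assignment group is no larger than B (as for the default scheme at
        n=3, with C(6,3)^2 = 400 assignments) it is enumerated exhaustively.
    alpha
        Selection threshold on the raw permutation p-value (default 0.05).
    scheme
        ``regroup`` (default): the permutation reassigns which samples of
        the minuend sextet (leader + photoconverted control) and of the
        subtrahend sextet (follower + non-photoconverted control) play the
        treatment versus the control role, preserving the cross-pair
        dependence of each difference grid; the joint-exceedance count is
        then calibrated against its own permutation distribution, making
        the p-value exact under exchangeability.
        ``pool``: reassign the 2*n^2 pooled difference values directly to
        the treatment/control roles and report the raw joint-exceedance
        fraction.  This variant ignores the dependence among the cross
        differences and does not control the type-I error; it is retained
        for sampling-accuracy checks against exhaustive enumeration.
    exhaustive
        Force full enumeration whenever the group size is at most
        ``exhaustive_cap``; p is then the exact fraction.
    """

    B: int = 500
    alpha: float = 0.05
    seed: int = 0
    scheme: str = "regroup"
    exhaustive: bool = False
    exhaustive_cap: int = 200_000
    welch: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scheme not in ("regroup", "pool"):
            raise ValueError("scheme must be 'regroup' or 'pool'")


def _sample_assignments(n_pool: int, m: int, B: int,
                        rng: np.random.Generator) -> np.ndarray:
    """B distinct m-subsets of range(n_pool), as a (B, n_pool) boolean matrix."""
    total = comb(n_pool, m, exact=True)
    if total <= B:
        combos = list(itertools.combinations(range(n_pool), m))
    else:
        seen: set[tuple[int, ...]] = set()
        combos = []
        while len(combos) < B:
            pick = tuple(sorted(rng.choice(n_pool, size=m, replace=False).tolist()))
            if pick not in seen:
                seen.add(pick)
                combos.append(pick)
    sel = np.zeros((len(combos), n_pool), dtype=bool)
    for i, c in enumerate(combos):
        sel[i, list(c)] = True
    return sel


def _exhaustive_assignments(n_pool: int, m: int) -> np.ndarray:
    sel = np.zeros((comb(n_pool, m, exact=True), n_pool), dtype=bool)
    for i, c in enumerate(itertools.combinations(range(n_pool), m)):
        sel[i, list(c)] = True
    return sel


def _perm_stats(pool: np.ndarray, sel: np.ndarray,
                welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Joint (t_one, t_two) for every (gene, assignment) pair.

    ``pool`` is (genes, 2m) signed values; ``sel`` is (B, 2m) booleans
    marking the treatment role.  Everything reduces to matrix products of
    the pool (and its squares / absolute values) with the role indicators.
    """
    m = sel.shape[1] // 2
    s = sel.T.astype(float)          # (2m, B)
    c = (~sel).T.astype(float)
    p = pool                          # (genes, 2m)
    p2 = pool ** 2
    pa = np.abs(pool)

    sum_t = p @ s                     # (genes, B)
    sumsq_t = p2 @ s
    mean_t = sum_t / m
    var_t = np.maximum(sumsq_t - sum_t ** 2 / m, 0.0) / (m - 1)

    sum_c = pa @ c
    sumsq_c = p2 @ c                  # |x|^2 == x^2
    mean_c = sum_c / m
    var_c = np.maximum(sumsq_c - sum_c ** 2 / m, 0.0) / (m - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_one = mean_t / np.sqrt(var_t / m)
        if welch:
            denom = np.sqrt(var_t / m + var_c / m)
        else:
            denom = np.sqrt((var_t + var_c) / 2.0 * (2.0 / m))
        t_two = (mean_t - mean_c) / denom
    t_one = np.where(var_t == 0, _degenerate_t(mean_t), t_one)
    t_two = np.where(denom == 0, _degenerate_t(mean_t - mean_c), t_two)
    return t_one, t_two


def _joint_exceed_count(pool: np.ndarray, sel: np.ndarray, t1_obs: np.ndarray,
                        t2_obs: np.ndarray, welch: bool,
                        block: int = 128) -> np.ndarray:
    """Count assignments whose permuted (t_one, t_two) both meet or exceed the
    observed pair; ties (including inf vs inf) count as exceedance."""
    genes = pool.shape[0]
    count = np.zeros(genes, dtype=np.int64)
    # numerical ties (identity assignment recomputed along a different
    # summation order) must still count as exceedance
    tol1 = 1e-9 * (1.0 + np.abs(t1_obs))
    tol2 = 1e-9 * (1.0 + np.abs(t2_obs))
    for start in range(0, sel.shape[0], block):
        t1, t2 = _perm_stats(pool, sel[start:start + block], welch)
        count += ((t1 >= (t1_obs - tol1)[:, None])
                  & (t2 >= (t2_obs - tol2)[:, None])).sum(axis=1)
    return count


# --- regrouping scheme -----------------------------------------------------

def _regroup_plan(n: int, params: PermParams,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Assignments for the regrouping scheme.

    Each assignment picks n of the 2n minuend samples and n of the 2n
    subtrahend samples for the treatment grid (the complements form the
    control grid).  Returns (sel_top, sel_bot, exhaustive) with the
    identity assignment (first n columns of each side) in row 0.
    """
    total = comb(2 * n, n, exact=True) ** 2
    cap = max(params.B, params.exhaustive_cap if params.exhaustive else 0)
    combos = list(itertools.combinations(range(2 * n), n))
    if total <= cap:
        pairs_idx = list(itertools.product(range(len(combos)), repeat=2))
        exhaustive = True
    else:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        seen = {(0, 0)}
        pairs_idx = [(0, 0)]  # identity first
        while len(pairs_idx) < params.B:
            pick = (int(rng.integers(len(combos))), int(rng.integers(len(combos))))
            if pick not in seen:
                seen.add(pick)
                pairs_idx.append(pick)
        exhaustive = False
    sel_top = np.zeros((len(pairs_idx), 2 * n), dtype=bool)
    sel_bot = np.zeros((len(pairs_idx), 2 * n), dtype=bool)
    for i, (a, b) in enumerate(pairs_idx):
        sel_top[i, list(combos[a])] = True
        sel_bot[i, list(combos[b])] = True
    return sel_top, sel_bot, exhaustive


def _regroup_stats(top: np.ndarray, bottom: np.ndarray, sel_top: np.ndarray,
                   sel_bot: np.ndarray, welch: bool
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(t_one, t_two) of shape (genes, assignments) for the regroup scheme."""
    genes = top.shape[0]
    A = sel_top.shape[0]
    t1 = np.empty((genes, A))
    t2 = np.empty((genes, A))
    t_two = _t_two_welch if welch else _t_two_pooled
    for a in range(A):
        st, sb = sel_top[a], sel_bot[a]
        treat = (top[:, st][:, :, None] - bottom[:, sb][:, None, :]).reshape(genes, -1)
        ctrl = (top[:, ~st][:, :, None] - bottom[:, ~sb][:, None, :]).reshape(genes, -1)
        t1[:, a] = _t_one(treat)
        t2[:, a] = t_two(treat, np.abs(ctrl))
    return t1, t2


def _calibrated_depth_p(t1: np.ndarray, t2: np.ndarray,
                        block: int = 256) -> np.ndarray:
    """Exact p from the joint-exceedance count, calibrated by permutation.

    For each assignment a, N(a) = #{b : t1(b) >= t1(a) and t2(b) >= t2(a)}
    (the number of times the permuted data meet or exceed both statistics).
    A small N marks an extreme assignment; the p-value is the fraction of
    assignments at least as extreme as the identity (column 0), with ties
    in N broken by the one-sample statistic.  Under exchangeability the
    identity's rank is uniform, so the p-value is exact.
    """
    genes, A = t1.shape
    p = np.empty(genes)
    for start in range(0, genes, block):
        sl = slice(start, min(start + block, genes))
        x1 = t1[sl][:, :, None]  # (g, A, 1)
        x2 = t2[sl][:, :, None]
        dom = (t1[sl][:, None, :] >= x1) & (t2[sl][:, None, :] >= x2)
        n_dom = dom.sum(axis=2)  # (g, A): N(a) for each assignment
        n0 = n_dom[:, :1]
        t1_0 = t1[sl][:, :1]
        extreme = (n_dom < n0) | ((n_dom == n0) & (t1[sl] >= t1_0))
        p[sl] = extreme.mean(axis=1)
    return p


def permutation_p(pairs: DifferencePairs, params: PermParams,
                  assignments=None) -> pd.Series:
    """Permutation p-value per gene under the configured scheme.

    regroup (default)
        Assignments regroup the minuend/subtrahend samples into treatment
        and control grids (identity included); the joint-exceedance count
        of (t_one, t_two) is calibrated against its own permutation
        distribution, giving an exact p under exchangeability.
    pool
        Assignments give m of the 2m pooled signed differences the
        treatment role and m the control role (absolute value applied);
        p = (count + 1) / (B + 1) for sampled plans, or the exact joint
        exceedance fraction (identity included) when exhaustive.
    """
    if params.scheme == "pool":
        return _pool_permutation_p(pairs, params, assignments)
    if pairs.top is None or pairs.bottom is None:
        raise ValueError("regroup scheme needs DifferencePairs built by "
                         "make_difference_pairs (with sample values)")
    n = pairs.n_reps
    if assignments is None:
        assignments = _regroup_plan(n, params)[:2]
    sel_top, sel_bot = assignments
    t1, t2 = _regroup_stats(pairs.top, pairs.bottom, sel_top, sel_bot,
                            params.welch)
    p = _calibrated_depth_p(t1, t2)
    return pd.Series(p, index=pairs.gene_ids, name=f"p_{pairs.direction}")


def _pool_permutation_p(pairs: DifferencePairs, params: PermParams,
                        assignments: np.ndarray | None = None) -> pd.Series:
    m = pairs.n_pairs
    pool = np.concatenate([pairs.treatment, pairs.control], axis=1)

    obs = gene_stats(pairs, welch=params.welch)
    t1_obs = obs.t_one.to_numpy()
    t2_obs = obs.t_two.to_numpy()

    total = comb(2 * m, m, exact=True)
    exhaustive = params.exhaustive and total <= params.exhaustive_cap
    if assignments is None:
        if exhaustive:
            assignments = _exhaustive_assignments(2 * m, m)
        else:
            rng = np.random.default_rng(params.seed)
            assignments = _sample_assignments(2 * m, m, params.B, rng)
    count = _joint_exceed_count(pool, assignments, t1_obs, t2_obs, params.welch)
    if exhaustive:
        p = count / len(assignments)
    else:
        p = (count + 1) / (len(assignments) + 1)
    return pd.Series(p, index=pairs.gene_ids, name=f"p_{pairs.direction}")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return sps.false_discovery_control(p, method="bh")


def run_de(matrix: pd.DataFrame, design: pd.DataFrame,
           params: PermParams | None = None) -> pd.DataFrame:
    """Two-directional permutation DE over a normalised gene-level matrix.

    Returns one row per gene with the observed statistics, the permutation
    p-value for each direction (leader-up tests leader - follower, the
    follower direction reverses the differences), the selection flags at
    ``alpha``, and supplementary Benjamini-Hochberg q-values (reported, not
    used for selection).  One shared assignment plan is drawn per direction
    and applied to all genes; the run metadata (B, alpha, seed, assignment
    digest) is stored in ``result.attrs``.
    """
    params = params or PermParams()
    validate_design(design)
    rng = np.random.default_rng(params.seed)

    out = {}
    meta = {"B": params.B, "alpha": params.alpha, "seed": params.seed,
            "scheme": params.scheme, "welch": params.welch,
            "exhaustive": params.exhaustive}
    for direction in ("leader", "follower"):
        pairs = make_difference_pairs(matrix, design, direction)
        m = pairs.n_pairs
        if params.scheme == "regroup":
            sel_top, sel_bot, exhausted = _regroup_plan(pairs.n_reps, params, rng)
            plan = (sel_top, sel_bot)
            digest_bits = np.concatenate([sel_top, sel_bot], axis=1)
        else:
            total = comb(2 * m, m, exact=True)
            if params.exhaustive and total <= params.exhaustive_cap:
                plan = _exhaustive_assignments(2 * m, m)
            else:
                plan = _sample_assignments(2 * m, m, params.B, rng)
            digest_bits = plan
        meta[f"assignment_digest_{direction}"] = hashlib.sha256(
            np.packbits(digest_bits).tobytes()).hexdigest()[:16]
        stats = gene_stats(pairs, welch=params.welch)
        p = permutation_p(pairs, params, assignments=plan)
        suffix = "L" if direction == "leader" else "F"
        out[f"t_one_{suffix}"] = stats.t_one
        out[f"t_two_{suffix}"] = stats.t_two
        out[f"p_{direction}"] = p

    result = pd.DataFrame(out, index=matrix.index)
    result["selected_leader"] = result.p_leader < params.alpha
    result["selected_follower"] = result.p_follower < params.alpha
    result["bh_q_leader"] = _bh_adjust(result.p_leader.to_numpy())
    result["bh_q_follower"] = _bh_adjust(result.p_follower.to_numpy())
    result.attrs.update(meta)
    return result
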