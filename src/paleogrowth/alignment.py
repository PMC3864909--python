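"""Composite growth series from multi-specimen longitudinal LAG data.

Each specimen contributes a short time series of annual growth-mark sizes
indexed from its first preserved mark.  Because specimens hatched in
different years and preserve different portions of their growth record, the
series must be shifted by per-specimen time offsets before they describe a
single growth trajectory.  Offsets are continuous (real-valued): nothing
forces two specimens to share a birthday, so integer-year alignment is a
special case the least-squares optimum is free to reject.

The alignment cost for a pair of shifted series is the sum of squared
differences between one series' points and the piecewise-linear
interpolation of the other over the age interval where both are defined;
the total cost sums this over all ordered pairs.  Minimisation is by
coordinate descent with a bounded scalar line search per specimen, warm
started from integer-offset grids.  A gauge is fixed by pinning the
reference specimen (the one with the most samples) at offset zero;
absolute ages remain undetermined up to a global shift unless the youngest
specimen is known to be a neonate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .datasets import LAGSeries, WholeBoneDataset

__all__ = [
    "OffsetAssignment",
    "overlap_cost",
    "pairwise_cost",
    "align_series",
    "composite",
    "split_align",
    "SplitResult",
]


@dataclass
class OffsetAssignment:
    """Per-specimen continuous time offsets and the cost they induce."""

    specimen_ids: list
    offsets: np.ndarray          # years, reference specimen at 0.0
    total_cost: float            # squared size units
    reference: str
    n_overlapping_pairs: int = 0
    n_pairs: int = 0
    components: Optional[list] = None   # connected components if > 1
    converged: bool = True

    @property
    def offset_by_id(self) -> dict:
        return dict(zip(self.specimen_ids, (float(o) for o in self.offsets)))

    @property
    def fully_connected(self) -> bool:
        return self.components is None or len(self.components) == 1


def overlap_cost(a: LAGSeries, b: LAGSeries, offset: float):
    """Cost of matching series ``a`` against series ``b`` shifted by ``offset``.

    ``b``'s samples are placed at ages ``year_index + offset`` in ``a``'s
    frame.  Returns ``(cost, n_overlap)``; a pair with no overlapping age
    interval contributes zero cost and is flagged by ``n_overlap == 0``.
    """
    ta = a.year_indices
    tb = b.year_indices + offset
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if lo > hi:
        return 0.0, 0
    sel = (ta >= lo) & (ta <= hi)
    n = int(np.sum(sel))
    if n == 0:
        return 0.0, 0
    interp = np.interp(ta[sel], tb, b.dimensions)
    return float(np.sum((a.dimensions[sel] - interp) ** 2)), n


def pairwise_cost(series: Sequence[LAGSeries], offsets) -> float:
    """Total alignment cost: sum of overlap_cost over all ordered pairs."""
    total = 0.0
    for i, j in itertools.permutations(range(len(series)), 2):
        sa, sb = series[i], series[j]
        c, _ = overlap_cost(_shifted(sa, offsets[i]), sb, offsets[j])
        total += c
    return total


def _shifted(s: LAGSeries, tau: float) -> LAGSeries:
    if tau == 0.0:
        return s
    out = LAGSeries.__new__(LAGSeries)
    out.specimen_id = s.specimen_id
    out.year_indices = s.year_indices + tau
    out.dimensions = s.dimensions
    out.bone, out.dimension_type, out.units = s.bone, s.dimension_type, s.units
    return out


def _cost_for_specimen(series, offsets, idx):
    """Cost terms involving specimen idx only (for coordinate descent)."""
    total = 0.0
    si = _shifted(series[idx], offsets[idx])
    for j in range(len(series)):
        if j == idx:
            continue
        sj = _shifted(series[j], offsets[j])
        c1, _ = overlap_cost(si, sj, 0.0)
        c2, _ = overlap_cost(sj, si, 0.0)
        total += c1 + c2
    return total


def align_series(series: Sequence[LAGSeries], max_iter: int = 200,
                 tol: float = 1e-10, integer_halfwidth: int = 15) -> OffsetAssignment:
    """Least-squares continuous offsets for a set of LAG series.

    The specimen with the most samples (ties: first) is the reference with
    offset 0.  Integer-offset warm starts bracket each specimen's offset;
    coordinate descent with a bounded scalar minimiser then refines all
    offsets until the total cost changes by less than ``tol``.
    """
    series = list(series)
    if len(series) == 0:
        raise ValueError("align_series needs at least one series")
    m = len(series)
    ids = [s.specimen_id for s in series]
    ref = max(range(m), key=lambda i: (series[i].n, -i))
    offsets = np.zeros(m)

    if m > 1:
        # warm start: add specimens in decreasing size, integer-grid each
        order = sorted((i for i in range(m) if i != ref),
                       key=lambda i: -np.max(series[i].dimensions))
        placed = [ref]
        for i in order:
            lo = -integer_halfwidth
            hi = int(max(s.year_indices[-1] + integer_halfwidth
                         for s in series)) + 1
            best_tau, best_c = 0.0, math.inf
            for tau in range(lo, hi):
                offsets[i] = float(tau)
                c = _cost_partial(series, offsets, placed + [i])
                n = _overlap_count(series, offsets, placed, i)
                if n == 0:
                    continue
                if c < best_c:
                    best_tau, best_c = float(tau), c
            offsets[i] = best_tau
            placed.append(i)

        last = pairwise_cost(series, offsets)
        converged = False
        for _ in range(max_iter):
            for i in range(m):
                if i == ref:
                    continue
                tau0 = offsets[i]

                def f(tau):
                    offsets[i] = tau
                    return _cost_for_specimen(series, offsets, i)

                res = optimize.minimize_scalar(
                    f, bounds=(tau0 - 2.0, tau0 + 2.0), method="bounded",
                    options={"xatol": 1e-10})
                cost0 = f(tau0)
                # a move may not strand the specimen without any overlap:
                # the zero cost of a disconnected placement is vacuous, not good
                offsets[i] = float(res.x)
                others = [j for j in range(m) if j != i]
                if res.fun > cost0 or _overlap_count(series, offsets, others,
                                                     i) == 0:
                    offsets[i] = tau0
            cost = pairwise_cost(series, offsets)
            if abs(last - cost) < tol:
                converged = True
                break
            last = cost
    else:
        converged = True

    offsets -= offsets[ref]
    total = pairwise_cost(series, offsets)
    n_pairs = m * (m - 1) // 2
    n_olap, comps = _overlap_graph(series, offsets)
    return OffsetAssignment(ids, offsets, total, ids[ref],
                            n_overlapping_pairs=n_olap, n_pairs=n_pairs,
                            components=comps if len(comps) > 1 else None,
                            converged=converged)


def _cost_partial(series, offsets, idxs):
    total = 0.0
    for i, j in itertools.permutations(idxs, 2):
        c, _ = overlap_cost(_shifted(series[i], offsets[i]), series[j],
                            offsets[j])
        total += c
    return total


def _overlap_count(series, offsets, placed, i):
    n = 0
    for j in placed:
        _, nij = overlap_cost(_shifted(series[i], offsets[i]), series[j],
                              offsets[j])
        n += nij
    return n


def _overlap_graph(series, offsets):
    m = len(series)
    n_olap = 0
    adj = {i: set() for i in range(m)}
    for i, j in itertools.combinations(range(m), 2):
        _, nij = overlap_cost(_shifted(series[i], offsets[i]), series[j],
                              offsets[j])
        _, nji = overlap_cost(_shifted(series[j], offsets[j]), series[i],
                              offsets[i])
        if nij + nji > 0:
            n_olap += 1
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(m):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(series[v].specimen_id)
            stack.extend(adj[v] - seen)
        comps.append(comp)
    return n_olap, comps


def composite(series: Sequence[LAGSeries], assignment: OffsetAssignment,
              global_shift: Optional[float] = None,
              name: str = "composite") -> WholeBoneDataset:
    """Merge aligned series into one cross-sectional data set.

    Ages are ``year_index + offset + global_shift``; the global shift encodes
    external knowledge of absolute age (e.g. the smallest specimen being a
    neonate).  With ``global_shift=None`` the smallest composite age is
    placed at zero — alignment alone cannot fix absolute ages, only relative
    ones.
    """
    off = assignment.offset_by_id
    ages, dims, ids = [], [], []
    for s in series:
        tau = off[s.specimen_id]
        ages.extend(s.year_indices + tau)
        dims.extend(s.dimensions)
        ids.extend([s.specimen_id] * s.n)
    ages = np.asarray(ages, float)
    shift = -float(np.min(ages)) if global_shift is None else float(global_shift)
    ages = ages + shift
    order = np.argsort(ages)
    ages = np.asarray(ages)[order]
    dims = np.asarray(dims)[order]
    ids = [ids[i] for i in order]
    first = series[0]
    return WholeBoneDataset(ages=ages, dimensions=dims, specimen_ids=ids,
                            dimension_type=first.dimension_type,
                            bone=first.bone, units=first.units, name=name)


@dataclass
class SplitResult:
    groups: list                  # list of lists of specimen ids
    assignments: list             # per-group OffsetAssignment
    split_cost: float
    single_cost: float

    @property
    def improvement(self) -> float:
        """Cost reduction of the split versus one-cluster alignment."""
        return self.single_cost - self.split_cost


def split_align(series: Sequence[LAGSeries], n_groups: int = 2,
                seed: int = 0, max_exhaustive: int = 10,
                n_restarts: int = 20) -> SplitResult:
    """Partition series into groups aligned separately, minimising total cost.

    Exhaustive search over all two-group partitions for up to
    ``max_exhaustive`` specimens; a seeded stochastic swap search beyond
    that.  Useful when incompatible specimens (e.g. two biologically distinct
    populations) corrupt a single-cluster alignment.
    """
    series = list(series)
    m = len(series)
    if m < 2:
        raise ValueError("split_align needs at least two series")
    if n_groups != 2:
        raise NotImplementedError("only two-group splits are supported")

    single = align_series(series)

    def eval_partition(mask):
        g1 = [series[i] for i in range(m) if mask[i]]
        g2 = [series[i] for i in range(m) if not mask[i]]
        if not g1 or not g2:
            return math.inf, None, None
        a1 = align_series(g1)
        a2 = align_series(g2)
        return a1.total_cost + a2.total_cost, a1, a2

    best = (math.inf, None, None, None)
    if m <= max_exhaustive:
        for bits in range(1, 2 ** (m - 1)):
            mask = [(bits >> i) & 1 == 1 for i in range(m - 1)] + [False]
            cost, a1, a2 = eval_partition(mask)
            if cost < best[0]:
                best = (cost, a1, a2, mask)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mask = rng.random(m) < 0.5
            if mask.all() or not mask.any():
                mask[0] = not mask[0]
            mask = list(mask)
            cost, a1, a2 = eval_partition(mask)
            improved = True
            while improved:
                improved = False
                for i in range(m):
                    trial = list(mask)
                    trial[i] = not trial[i]
                    c2, b1, b2 = eval_partition(trial)
                    if c2 < cost:
                        mask, cost, a1, a2 = trial, c2, b1, b2
                        improved = True
            if cost < best[0]:
                best = (cost, a1, a2, mask)

    cost, a1, a2, mask = best
    groups = [[series[i].specimen_id for i in range(m) if mask[i]],
              [series[i].specimen_id for i in range(m) if not mask[i]]]
    return SplitResult(groups=groups, assignments=[a1, a2],
                       split_cost=cost, single_cost=single.total_cost)
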