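"""Data preparation: 3-sigma outlier exclusion and stratified balanced sampling.

Two stages run between raw yield-monitor ingestion and model fitting:

* a single-pass 3-sigma filter — within each scope (by default each treatment
  group separately) the mean and standard deviation of dry yield are computed
  once from the unfiltered data and every measurement outside mean ± 3·sd is
  excluded;
* stratified random sampling with each field as a stratum, drawing a number of
  measurements per group proportional to stratum sizes (largest-remainder
  rounding) so that both treatment groups end up with identical sample sizes
  and no single large field dominates the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ScopeTooSmallError(ValueError):
    """A filtering scope holds fewer than two measurements (sd undefined)."""


@dataclass(frozen=True)
class FilterReport:
    """Outcome of 3-sigma filtering within one scope."""

    scope: str
    n_input: int
    n_removed: int
    lower_bound: float
    upper_bound: float

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    @property
    def retained_fraction(self) -> float:
        return self.n_kept / self.n_input


def three_sigma_filter(df: pd.DataFrame, scope: str = "group",
                       n_sigma: float = 3.0):
    """Exclude yields outside mean ± ``n_sigma``·sd of their scope.

    Parameters
    ----------
    df : measurement table (see :data:`~yieldbayes.simulate.MEASUREMENT_COLUMNS`).
    scope : ``"group"`` (default) filters test and control separately, so a
        genuine treatment effect cannot push one group's tail past the pooled
        bounds; ``"pooled"`` uses a single set of bounds for the whole table.
    n_sigma : half-width of the retention band in standard deviations.

    Returns
    -------
    (kept, reports) : the retained rows (original order) and one
    :class:`FilterReport` per scope.

    Bounds come from the unfiltered data and are applied once (no iterative
    re-estimation).  A zero-variance scope keeps every measurement — the bounds
    collapse onto the common value.
    """
    if scope == "group":
        grouped = [(f"group={g}", sub) for g, sub in df.groupby("group", sort=True)]
    elif scope == "pooled":
        grouped = [("pooled", df)]
    else:
        raise ValueError(f"unknown filter scope {scope!r}")

    keep = pd.Series(False, index=df.index)
    reports = []
    for label, sub in grouped:
        if len(sub) < 2:
            raise ScopeTooSmallError(
                f"scope {label!r} has {len(sub)} measurement(s); need >= 2")
        y = sub["dry_yield_kg_ha"]
        mean, sd = y.mean(), y.std(ddof=1)
        lo, hi = mean - n_sigma * sd, mean + n_sigma * sd
        inside = (y >= lo) & (y <= hi)
        keep.loc[sub.index] = inside
        reports.append(FilterReport(scope=label, n_input=len(sub),
                                    n_removed=int((~inside).sum()),
                                    lower_bound=float(lo), upper_bound=float(hi)))
        logger.info("3-sigma filter %s: kept %d/%d in [%.1f, %.1f]",
                    label, int(inside.sum()), len(sub), lo, hi)
    return df[keep], reports


@dataclass(frozen=True)
class SamplingPlan:
    """Per-stratum allocation of the balanced sample."""

    target_per_group: int
    seed: int
    allocations: dict = field(default_factory=dict)  # group -> {field_id: count}

    def group_total(self, group: str) -> int:
        return sum(self.allocations[group].values())


def proportional_allocation(sizes: pd.Series, target: int) -> dict:
    """Largest-remainder allocation of ``target`` over strata with ``sizes``.

    Ties in the fractional remainders are broken lexicographically by stratum
    id, making the allocation fully deterministic.
    """
    total = int(sizes.sum())
    if target > total:
        raise ValueError(f"target {target} exceeds group size {total}")
    exact = sizes * target / total
    base = np.floor(exact).astype(int)
    shortfall = target - int(base.sum())
    remainders = exact - base
    order = sorted(sizes.index, key=lambda fid: (-remainders[fid], str(fid)))
    alloc = base.to_dict()
    for fid in order[:shortfall]:
        alloc[fid] += 1
    return {str(k): int(v) for k, v in alloc.items()}


def stratified_balance_sample(df: pd.DataFrame, target_per_group: int | None = None,
                              seed: int = 0):
    """Equalise the two treatment groups by per-field stratified sampling.

    Each field is a stratum; within each group, ``target_per_group``
    measurements are allocated to strata proportionally to stratum size
    (largest-remainder rounding) and then drawn uniformly without replacement
    with a seeded generator.  The default target is the size of the smaller
    group, so the larger group is thinned down to parity.

    Returns ``(sampled, plan)``; ``sampled`` preserves the original row order.
    """
    group_sizes = df.groupby("group").size()
    if len(group_sizes) < 2:
        raise ValueError("both test and control measurements are required")
    if target_per_group is None:
        target_per_group = int(group_sizes.min())
    if target_per_group < 1:
        raise ValueError("target_per_group must be positive")

    ss = np.random.SeedSequence(seed)
    allocations: dict = {}
    chosen = []
    for child, (group, sub) in zip(ss.spawn(len(group_sizes)),
                                   df.groupby("group", sort=True)):
        if target_per_group > len(sub):
            raise ValueError(
                f"target_per_group={target_per_group} exceeds group "
                f"{group!r} size {len(sub)}")
        rng = np.random.default_rng(child)
        sizes = sub.groupby("field_id").size()
        alloc = proportional_allocation(sizes, target_per_group)
        allocations[group] = alloc
        for fid in sorted(alloc):
            k = alloc[fid]
            if k == 0:
                logger.info("stratum %s/%s allocated 0 measurements", group, fid)
                continue
            idx = sub.index[sub["field_id"] == fid].to_numpy()
            chosen.append(rng.choice(idx, size=k, replace=False))
    plan = SamplingPlan(target_per_group=target_per_group, seed=seed,
                        allocations=allocations)
    picked = np.sort(np.concatenate(chosen))
    return df.loc[picked], plan
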