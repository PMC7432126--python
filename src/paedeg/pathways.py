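"""Microbial degradation pathway barrier accounting.

A compound's degradation is represented as named transformation paths
(Path1: Gram-negative 4,5-dioxygenation route; Path2: Gram-positive
3,4-dihydroxylation route), each an ordered chain of reaction steps with a
quantum-chemically computed energy barrier (kJ/mol, inputs here).  The
module sums step barriers into path totals, computes change rates against a
reference compound, aggregates them, and pairs barrier changes with
composite-biodegradability changes to check for the expected sign
opposition (lower barrier, higher biodegradability).

The published "total change rate" is the *sum* of the per-path percent
changes.  That aggregate is reproduced as the default because it is the
printed convention; a per-path mean is available via ``aggregate="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathwayStep",
    "path_total",
    "path_change_rate",
    "total_change_rate",
    "pathway_report",
    "consistency_report",
]


@dataclass
class PathwayStep:
    reactant: str
    product: str
    barrier: float  # kJ/mol


def _validate_chain(steps: list[PathwayStep]) -> None:
    if not steps:
        raise ValueError("empty path")
    for prev, nxt in zip(steps, steps[1:]):
        if prev.product != nxt.reactant:
            raise ValueError(
                f"broken chain: step product {prev.product!r} != next "
                f"reactant {nxt.reactant!r}")
    if any(s.barrier <= 0 for s in steps):
        raise ValueError("step barriers must be positive")


def path_total(steps: list[PathwayStep]) -> float:
    """Total barrier of a path: the sum of its chained step barriers."""
    _validate_chain(steps)
    return float(sum(s.barrier for s in steps))


def path_change_rate(derivative_total: float, reference_total: float) -> float:
    """Percent change ``100 (derivative - reference) / reference``."""
    if reference_total <= 0:
        raise ValueError("reference total barrier must be positive")
    return 100.0 * (derivative_total - reference_total) / reference_total


def total_change_rate(path_change_rates, aggregate: str = "sum") -> float:
    """Aggregate per-path change rates across paths.

    ``"sum"`` is the published convention (per-path percentages are added);
    ``"mean"`` averages them instead.
    """
    rates = np.asarray(list(path_change_rates), dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one path change rate")
    if aggregate == "sum":
        return float(rates.sum())
    if aggregate == "mean":
        return float(rates.mean())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def pathway_report(steps: pd.DataFrame, reference: str = "DEP",
                   aggregate: str = "sum") -> pd.DataFrame:
    """Totals and change rates for a long-format step table.

    ``steps`` needs columns ``compound, path, step, reactant, product,
    barrier``; rows are ordered by ``step`` within each (compound, path).
    The reference compound gets no change rate.
    """
    required = {"compound", "path", "step", "reactant", "product", "barrier"}
    missing = required - set(steps.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    totals: dict[tuple[str, str], float] = {}
    for (comp, path), grp in steps.groupby(["compound", "path"], sort=False):
        grp = grp.sort_values("step")
        chain = [PathwayStep(r.reactant, r.product, r.barrier)
                 for r in grp.itertuples()]
        totals[(comp, path)] = path_total(chain)
    ref_totals = {p: t for (c, p), t in totals.items() if c == reference}
    if not ref_totals:
        raise KeyError(f"reference compound {reference!r} not in table")
    rows = []
    for (comp, path), total in totals.items():
        rate = (np.nan if comp == reference
                else path_change_rate(total, ref_totals[path]))
        rows.append({"compound": comp, "path": path, "total": total,
                     "rate": rate})
    out = pd.DataFrame(rows)
    agg = (out.dropna(subset=["rate"]).groupby("compound")["rate"]
           .apply(lambda r: total_change_rate(r, aggregate=aggregate)))
    out["total_rate"] = out["compound"].map(agg)
    return out


def consistency_report(barrier_changes: pd.Series,
                       biodeg_changes: pd.Series) -> pd.DataFrame:
    """Pair barrier vs biodegradability change rates per derivative.

    Both series are indexed by derivative id (percent).  Reports whether the
    signs oppose (barrier down while biodegradability up, or vice versa),
    which is the mechanistic consistency check of the workflow.  Row order
    is by sorted id, so shuffled inputs give identical reports.
    """
    if set(barrier_changes.index) != set(biodeg_changes.index):
        raise KeyError("derivative ids of the two change-rate tables differ")
    ids = sorted(barrier_changes.index)
    df = pd.DataFrame({
        "barrier_change_pct": [barrier_changes[i] for i in ids],
        "biodeg_change_pct": [biodeg_changes[i] for i in ids],
    }, index=pd.Index(ids, name="id"))
    df["sign_opposed"] = np.sign(df.barrier_change_pct) * np.sign(
        df.biodeg_change_pct) < 0
    return df
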