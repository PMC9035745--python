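"""Incremental cost-effectiveness arithmetic.

ICER = ΔCost / ΔQALY between a comparator and a reference strategy, with
explicit dominance classification: a comparator that is cheaper and more
effective dominates; costlier and less effective is dominated. A negative
ratio is never interpretable on its own — here it always travels with its
quadrant label. Net monetary benefit (NMB = QALY x WTP − cost) gives the
decision-equivalent linear form used for acceptability curves, and the
efficiency frontier removes strictly and extendedly dominated strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def _cq(point) -> Tuple[float, float]:
    if isinstance(point, Mapping):
        return float(point["cost"]), float(point["qaly"])
    cost, qaly = point
    return float(cost), float(qaly)


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison of one comparator against a reference."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    ratio: Optional[float]  # raw ΔC/ΔQ whenever ΔQ != 0, sign included
    dominance: str  # 'none' | 'dominant' | 'dominated'
    label: str  # quadrant/edge label for reports
    nmb_at_wtp: float  # incremental NMB at the decision threshold
    cost_effective_at_wtp: bool
    equivalent: bool = False

    @property
    def icer(self) -> Optional[float]:
        """Numeric ICER only when the comparison is a genuine trade-off."""
        if self.dominance != "none" or self.ratio is None:
            return None
        return self.ratio


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = qaly x wtp − cost."""
    return qaly * wtp - cost


def icer(reference, comparator, wtp: float, reference_name: str = "reference",
         comparator_name: str = "comparator") -> CEAResult:
    """Classify a pairwise comparison and compute its ICER/NMB.

    ``reference`` and ``comparator`` are ``{cost, qaly}`` mappings or
    ``(cost, qaly)`` pairs. ΔQ = 0 with ΔC != 0 leaves the ICER undefined
    and decides by cost sign; the south-west quadrant (cheaper, less
    effective) is judged by incremental NMB.
    """
    ref_c, ref_q = _cq(reference)
    com_c, com_q = _cq(comparator)
    if not all(isfinite(x) for x in (ref_c, ref_q, com_c, com_q)):
        raise ValueError("costs and QALYs must be finite")
    dc = com_c - ref_c
    dq = com_q - ref_q
    inmb = dq * wtp - dc
    ratio = dc / dq if dq != 0 else None

    if dc == 0 and dq == 0:
        return CEAResult(reference_name, comparator_name, dc, dq, None, "none",
                         "equivalent", inmb, False, equivalent=True)
    if dq == 0:
        return CEAResult(reference_name, comparator_name, dc, dq, None, "none",
                         "equal_effect", inmb, dc < 0)
    if dc < 0 and dq > 0:
        return CEAResult(reference_name, comparator_name, dc, dq, ratio, "dominant",
                         "dominant", inmb, True)
    if dc > 0 and dq < 0:
        return CEAResult(reference_name, comparator_name, dc, dq, ratio, "dominated",
                         "dominated", inmb, False)
    if dc <= 0 and dq < 0:
        return CEAResult(reference_name, comparator_name, dc, dq, ratio, "none",
                         "south_west", inmb, inmb > 0)
    # north-east (dc >= 0, dq > 0): the ordinary trade-off quadrant
    return CEAResult(reference_name, comparator_name, dc, dq, ratio, "none",
                     "north_east", inmb, ratio <= wtp)


def efficiency_frontier(
    strategies: Mapping[str, Tuple[float, float]] | Sequence[Tuple[float, float]],
) -> pd.DataFrame:
    """Efficiency frontier with sequential ICERs.

    ``strategies`` maps name -> (cost, qaly) (or is a plain sequence of
    (cost, qaly) pairs, auto-named). Strictly dominated strategies (another
    one is at least as effective and no costlier, with one strict
    inequality) are removed first, then extendedly dominated ones (their
    sequential ICER exceeds that of the next frontier step). Exact duplicate
    points keep the first name, flagged in the ``note`` column.
    """
    if not isinstance(strategies, Mapping):
        strategies = {f"s{i}": cq for i, cq in enumerate(strategies)}
    if len(strategies) < 2:
        raise ValueError("need at least two strategies")

    items = [(name, float(c), float(q)) for name, (c, q) in strategies.items()]
    status: Dict[str, str] = {name: "frontier" for name, _, _ in items}
    note: Dict[str, str] = {name: "" for name, _, _ in items}

    # Duplicates: keep first encountered.
    seen: Dict[Tuple[float, float], str] = {}
    for name, c, q in items:
        if (c, q) in seen:
            status[name] = "duplicate"
            note[name] = f"tie with {seen[(c, q)]}"
        else:
            seen[(c, q)] = name

    live = [(n, c, q) for n, c, q in items if status[n] == "frontier"]
    for n, c, q in live:
        for n2, c2, q2 in live:
            if n2 != n and c2 <= c and q2 >= q and (c2 < c or q2 > q):
                status[n] = "dominated"
                note[n] = f"strictly dominated by {n2}"
                break

    candidates = sorted(
        [(n, c, q) for n, c, q in live if status[n] == "frontier"],
        key=lambda t: (t[1], -t[2]),
    )
    frontier: List[Tuple[str, float, float]] = []
    for n, c, q in candidates:
        while frontier:
            if q <= frontier[-1][2]:
                # same-cost tie already handled by strict dominance; defensive
                status[n] = "dominated"
                note[n] = f"strictly dominated by {frontier[-1][0]}"
                break
            if len(frontier) >= 2:
                n1, c1, q1 = frontier[-2]
                n2, c2, q2 = frontier[-1]
                icer_prev = (c2 - c1) / (q2 - q1)
                icer_new = (c - c2) / (q - q2)
                if icer_new < icer_prev:
                    status[n2] = "extended"
                    note[n2] = f"extendedly dominated between {n1} and {n}"
                    frontier.pop()
                    continue
            break
        if status[n] == "frontier":
            frontier.append((n, c, q))

    seq_icer = {frontier[0][0]: np.nan}
    for (n1, c1, q1), (n2, c2, q2) in zip(frontier, frontier[1:]):
        seq_icer[n2] = (c2 - c1) / (q2 - q1)

    rows = []
    for name, c, q in items:
        rows.append(
            {
                "strategy": name,
                "cost": c,
                "qaly": q,
                "on_frontier": status[name] == "frontier",
                "status": status[name],
                "sequential_icer": seq_icer.get(name, np.nan),
                "note": note[name],
            }
        )
    return pd.DataFrame(rows)
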