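"""Deterministic and probabilistic sensitivity analysis.

Probabilities (case fatality, incidence) draw from Beta distributions —
Jeffreys-count form (events + 0.5, n − events + 0.5) when counts are
available, otherwise moment-fit from (mean, CV). Costs and treatment-state
utilities draw from moment-fit Gamma distributions (shape = 1/CV²,
scale = mean·CV²), with treatment-state utility draws capped at 1.0. Each
PSA iteration redraws every parameter once and runs all strategies on those
common draws, so pairwise comparisons are correlated exactly as a trial on
a shared parameter set would be; iterations whose event probabilities sum
above 1 for any drug are rejected and redrawn (counted).

The one-way deterministic analysis re-runs the base case at each
parameter's low/high bound (default: the central 95% interval of its PSA
distribution; ±25% for fixed parameters) and reports the induced ICER (and
incremental-NMB) range per comparator, sorted for a tornado diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cea import icer
from .codes import EVENTS
from .markov import ModelSettings, run_strategy
from .params import ModelParameters

logger = logging.getLogger(__name__)

DEFAULT_COST_CV = 0.2
DEFAULT_EVENT_UTILITY_CV = 0.2
#: Treatment-state utilities sit near the ceiling of the utility scale with
#: published spreads of ~0.01; a small CV keeps draws inside a plausible
#: range (the 1.0 cap still applies and cap hits are logged).
DEFAULT_DRUG_UTILITY_CV = 0.005


class DistributionError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: family, parameterization, DSA bounds."""

    name: str
    family: str  # 'beta' | 'gamma' | 'fixed'
    value: float  # base-case value
    mean: Optional[float] = None
    cv: Optional[float] = None
    events: Optional[float] = None
    n: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    cap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise DistributionError(f"unknown family {self.family!r} for {self.name}")
        if self.family == "fixed":
            return
        if self.family == "beta" and self.events is not None:
            if self.n is None or self.n <= 0 or not 0 <= self.events <= self.n:
                raise DistributionError(f"invalid beta counts for {self.name}")
            return
        if self.mean is None or self.cv is None:
            raise DistributionError(f"{self.name}: moment fit needs mean and cv")
        if self.cv <= 0:
            raise DistributionError(f"{self.name}: cv must be positive")
        if self.family == "beta" and not 0 < self.mean < 1:
            raise DistributionError(f"{self.name}: beta mean must lie in (0, 1)")
        if self.family == "gamma" and self.mean <= 0:
            raise DistributionError(f"{self.name}: gamma mean must be positive")

    def _shape_params(self) -> Tuple[float, float]:
        """(a, b) for beta; (shape, scale) for gamma."""
        if self.family == "beta":
            if self.events is not None:
                return self.events + 0.5, self.n - self.events + 0.5
            var = (self.mean * self.cv) ** 2
            common = self.mean * (1 - self.mean) / var - 1.0
            if common <= 0:
                raise DistributionError(f"{self.name}: beta CV too large for moment fit")
            return self.mean * common, (1 - self.mean) * common
        if self.family == "gamma":
            return 1.0 / self.cv**2, self.mean * self.cv**2
        raise DistributionError("fixed parameters have no distribution")

    def _frozen(self):
        a, b = self._shape_params()
        return stats.beta(a, b) if self.family == "beta" else stats.gamma(a, scale=b)

    def draw(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.family == "fixed":
            return self.value if size is None else np.full(size, self.value)
        a, b = self._shape_params()
        n = 1 if size is None else size
        sample = rng.beta(a, b, size=n) if self.family == "beta" else rng.gamma(a, b, size=n)
        if self.cap is not None:
            capped = sample > self.cap
            if np.any(capped):
                logger.debug("%s: %d draw(s) capped at %s", self.name, int(np.sum(capped)), self.cap)
            sample = np.minimum(sample, self.cap)
        return float(sample[0]) if size is None else sample

    def analytic_mean(self) -> float:
        if self.family == "fixed":
            return self.value
        return float(self._frozen().mean())

    def interval(self, level: float = 0.95) -> Tuple[float, float]:
        """Central interval for one-way bounds; fixed parameters get ±25%."""
        if self.family == "fixed":
            if self.low is not None and self.high is not None:
                return self.low, self.high
            span = abs(self.value) * 0.25
            return self.value - span, self.value + span
        if self.low is not None and self.high is not None:
            return self.low, self.high
        lo, hi = self._frozen().interval(level)
        if self.cap is not None:
            lo, hi = min(lo, self.cap), min(hi, self.cap)
        return float(lo), float(hi)


def build_distributions(
    mp: ModelParameters,
    cost_cv: float = DEFAULT_COST_CV,
    event_utility_cv: float = DEFAULT_EVENT_UTILITY_CV,
    drug_utility_cv: float = DEFAULT_DRUG_UTILITY_CV,
) -> List[ParameterDistribution]:
    """PSA distributions for every uncertain model parameter.

    Fatality and incidence use Beta (count-based where counts exist),
    event-state utilities Beta (moment fit), costs and treatment-state
    utilities Gamma (moment fit, utilities capped at 1).
    """
    dists: List[ParameterDistribution] = []
    for e in EVENTS:
        f = mp.fatality[e]
        counts = (mp.fatality_counts or {}).get(e)
        if counts is not None:
            d, n = counts
            dists.append(ParameterDistribution(f"fatality:{e}", "beta", f, events=d, n=n))
        elif f > 0:
            dists.append(ParameterDistribution(f"fatality:{e}", "beta", f, mean=f, cv=event_utility_cv))
        else:
            dists.append(ParameterDistribution(f"fatality:{e}", "fixed", f, low=0.0, high=0.0))
    for (drug, e), p in mp.incidence.items():
        name = f"incidence:{drug}:{e}"
        counts = (mp.incidence_counts or {}).get((drug, e))
        if counts is not None and counts[1] > 0:
            k, n = counts
            dists.append(ParameterDistribution(name, "beta", p, events=k, n=n))
        elif 0 < p < 1:
            dists.append(ParameterDistribution(name, "beta", p, mean=p, cv=event_utility_cv))
        else:
            dists.append(ParameterDistribution(name, "fixed", p, low=p, high=p))
    for drug, u in mp.drug_utilities.items():
        dists.append(
            ParameterDistribution(f"drug_utility:{drug}", "gamma", u, mean=u, cv=drug_utility_cv, cap=1.0)
        )
    for e, u in mp.event_utilities.items():
        dists.append(ParameterDistribution(f"event_utility:{e}", "beta", u, mean=u, cv=event_utility_cv))
    for drug, c in mp.medication_costs.items():
        dists.append(ParameterDistribution(f"med_cost:{drug}", "gamma", c, mean=c, cv=cost_cv))
    for e, c in mp.event_costs.items():
        dists.append(ParameterDistribution(f"event_cost:{e}", "gamma", c, mean=c, cv=cost_cv))
    for e, c in mp.post_event_costs.items():
        if c > 0:
            dists.append(ParameterDistribution(f"post_cost:{e}", "gamma", c, mean=c, cv=cost_cv))
    return dists


def draw_parameters(
    distributions: Iterable[ParameterDistribution], rng: np.random.Generator
) -> Dict[str, float]:
    """One joint draw of all parameters (common across strategies)."""
    return {d.name: d.draw(rng) for d in distributions}


def _event_prob_sums(mp: ModelParameters) -> Dict[str, float]:
    sums: Dict[str, float] = {}
    for (drug, _), p in mp.incidence.items():
        sums[drug] = sums.get(drug, 0.0) + p
    return sums


@dataclass
class PSAResult:
    """Iteration-level PSA outputs plus Table-style summary statistics."""

    iterations: pd.DataFrame  # iteration, strategy, cost, qaly
    summary: pd.DataFrame
    n_iterations: int
    rejected_draws: int
    reference: str
    wtp: float

    def probability_cost_effective(self, wtp: Optional[float] = None) -> pd.Series:
        """Pairwise P(comparator beats reference on NMB) at the WTP."""
        wtp = self.wtp if wtp is None else wtp
        wide_c = self.iterations.pivot(index="iteration", columns="strategy", values="cost")
        wide_q = self.iterations.pivot(index="iteration", columns="strategy", values="qaly")
        nmb = wide_q * wtp - wide_c
        ref = nmb[self.reference]
        out = {}
        for s in nmb.columns:
            if s == self.reference:
                continue
            diff = nmb[s] - ref
            out[s] = float((diff > 0).mean() + 0.5 * (diff == 0).mean())
        return pd.Series(out, name="p_cost_effective")


def _summarize(iterations: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (strategy, measure), values in (
        iterations.melt(
            id_vars=["iteration", "strategy"],
            value_vars=["cost", "qaly"],
            var_name="measure",
        )
        .groupby(["strategy", "measure"])["value"]
    ):
        v = values.to_numpy()
        rows.append(
            {
                "strategy": strategy,
                "measure": measure,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "median": float(np.median(v)),
                "min": v.min(),
                "max": v.max(),
                "sum": v.sum(),
                "size": len(v),
                "variance": v.var(ddof=1) if len(v) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_psa(
    mp: ModelParameters,
    distributions: Optional[Sequence[ParameterDistribution]] = None,
    n_iter: int = 10_000,
    seed: int = 0,
    max_rejections: int = 1_000_000,
) -> PSAResult:
    """Monte Carlo PSA with common random parameter draws across strategies."""
    distributions = list(distributions) if distributions is not None else build_distributions(mp)
    rng = np.random.default_rng(seed)
    drugs = mp.drugs
    records: List[dict] = []
    rejected = 0
    for it in range(n_iter):
        while True:
            draws = draw_parameters(distributions, rng)
            candidate = mp.with_values(draws)
            if all(s <= 1.0 for s in _event_prob_sums(candidate).values()):
                break
            rejected += 1
            if rejected > max_rejections:
                raise RuntimeError("PSA rejected too many draws; check incidence inputs")
        for drug in drugs:
            trace = run_strategy(candidate.strategy(drug), mp.settings)
            records.append(
                {"iteration": it, "strategy": drug, "cost": trace.total_cost, "qaly": trace.total_qaly}
            )
    iterations = pd.DataFrame(records)
    if rejected:
        logger.info("PSA rejected and redrew %d parameter sets", rejected)
    return PSAResult(
        iterations=iterations,
        summary=_summarize(iterations),
        n_iterations=n_iter,
        rejected_draws=rejected,
        reference=mp.reference,
        wtp=mp.settings.wtp,
    )


def default_wtp_grid(maximum: float = 100_000.0, step: float = 1_000.0, always: float = 32_000.0) -> np.ndarray:
    grid = np.arange(0.0, maximum + step / 2, step)
    if always not in grid:
        grid = np.sort(np.append(grid, always))
    return grid


def ceac(
    iterations: pd.DataFrame,
    wtp_grid: Optional[Sequence[float]] = None,
    reference: str = "warfarin",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA iterations.

    Per WTP point and strategy: the pairwise probability of a higher NMB
    than the reference (ties split evenly) and the multi-way probability of
    having the maximum NMB (ties split evenly; these sum to 1 per point).
    """
    if not len(iterations):
        raise ValueError("iteration table is empty")
    wtp_grid = np.asarray(wtp_grid if wtp_grid is not None else default_wtp_grid(), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid is empty")
    cost = iterations.pivot(index="iteration", columns="strategy", values="cost")
    qaly = iterations.pivot(index="iteration", columns="strategy", values="qaly")
    strategies = list(cost.columns)
    if reference not in strategies:
        raise ValueError(f"reference {reference!r} not among strategies")
    c = cost.to_numpy()
    q = qaly.to_numpy()
    ref_i = strategies.index(reference)
    rows = []
    for w in wtp_grid:
        nmb = q * w - c
        best = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = is_best / is_best.sum(axis=1, keepdims=True)
        diff = nmb - nmb[:, [ref_i]]
        for j, s in enumerate(strategies):
            pairwise = np.nan
            if j != ref_i:
                pairwise = float((diff[:, j] > 0).mean() + 0.5 * (diff[:, j] == 0).mean())
            rows.append(
                {
                    "wtp": float(w),
                    "strategy": s,
                    "p_cost_effective_vs_reference": pairwise,
                    "p_optimal": float(share[:, j].mean()),
                }
            )
    return pd.DataFrame(rows)


def one_way_dsa(
    mp: ModelParameters,
    distributions: Optional[Sequence[ParameterDistribution]] = None,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity (tornado) analysis.

    For every parameter, re-runs the model at its low and high bound with
    everything else at base case and records, per comparator strategy, the
    ICER vs the reference and the incremental NMB at the WTP. The frame is
    sorted per comparator by descending ICER range (NMB range breaks ties
    and covers dominance flips, where the ICER is undefined at an endpoint).
    """
    distributions = list(distributions) if distributions is not None else build_distributions(mp)
    reference = reference or mp.reference
    settings = mp.settings
    drugs = mp.drugs
    comparators = [d for d in drugs if d != reference]

    def outcomes(params: ModelParameters) -> Dict[str, Tuple[float, float]]:
        return {
            d: (lambda t: (t.total_cost, t.total_qaly))(run_strategy(params.strategy(d), settings))
            for d in drugs
        }

    base = outcomes(mp)
    rows = []
    for dist in distributions:
        lo, hi = dist.interval()
        results = {}
        for bound_name, bound in (("low", lo), ("high", hi)):
            if bound == dist.value:
                results[bound_name] = base
            else:
                results[bound_name] = outcomes(mp.with_values({dist.name: bound}))
        for comp in comparators:
            rec = {"parameter": dist.name, "comparator": comp, "low": lo, "high": hi}
            for bound_name in ("low", "high"):
                ref_c, ref_q = results[bound_name][reference]
                com_c, com_q = results[bound_name][comp]
                res = icer((ref_c, ref_q), (com_c, com_q), settings.wtp)
                rec[f"icer_{bound_name}"] = res.ratio if res.dominance == "none" else np.nan
                rec[f"inmb_{bound_name}"] = res.nmb_at_wtp
                rec[f"dominance_{bound_name}"] = res.label
            rec["icer_range"] = (
                abs(rec["icer_high"] - rec["icer_low"])
                if np.isfinite(rec["icer_low"]) and np.isfinite(rec["icer_high"])
                else np.nan
            )
            rec["inmb_range"] = abs(rec["inmb_high"] - rec["inmb_low"])
            rows.append(rec)
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["comparator", "icer_range", "inmb_range"],
        ascending=[True, False, False],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return frame


def scatter_table(psa: PSAResult) -> pd.DataFrame:
    """Incremental cost vs incremental QALY per iteration and comparator."""
    cost = psa.iterations.pivot(index="iteration", columns="strategy", values="cost")
    qaly = psa.iterations.pivot(index="iteration", columns="strategy", values="qaly")
    rows = []
    for s in cost.columns:
        if s == psa.reference:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "iteration": cost.index,
                    "comparator": s,
                    "incremental_cost": cost[s] - cost[psa.reference],
                    "incremental_qaly": qaly[s] - qaly[psa.reference],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
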