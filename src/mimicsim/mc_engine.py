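"""Monte-Carlo engine: replications, the factorial grid, and aggregate contrasts.

Power of the MIMIC Wald test is the fraction of replications in which the true
DIF item is flagged; the Type I error rate is the mean flagging rate over the
DIF-free items.  A replication whose fits do not all converge properly is
redrawn from the next child seed up to a retry budget; item fits that are
still improper after the retries are excluded from both the numerator and the
denominator of the corresponding rate.

The full factorial grid crosses 5 sample-size ratios x 2 DIF magnitudes x
2 scale lengths x 3 category counts x 13 trait-distribution conditions
(780 scenarios).  Per-scenario seeds are derived deterministically from one
base seed, so any subset rerun reproduces identical rows, serial or parallel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dif_pipeline import DifDecision, evaluate_dataset
from .synthetic_data import (
    DISTRIBUTION_CONDITIONS,
    Scenario,
    distribution_class,
    generate_dataset,
    replication_rng,
)

__all__ = [
    "ScenarioResult",
    "DEFAULT_RATIOS",
    "DEFAULT_DELTAS",
    "DEFAULT_SCALE_LENGTHS",
    "DEFAULT_CATEGORY_COUNTS",
    "run_scenario",
    "enumerate_scenarios",
    "scenario_seed",
    "run_grid",
    "aggregate_contrast",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_RATIOS: tuple[tuple[int, int], ...] = (
    (100, 100),
    (200, 100),
    (300, 100),
    (400, 100),
    (500, 100),
)
DEFAULT_DELTAS: tuple[float, ...] = (0.5, 1.0)
DEFAULT_SCALE_LENGTHS: tuple[int, ...] = (5, 10)
DEFAULT_CATEGORY_COUNTS: tuple[int, ...] = (3, 5, 7)

_INDEX_NAMES = ("rmsea", "rmr", "tli", "cfi", "gfi")

RESULT_COLUMNS = [
    "n_ref",
    "n_focal",
    "delta",
    "n_items",
    "n_categories",
    "condition_id",
    "reps",
    "n_converged",
    "n_retries",
    "power",
    "type1_error",
] + [f"mean_{name}" for name in _INDEX_NAMES]


@dataclass
class ScenarioResult:
    """Power / Type I error estimates for one scenario across replications."""

    scenario: Scenario
    n_reps_requested: int
    n_converged: int
    power: float
    type1_error: float
    mean_fit_indices: dict = field(default_factory=dict)
    n_retries: int = 0

    def to_row(self) -> dict:
        s = self.scenario
        row = {
            "n_ref": s.n_ref,
            "n_focal": s.n_focal,
            "delta": s.dif_magnitude,
            "n_items": s.n_items,
            "n_categories": s.n_categories,
            "condition_id": s.condition_id,
            "reps": self.n_reps_requested,
            "n_converged": self.n_converged,
            "n_retries": self.n_retries,
            "power": self.power,
            "type1_error": self.type1_error,
        }
        for name in _INDEX_NAMES:
            row[f"mean_{name}"] = self.mean_fit_indices.get(name, np.nan)
        return row


def _proper(d: DifDecision) -> bool:
    return d.converged and not d.heywood


def run_scenario(
    scenario: Scenario,
    n_reps: int,
    alpha: float = 0.05,
    retry_budget: int = 5,
    power_only: bool = False,
    alpha_item_policy: str = "all_dif_free",
    fixed_bank: bool = False,
) -> ScenarioResult:
    """Estimate power and Type I error for one scenario.

    Each replication generates a fresh dataset (new item bank unless
    ``fixed_bank``) and tests items one at a time.  ``power_only`` restricts
    testing to the studied item, which is much cheaper when only power is
    needed.  ``alpha_item_policy`` chooses whether the Type I error averages
    over all DIF-free items (default) or only the first anchor item
    (``"first_anchor_only"``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if alpha_item_policy not in ("all_dif_free", "first_anchor_only"):
        raise ValueError(f"unknown alpha_item_policy {alpha_item_policy!r}")
    studied = scenario.studied_item
    if power_only:
        items = [studied]
    elif alpha_item_policy == "first_anchor_only":
        first_anchor = next(i for i in range(scenario.n_items) if i != studied)
        items = [studied, first_anchor]
    else:
        items = list(range(scenario.n_items))

    bank = None
    if fixed_bank:
        bank = generate_dataset(scenario, replication_rng(scenario.seed, 0, 0)).item_bank

    power_num = power_den = 0
    fp_num = fp_den = 0
    n_converged = 0
    n_retries = 0
    index_sums = dict.fromkeys(_INDEX_NAMES, 0.0)
    index_count = 0

    for r in range(n_reps):
        decisions: list[DifDecision] = []
        for attempt in range(retry_budget + 1):
            rng = replication_rng(scenario.seed, r, attempt)
            data = generate_dataset(scenario, rng, bank=bank)
            decisions = evaluate_dataset(data, alpha, items=items)
            if all(_proper(d) for d in decisions):
                break
            n_retries += 1
        for d in decisions:
            if not _proper(d):
                continue
            if d.item == studied:
                power_den += 1
                power_num += d.rejected
            else:
                fp_den += 1
                fp_num += d.rejected
        studied_dec = next(d for d in decisions if d.item == studied)
        if _proper(studied_dec):
            n_converged += 1
            if studied_dec.fit is not None:
                for name in _INDEX_NAMES:
                    index_sums[name] += studied_dec.fit.fit_indices[name]
                index_count += 1

    if power_den == 0:
        logger.warning("scenario %s: no converged replications", scenario)
        power = np.nan
    else:
        power = power_num / power_den
    type1 = fp_num / fp_den if fp_den else np.nan
    mean_idx = (
        {name: index_sums[name] / index_count for name in _INDEX_NAMES}
        if index_count
        else {}
    )
    return ScenarioResult(
        scenario=scenario,
        n_reps_requested=n_reps,
        n_converged=n_converged,
        power=float(power),
        type1_error=float(type1),
        mean_fit_indices=mean_idx,
        n_retries=n_retries,
    )


def scenario_seed(
    base_seed: int,
    n_ref: int,
    n_focal: int,
    delta: float,
    n_items: int,
    n_categories: int,
    condition_id: int,
) -> int:
    """Deterministic per-scenario seed below 2**31.

    Keyed to the scenario's identity (not its position in a grid), so a subset
    rerun of any factor combination reproduces the identical result row.
    """
    key = (n_ref, n_focal, int(round(delta * 1000)), n_items, n_categories, condition_id)
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def enumerate_scenarios(
    base_seed: int,
    ratios=DEFAULT_RATIOS,
    deltas=DEFAULT_DELTAS,
    scale_lengths=DEFAULT_SCALE_LENGTHS,
    category_counts=DEFAULT_CATEGORY_COUNTS,
    conditions=tuple(DISTRIBUTION_CONDITIONS),
) -> list[Scenario]:
    """Enumerate the factorial grid in a fixed deterministic order."""
    scenarios = []
    for ratio, delta, k, J, cond in itertools.product(
        ratios, deltas, scale_lengths, category_counts, conditions
    ):
        scenarios.append(
            Scenario(
                n_ref=ratio[0],
                n_focal=ratio[1],
                dif_magnitude=delta,
                n_items=k,
                n_categories=J,
                condition_id=cond,
                seed=scenario_seed(base_seed, ratio[0], ratio[1], delta, k, J, cond),
            )
        )
    return scenarios


def run_grid(
    scenarios: list[Scenario],
    n_reps: int,
    alpha: float = 0.05,
    retry_budget: int = 5,
    power_only: bool = False,
    alpha_item_policy: str = "all_dif_free",
    n_jobs: int = 1,
    out: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario and return one results row per scenario.

    Per-scenario RNG streams are independent of worker scheduling, so serial
    and parallel runs agree exactly.  When ``out`` is given, rows are appended
    to a CSV as scenarios complete (serial runs only) so partial results
    survive interruption.
    """

    def one(s: Scenario) -> dict:
        res = run_scenario(
            s,
            n_reps,
            alpha=alpha,
            retry_budget=retry_budget,
            power_only=power_only,
            alpha_item_policy=alpha_item_policy,
        )
        if progress:
            logger.info(
                "scenario %s delta=%s k=%s J=%s cond=%s: power=%.3f alpha=%.3f "
                "(converged %d/%d, retries %d)",
                s.ratio_label,
                s.dif_magnitude,
                s.n_items,
                s.n_categories,
                s.condition_id,
                res.power,
                res.type1_error,
                res.n_converged,
                n_reps,
                res.n_retries,
            )
        return res.to_row()

    if n_jobs == 1:
        rows = []
        for s in scenarios:
            row = one(s)
            rows.append(row)
            if out is not None:
                header = len(rows) == 1
                pd.DataFrame([row]).to_csv(out, mode="w" if header else "a",
                                           header=header, index=False)
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in scenarios)
        if out is not None:
            pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(out, index=False)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


_FACTOR_KEYS = {
    "distribution_class": lambda df: df["condition_id"].map(distribution_class),
    "delta": lambda df: df["delta"],
    "n_items": lambda df: df["n_items"],
    "n_categories": lambda df: df["n_categories"],
    "ratio": lambda df: "R" + df["n_ref"].astype(str) + "/F" + df["n_focal"].astype(str),
}

_CLASS_ORDER = ["normal", "moderate", "high"]


@dataclass
class ContrastTable:
    """Per-level means of power / Type I error plus pairwise differences."""

    factor: str
    means: pd.DataFrame
    pairwise_pp: pd.DataFrame


def aggregate_contrast(results: pd.DataFrame, factor: str) -> ContrastTable:
    """Unweighted scenario-mean power and Type I error by one design factor.

    ``distribution_class`` groups trait conditions into normal (condition 13),
    moderately skewed (1, 3, 5, 7, 9, 11), and highly skewed (2, 4, 6, 8, 10,
    12).  Pairwise level differences are reported in percentage points.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    if factor not in _FACTOR_KEYS:
        raise ValueError(f"unknown factor {factor!r}; one of {sorted(_FACTOR_KEYS)}")
    key = _FACTOR_KEYS[factor](results)
    grouped = results.groupby(key, sort=True).agg(
        mean_power=("power", "mean"),
        mean_type1_error=("type1_error", "mean"),
        n_scenarios=("power", "size"),
    )
    if factor == "distribution_class":
        order = [lvl for lvl in _CLASS_ORDER if lvl in grouped.index]
        grouped = grouped.loc[order]
    grouped.index.name = factor
    levels = list(grouped.index)
    pairs = []
    for a, b in itertools.combinations(levels, 2):
        pairs.append(
            {
                "level_a": a,
                "level_b": b,
                "power_diff_pp": 100.0 * (grouped.loc[a, "mean_power"] - grouped.loc[b, "mean_power"]),
                "type1_diff_pp": 100.0
                * (grouped.loc[a, "mean_type1_error"] - grouped.loc[b, "mean_type1_error"]),
            }
        )
    return ContrastTable(factor=factor, means=grouped, pairwise_pp=pd.DataFrame(pairs))
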