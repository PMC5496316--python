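"""Two-group ordinal questionnaire data simulated from the graded response model.

A k-item scale with J ordered response categories is generated from Samejima's
graded response model (GRM).  For item ``i`` with discrimination ``a_i`` and
ascending thresholds ``b_i1 < ... < b_i,J-1``, the probability of responding in
category ``j`` *or above* at latent-trait level ``theta`` is the two-parameter
logistic

    P*_ij(theta) = expit(a_i * (theta - b_ij)),

and category probabilities are adjacent differences of the cumulative curve.

Two groups are simulated: a *reference* group (coded 0) and a typically smaller
*focal* group (coded 1).  Uniform differential item functioning (DIF) is
injected by adding a constant shift to every threshold of one studied item in
the focal group only, which lowers that item's expected score for the focal
group at every trait level.  Latent traits are drawn either from N(0, 1) or
from a Beta distribution standardized analytically to mean 0 and variance 1,
so skewed-trait groups differ from normal ones in shape but not in location or
scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "LatentTraitSpec",
    "ItemBank",
    "Scenario",
    "Dataset",
    "NORMAL_TRAIT",
    "DISTRIBUTION_CONDITIONS",
    "distribution_class",
    "standardized_beta_params",
    "sample_latent",
    "draw_item_bank",
    "apply_uniform_dif",
    "grm_category_probs",
    "generate_dataset",
    "replication_rng",
]


@dataclass(frozen=True)
class LatentTraitSpec:
    """Distribution of the latent trait for one group.

    ``family`` is ``"normal"`` (standard normal) or ``"beta"``.  Beta draws are
    always standardized with the analytic Beta moments so the population mean
    is exactly 0 and the population variance exactly 1; only the shape
    (skewness, kurtosis) distinguishes them from N(0, 1).
    """

    family: str
    shape1: float = float("nan")
    shape2: float = float("nan")
    standardized: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("normal", "beta"):
            raise ValueError(f"unknown trait family {self.family!r}")
        if self.family == "beta":
            if not (self.shape1 > 0 and self.shape2 > 0):
                raise ValueError("beta shape parameters must be positive")
            if not self.standardized:
                raise ValueError("beta traits are always standardized")

    @property
    def skewness(self) -> float:
        """Population skewness (0 for normal; closed form for Beta)."""
        if self.family == "normal":
            return 0.0
        a, b = self.shape1, self.shape2
        return 2.0 * (b - a) * np.sqrt(a + b + 1.0) / ((a + b + 2.0) * np.sqrt(a * b))


NORMAL_TRAIT = LatentTraitSpec("normal")


def _beta(a: float, b: float) -> LatentTraitSpec:
    return LatentTraitSpec("beta", a, b)


#: Condition id -> (reference-group trait, focal-group trait).  Conditions 1-4
#: pair a normal reference with a skewed focal group, 5-8 use the same skewed
#: distribution in both groups, 9-12 use opposite skew directions, and 13 is
#: the all-normal benchmark.
DISTRIBUTION_CONDITIONS: dict[int, tuple[LatentTraitSpec, LatentTraitSpec]] = {
    1: (NORMAL_TRAIT, _beta(1, 4)),
    2: (NORMAL_TRAIT, _beta(0.5, 4)),
    3: (NORMAL_TRAIT, _beta(4, 1)),
    4: (NORMAL_TRAIT, _beta(4, 0.5)),
    5: (_beta(1, 4), _beta(1, 4)),
    6: (_beta(0.5, 4), _beta(0.5, 4)),
    7: (_beta(4, 1), _beta(4, 1)),
    8: (_beta(4, 0.5), _beta(4, 0.5)),
    9: (_beta(1, 4), _beta(4, 1)),
    10: (_beta(0.5, 4), _beta(4, 0.5)),
    11: (_beta(4, 1), _beta(1, 4)),
    12: (_beta(4, 0.5), _beta(0.5, 4)),
    13: (NORMAL_TRAIT, NORMAL_TRAIT),
}


def distribution_class(condition_id: int) -> str:
    """Classify a distribution condition by the skewness severity involved.

    ``"normal"`` for the all-normal condition, ``"moderate"`` when the skewed
    shapes are Beta(1,4)/Beta(4,1), ``"high"`` for Beta(0.5,4)/Beta(4,0.5).
    """
    if condition_id == 13:
        return "normal"
    if condition_id in (1, 3, 5, 7, 9, 11):
        return "moderate"
    if condition_id in (2, 4, 6, 8, 10, 12):
        return "high"
    raise ValueError(f"unknown condition id {condition_id}")


def standardized_beta_params(shape1: float, shape2: float) -> tuple[float, float]:
    """Analytic mean and sd of Beta(shape1, shape2), used to standardize draws.

    Returns ``(mean, sd)`` with mean = a/(a+b) and
    sd = sqrt(ab / ((a+b)^2 (a+b+1))); a raw draw x is mapped to
    ``(x - mean) / sd`` so the standardized variable has population mean 0 and
    variance 1 exactly.
    """
    if not (shape1 > 0 and shape2 > 0):
        raise ValueError("beta shape parameters must be positive")
    s = shape1 + shape2
    mean = shape1 / s
    var = shape1 * shape2 / (s * s * (s + 1.0))
    return mean, float(np.sqrt(var))


def sample_latent(spec: LatentTraitSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` latent-trait values under ``spec`` (population mean 0, var 1)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if spec.family == "normal":
        return rng.standard_normal(n)
    mean, sd = standardized_beta_params(spec.shape1, spec.shape2)
    return (rng.beta(spec.shape1, spec.shape2, size=n) - mean) / sd


@dataclass(frozen=True)
class ItemBank:
    """Per-item GRM parameters for a k-item, J-category scale.

    ``discriminations`` has shape (k,); ``thresholds`` has shape (k, J-1) with
    each row strictly ascending.
    """

    discriminations: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.discriminations, dtype=float)
        b = np.asarray(self.thresholds, dtype=float)
        if a.ndim != 1 or b.ndim != 2 or b.shape[0] != a.shape[0]:
            raise ValueError("discriminations (k,) and thresholds (k, J-1) required")
        if not np.all(a > 0):
            raise ValueError("discriminations must be positive")
        if b.shape[1] >= 2 and not np.all(np.diff(b, axis=1) > 0):
            raise ValueError("each item's thresholds must be strictly ascending")
        object.__setattr__(self, "discriminations", a)
        object.__setattr__(self, "thresholds", b)

    @property
    def n_items(self) -> int:
        return self.discriminations.shape[0]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1


def draw_item_bank(k: int, J: int, rng: np.random.Generator) -> ItemBank:
    """Draw a fresh bank: a_i ~ U(1.5, 2), thresholds i.i.d. N(0,1) sorted per item."""
    if k < 2:
        raise ValueError("at least 2 items required")
    if J < 2:
        raise ValueError("at least 2 response categories required")
    a = rng.uniform(1.5, 2.0, size=k)
    b = np.sort(rng.standard_normal((k, J - 1)), axis=1)
    return ItemBank(a, b)


def apply_uniform_dif(bank: ItemBank, item: int, delta: float) -> ItemBank:
    """Shift every threshold of ``item`` by ``delta`` (uniform DIF); others untouched.

    Negative ``delta`` is accepted so a shift can be undone; the cumulative
    shift is tracked against the unshifted base thresholds, so shifts that
    cancel restore the original bank bit-exactly.
    """
    if not 0 <= item < bank.n_items:
        raise IndexError(f"item index {item} out of range for {bank.n_items} items")
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    base = getattr(bank, "_base_thresholds", bank.thresholds)
    shifts = getattr(bank, "_shifts", np.zeros(bank.n_items)).copy()
    shifts[item] += delta
    b = base + shifts[:, None]
    b[shifts == 0] = base[shifts == 0]
    shifted = ItemBank(bank.discriminations.copy(), b)
    object.__setattr__(shifted, "_base_thresholds", base)
    object.__setattr__(shifted, "_shifts", shifts)
    return shifted


def grm_category_probs(theta, a: float, thresholds) -> np.ndarray:
    """Category probabilities of the GRM at trait level(s) ``theta``.

    Cumulative curves P*_j = expit(a (theta - b_j)) are differenced with the
    conventions P*_0 = 1 and P*_J = 0, giving a length-J probability vector
    (last axis) that is nonnegative and sums to 1.
    """
    b = np.asarray(thresholds, dtype=float)
    if b.ndim != 1:
        raise ValueError("thresholds must be a 1-d vector")
    if b.size >= 2 and not np.all(np.diff(b) > 0):
        raise ValueError("thresholds must be strictly ascending")
    th = np.asarray(theta, dtype=float)
    pstar = expit(a * (th[..., None] - b))
    probs = np.concatenate(
        [1.0 - pstar[..., :1], -np.diff(pstar, axis=-1), pstar[..., -1:]], axis=-1
    )
    return probs


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial simulation design."""

    n_ref: int
    n_focal: int
    dif_magnitude: float
    n_items: int
    n_categories: int
    condition_id: int
    studied_item: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ref < 1 or self.n_focal < 1:
            raise ValueError("group sizes must be positive")
        if self.dif_magnitude < 0:
            raise ValueError("dif_magnitude must be nonnegative")
        if self.n_items < 2 or self.n_categories < 2:
            raise ValueError("need at least 2 items and 2 categories")
        if self.condition_id not in DISTRIBUTION_CONDITIONS:
            raise ValueError(f"condition_id must be in 1..13, got {self.condition_id}")
        if not 0 <= self.studied_item < self.n_items:
            raise ValueError("studied_item out of range")

    @property
    def n_total(self) -> int:
        return self.n_ref + self.n_focal

    @property
    def ratio_label(self) -> str:
        return f"R{self.n_ref}/F{self.n_focal}"


@dataclass(frozen=True)
class Dataset:
    """A simulated two-group response matrix plus its generating truth.

    ``responses`` is (n, k) of integers 1..J; ``group`` is 0 for reference and
    1 for focal rows; ``true_dif_item`` is None when no DIF was injected.
    """

    responses: np.ndarray
    group: np.ndarray
    item_bank: ItemBank
    true_dif_item: int | None

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_categories(self) -> int:
        return self.item_bank.n_categories

    def to_frame(self):
        import pandas as pd

        k = self.n_items
        cols = {f"item_{i + 1}": self.responses[:, i] for i in range(k)}
        cols["group"] = self.group
        return pd.DataFrame(cols)


def _respond(theta: np.ndarray, bank: ItemBank, rng: np.random.Generator) -> np.ndarray:
    """Sample one response per (subject, item) from the GRM.

    A single uniform u per cell suffices: the response is
    1 + #{j : u < P*_j(theta)} because the cumulative curves are decreasing
    in j, so the events nest.
    """
    n, k = theta.shape[0], bank.n_items
    u = rng.random((n, k))
    out = np.empty((n, k), dtype=np.int64)
    for i in range(k):
        pstar = expit(bank.discriminations[i] * (theta[:, None] - bank.thresholds[i]))
        out[:, i] = 1 + (u[:, i, None] < pstar).sum(axis=1)
    return out


def generate_dataset(
    scenario: Scenario,
    rng: np.random.Generator | None = None,
    bank: ItemBank | None = None,
) -> Dataset:
    """Generate one replication's dataset for a scenario.

    Draws a fresh item bank (unless ``bank`` is supplied for fixed-bank
    sensitivity runs), latent traits for each group from the condition's trait
    specs, applies the uniform-DIF threshold shift to the studied item for the
    focal group only, and samples ordinal responses.  Reference rows come
    first, then focal rows; deterministic given ``rng`` (default: fresh
    generator seeded with ``scenario.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if bank is None:
        bank = draw_item_bank(scenario.n_items, scenario.n_categories, rng)
    ref_spec, focal_spec = DISTRIBUTION_CONDITIONS[scenario.condition_id]
    theta_ref = sample_latent(ref_spec, scenario.n_ref, rng)
    theta_focal = sample_latent(focal_spec, scenario.n_focal, rng)
    focal_bank = apply_uniform_dif(bank, scenario.studied_item, scenario.dif_magnitude)
    resp = np.vstack(
        [_respond(theta_ref, bank, rng), _respond(theta_focal, focal_bank, rng)]
    )
    grp = np.concatenate(
        [np.zeros(scenario.n_ref, dtype=np.int64), np.ones(scenario.n_focal, dtype=np.int64)]
    )
    dif_item = scenario.studied_item if scenario.dif_magnitude > 0 else None
    return Dataset(resp, grp, bank, dif_item)


def replication_rng(scenario_seed: int, replication: int, attempt: int = 0) -> np.random.Generator:
    """Deterministic child stream for one replication (and redraw attempt).

    Any replication is reproducible in isolation from the scenario seed alone;
    redraws after nonconvergence advance ``attempt``.
    """
    ss = np.random.SeedSequence(entropy=scenario_seed, spawn_key=(replication, attempt))
    return np.random.default_rng(ss)
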