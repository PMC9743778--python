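"""Synthetic microbiome count data with known differential-abundance truth.

The generator emulates the character of real 16S amplicon count tables:
per-taxon counts that are strongly overdispersed (sample variance far above
the mean) and zero-inflated, with heterogeneous per-sample library sizes.
The base table is drawn from a zero-inflated negative binomial with
taxon-specific mean, dispersion and zero probability sampled from configured
ranges, scaled by log-normal per-sample library-size factors.

Signal is then injected on top of the base table so the ground truth is known
exactly:

* *diet*: every sample is assigned one of four diet groups (meateater,
  fisheater, vegetarian, vegan) with equal probability; each group gets its
  own random 10% of taxa made differentially abundant in that group's
  samples.
* *count signal*: non-zero counts of an affected (taxon, sample) cell are
  multiplied by the effect size (e.g. 2.0 for +100%) and rounded
  half-to-even; zeros stay zero.
* *zero signal*: the taxon's baseline odds of a non-zero count are multiplied
  by the effect size for affected samples; zero/non-zero status is redrawn
  for every sample of the taxon, and non-zero draws take values sampled
  without replacement from the taxon's original non-zero counts -- the
  values are conserved and only shuffled, with surplus demand resolved to
  zeros once the pool depletes.
* *confounders* (optional): urbanization (low/high) correlated with diet per
  a fixed joint table, with its own 10% of taxa at +200% in the 'high'
  group; and age in [20, 69], decade drawn conditionally on diet and uniform
  within the decade, with a per-sample multiplier ramping linearly from +0%
  at age 20 to +400% at age 69 for its own 10% of taxa.

Library sizes are recomputed after injection, since they are by definition
the row sums of the final table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import CountTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "DIET_LEVELS",
    "URBANIZATION_GIVEN_DIET",
    "AGE_DECADE_GIVEN_DIET",
    "generate_base_counts",
    "assign_diet_groups",
    "assign_confounders",
    "select_da_taxa",
    "inject_count_signal",
    "inject_zero_signal",
    "inject_age_signal",
    "build_experiment",
]

DIET_LEVELS = ("meateater", "fisheater", "vegetarian", "vegan")

# P(urbanization = low | diet); the joint law with uniform 25% diet groups is
# meateater (20, 5), fisheater (15, 10), vegetarian (10, 15), vegan (5, 20)
# percent for (low, high).
URBANIZATION_GIVEN_DIET = {
    "meateater": 0.80,
    "fisheater": 0.60,
    "vegetarian": 0.40,
    "vegan": 0.20,
}

# P(age decade | diet), decades [20,30) ... [60,70); columns sum to 1.
AGE_DECADES = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70))
AGE_DECADE_GIVEN_DIET = {
    "meateater": (0.00, 0.10, 0.20, 0.30, 0.40),
    "fisheater": (0.10, 0.15, 0.20, 0.25, 0.30),
    "vegetarian": (0.30, 0.25, 0.20, 0.15, 0.10),
    "vegan": (0.40, 0.30, 0.20, 0.10, 0.00),
}

for _diet, _probs in AGE_DECADE_GIVEN_DIET.items():
    assert abs(sum(_probs) - 1.0) < 1e-12, f"age table column {_diet} != 100%"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror the real-data regime the simulation stands in for: 149
    persons x 531 taxa, 10% of taxa differentially abundant per factor, a
    +100% diet effect, +200% urbanization effect, and a 0-400% linear age
    ramp; per-taxon base parameters span means of roughly 1-100, negative
    binomial dispersions 0.1-2 and zero-inflation 0-0.6.
    """

    n_samples: int = 149
    n_taxa: int = 531
    da_fraction: float = 0.10
    diet_multiplier: float = 2.0          # +100%
    urbanization_multiplier: float = 3.0  # +200%
    age_max_increment: float = 4.0        # +400% at the top of the age range
    signal_mode: str = "counts"           # "counts" or "counts_and_zeros"
    confounded: bool = False
    mean_range: tuple[float, float] = (1.0, 100.0)
    dispersion_range: tuple[float, float] = (0.1, 2.0)
    zero_inflation_range: tuple[float, float] = (0.0, 0.6)
    libsize_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.da_fraction < 1.0):
            raise ValueError("da_fraction must be in (0, 1)")
        for mult in (self.diet_multiplier, self.urbanization_multiplier):
            if mult <= 1.0:
                raise ValueError("effect multipliers must exceed 1")
        if self.signal_mode not in ("counts", "counts_and_zeros"):
            raise ValueError("signal_mode must be 'counts' or 'counts_and_zeros'")
        if self.n_samples < 1 or self.n_taxa < 1:
            raise ValueError("n_samples and n_taxa must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment.

    ``da_mask`` has one row per signal factor (the four diet groups and, in
    confounded mode, urbanization and age) and one column per taxon.  The
    per-factor taxon sets are drawn independently.
    """

    da_mask: pd.DataFrame
    group_assignment: np.ndarray
    multipliers: dict[str, float]
    urbanization: Optional[np.ndarray] = None
    age: Optional[np.ndarray] = None

    def da_any(self, factors=None) -> np.ndarray:
        """Per-taxon indicator of being differentially abundant for any of
        the given factors (default: all)."""
        mask = self.da_mask if factors is None else self.da_mask.loc[list(factors)]
        return mask.to_numpy().any(axis=0)

    def diet_factors(self) -> list[str]:
        return [f for f in self.da_mask.index if f in DIET_LEVELS]


def generate_base_counts(config: SimulationConfig, rng=None) -> CountTable:
    """Zero-inflated negative binomial base table with no injected signal.

    Taxon j draws ``Y_ij ~ ZINB(mean = mu_j * f_i, size = theta_j, pi_j)``
    where ``f_i`` is a log-normal library-size factor; means are log-uniform
    over ``mean_range`` so rare taxa dominate, as in real tables.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n, m = config.n_samples, config.n_taxa
    mu = np.exp(rng.uniform(*np.log(config.mean_range), size=m))
    theta = rng.uniform(*config.dispersion_range, size=m)
    pi = rng.uniform(*config.zero_inflation_range, size=m)
    f = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n)

    lam = rng.gamma(shape=theta, scale=(f[:, None] * mu) / theta)
    counts = rng.poisson(lam)
    counts[rng.random((n, m)) < pi] = 0
    # a sample with an all-zero row has no library; give it one pseudo-count
    # in its largest-mean taxon so downstream offsets stay defined
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, int(np.argmax(mu))] = 1
    return CountTable(
        counts=counts,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        taxon_ids=[f"T{j:04d}" for j in range(m)],
    )


def assign_diet_groups(n: int, seed) -> np.ndarray:
    """I.i.d. uniform assignment over the four diet groups."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(DIET_LEVELS, size=n)


def assign_confounders(diet: np.ndarray, seed) -> tuple[np.ndarray, np.ndarray]:
    """Urbanization and age correlated with diet.

    Urbanization is 'low' with the diet-conditional probability of the fixed
    joint table; the age decade is drawn conditionally on diet and the age
    uniformly (integer) within the decade.  Returns ``(urbanization, age)``.
    """
    rng = np.random.default_rng(seed)
    diet = np.asarray(diet)
    n = len(diet)
    p_low = np.array([URBANIZATION_GIVEN_DIET[d] for d in diet])
    urban = np.where(rng.random(n) < p_low, "low", "high")
    age = np.empty(n, dtype=int)
    for i, d in enumerate(diet):
        k = rng.choice(len(AGE_DECADES), p=AGE_DECADE_GIVEN_DIET[d])
        lo, hi = AGE_DECADES[k]
        age[i] = rng.integers(lo, hi)
    return urban, age


def select_da_taxa(n_taxa: int, da_fraction: float, n_factors: int, seed) -> np.ndarray:
    """Independent uniform subsets of ``round(da_fraction * n_taxa)`` taxa,
    one per factor, as an (n_factors, n_taxa) boolean mask."""
    if not (0.0 < da_fraction < 1.0):
        raise ValueError("da_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = round(da_fraction * n_taxa)
    mask = np.zeros((n_factors, n_taxa), dtype=bool)
    for f in range(n_factors):
        mask[f, rng.choice(n_taxa, size=k, replace=False)] = True
    return mask


def inject_count_signal(column, affected, multiplier) -> np.ndarray:
    """Multiply the non-zero counts of affected samples by the effect size.

    ``multiplier`` may be a scalar or a per-sample vector (the age ramp);
    products are rounded half-to-even back to integers and zeros are left
    untouched.
    """
    col = np.asarray(column, dtype=np.int64).copy()
    affected = np.asarray(affected, dtype=bool)
    mult = np.broadcast_to(np.asarray(multiplier, dtype=float), col.shape)
    if np.any(mult[affected] < 1.0):
        raise ValueError("effect multipliers must be >= 1")
    hit = affected & (col > 0)
    col[hit] = np.rint(col[hit].astype(float) * mult[hit]).astype(np.int64)
    return col


def inject_zero_signal(column, affected, multiplier, rng) -> np.ndarray:
    """Shuffle a taxon's counts so affected samples are more often non-zero.

    The baseline odds ``o = #nonzero / #zero`` are multiplied by the effect
    size for affected samples; every sample's zero/non-zero status is then
    redrawn from its odds, and non-zero statuses receive values sampled
    without replacement from the column's original non-zero counts.  When
    the pool depletes, a random subset of the surplus non-zero draws is
    assigned zero instead, so the output's non-zero values are always a
    sub-multiset of the input's.
    """
    rng = np.random.default_rng(rng)
    col = np.asarray(column, dtype=np.int64)
    affected = np.asarray(affected, dtype=bool)
    nonzero_pool = col[col > 0]
    n_nonzero, n_zero = nonzero_pool.size, col.size - nonzero_pool.size
    if n_nonzero == 0 or n_zero == 0:
        raise ValueError(
            "zero-odds signal needs both zero and non-zero counts in the column"
        )
    odds = n_nonzero / n_zero
    mult = np.broadcast_to(np.asarray(multiplier, dtype=float), col.shape)
    if np.any(mult[affected] < 1.0):
        raise ValueError("effect multipliers must be >= 1")
    o = np.where(affected, odds * mult, odds)
    p_nonzero = o / (1.0 + o)
    want = rng.random(col.size) < p_nonzero
    out = np.zeros_like(col)
    idx = np.flatnonzero(want)
    if idx.size > n_nonzero:
        idx = rng.choice(idx, size=n_nonzero, replace=False)  # pool depleted
    values = rng.choice(nonzero_pool, size=idx.size, replace=False)
    out[idx] = values
    return out


def age_multiplier(age, max_increment: float = 4.0) -> np.ndarray:
    """Linear effect ramp: +0% at age 20 up to +400% at age 69."""
    age = np.asarray(age, dtype=float)
    if np.any((age < 20) | (age > 69)):
        raise ValueError("ages must lie in [20, 69]")
    return 1.0 + max_increment * (age - 20.0) / (69.0 - 20.0)


def inject_age_signal(counts, ages, da_mask_age, rng, mode="counts",
                      max_increment: float = 4.0) -> np.ndarray:
    """Apply the per-sample age ramp to the age factor's taxa.

    Every sample is 'affected' with its own multiplier ``1 + 4(age-20)/49``;
    in counts-and-zeros mode the odds scheme runs first with the same
    per-sample multiplier, then the count multiplication.
    """
    rng = np.random.default_rng(rng)
    counts = np.asarray(counts, dtype=np.int64).copy()
    mult = age_multiplier(ages, max_increment)
    affected = mult > 1.0
    for j in np.flatnonzero(np.asarray(da_mask_age, dtype=bool)):
        col = counts[:, j]
        if mode == "counts_and_zeros" and np.any(col > 0) and np.any(col == 0):
            col = inject_zero_signal(col, affected, mult, rng)
        counts[:, j] = inject_count_signal(col, affected, mult)
    return counts


def build_experiment(
    config: SimulationConfig,
) -> tuple[CountTable, pd.DataFrame, SimulationTruth]:
    """Compose the full simulated study.

    Returns the injected count table, the per-sample covariate table
    (sample_id, diet and, in confounded mode, urbanization and age) and the
    ground truth.  Fully reproducible from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    s_base, s_diet, s_conf, s_mask, s_inject = root.spawn(5)

    base = generate_base_counts(config, rng=np.random.default_rng(s_base))
    counts = base.counts.copy()
    n, m = counts.shape

    diet = assign_diet_groups(n, s_diet)
    factors = list(DIET_LEVELS)
    if config.confounded:
        urban, age = assign_confounders(diet, s_conf)
        factors += ["urbanization", "age"]
    else:
        urban = age = None

    mask = select_da_taxa(m, config.da_fraction, len(factors), s_mask)
    da_mask = pd.DataFrame(mask, index=factors, columns=base.taxon_ids)

    rng = np.random.default_rng(s_inject)
    zeros_too = config.signal_mode == "counts_and_zeros"

    def apply_group_signal(factor: str, in_group: np.ndarray, mult: float):
        for j in np.flatnonzero(da_mask.loc[factor].to_numpy()):
            col = counts[:, j]
            if zeros_too and np.any(col > 0) and np.any(col == 0):
                col = inject_zero_signal(col, in_group, mult, rng)
            counts[:, j] = inject_count_signal(col, in_group, mult)

    for level in DIET_LEVELS:
        apply_group_signal(level, diet == level, config.diet_multiplier)
    if config.confounded:
        apply_group_signal(
            "urbanization", urban == "high", config.urbanization_multiplier
        )
        counts[:, :] = inject_age_signal(
            counts, age, da_mask.loc["age"].to_numpy(), rng,
            mode=config.signal_mode, max_increment=config.age_max_increment,
        )

    cov = pd.DataFrame({"sample_id": base.sample_ids, "diet": diet})
    if config.confounded:
        cov["urbanization"] = urban
        cov["age"] = age

    multipliers = {lv: config.diet_multiplier for lv in DIET_LEVELS}
    if config.confounded:
        multipliers["urbanization"] = config.urbanization_multiplier
        multipliers["age"] = 1.0 + config.age_max_increment

    table = CountTable(  # library sizes recomputed from the injected counts
        counts=counts, sample_ids=base.sample_ids, taxon_ids=base.taxon_ids
    )
    truth = SimulationTruth(
        da_mask=da_mask,
        group_assignment=diet,
        multipliers=multipliers,
        urbanization=urban,
        age=age,
    )
    return table, cov, truth
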