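"""Multiplicity strata: how many distinct factors bind each union region, and
how strongly conservation / in-vivo validation track that multiplicity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

from .intervals import GenomicInterval, IntervalIndex
from .model import Compendium
from .occupancy import UnionRegionSet


def region_multiplicity(union: UnionRegionSet, compendium: Compendium
                        ) -> np.ndarray:
    """Distinct factors (not samples) bound per union region.

    A factor assayed in several cell types counts once, so heavily re-assayed
    factors do not inflate multiplicity.
    """
    factors = sorted({ps.factor for ps in compendium.values()})
    fmat = np.zeros((len(union.regions), len(factors)), dtype=bool)
    for s, sid in enumerate(union.sample_ids):
        f = factors.index(compendium[sid].factor)
        fmat[:, f] |= union.occupancy[:, s]
    return fmat.sum(axis=1)


def multi_factor_fraction(multiplicity: np.ndarray) -> float:
    """Fraction of occupied regions bound by more than one factor."""
    occupied = multiplicity[multiplicity > 0]
    return float((occupied > 1).mean()) if occupied.size else float("nan")


@dataclass
class MultiplicityStrata:
    table: pd.DataFrame     # index: multiplicity (capped); columns: n, fraction, ci
    multiplicity: np.ndarray
    feature_flags: np.ndarray
    cap: int


def stratified_overlap_fraction(
    union: UnionRegionSet,
    multiplicity: np.ndarray,
    features: Sequence[GenomicInterval],
    cap: int = 8,
    ci_level: float = 0.95,
) -> MultiplicityStrata:
    """Per-multiplicity-stratum fraction of regions touching >= 1 feature.

    Strata above ``cap`` pool into a top bin.  Empty strata report NaN
    fractions.  Clopper-Pearson binomial CIs are attached per stratum.
    """
    flags = (
        IntervalIndex(features).interval_overlap_flags(union.regions)
        if len(features)
        else np.zeros(len(union.regions), dtype=bool)
    )
    capped = np.minimum(multiplicity, cap)
    rows = []
    for m in range(1, cap + 1):
        sel = capped == m
        n = int(sel.sum())
        if n == 0:
            rows.append((m, 0, np.nan, np.nan, np.nan))
            continue
        k = int(flags[sel].sum())
        ci = binomtest(k, n).proportion_ci(ci_level, method="exact")
        rows.append((m, n, k / n, ci.low, ci.high))
    table = pd.DataFrame(
        rows, columns=["multiplicity", "n", "fraction", "ci_low", "ci_high"]
    ).set_index("multiplicity")
    return MultiplicityStrata(table, capped, flags, cap)


@dataclass
class TrendTest:
    stratum_rho: float   # Spearman over (stratum multiplicity, fraction)
    region_rho: float    # Spearman over (per-region multiplicity, feature flag)
    p_value: float       # permutation p on the region-level statistic
    n_permutations: int


def multiplicity_trend_test(
    strata: MultiplicityStrata, n_perm: int = 10_000, seed: int = 0
) -> TrendTest:
    """Does feature overlap increase with binding multiplicity?

    The reported stratum-level Spearman correlates multiplicity with the
    per-stratum fraction.  The permutation test permutes the per-region
    feature flags and uses the region-level Spearman between multiplicity and
    flag as its statistic — the quantity that region-label permutation
    actually randomises, and one with per-region resolution.  Two-sided
    add-one empirical p.
    """
    t = strata.table.dropna(subset=["fraction"])
    if len(t) < 3:
        raise ValueError("need >= 3 non-empty strata")
    stratum_rho = float(spearmanr(t.index.to_numpy(), t["fraction"]).statistic)

    mult = strata.multiplicity.astype(float)
    flags = strata.feature_flags.astype(float)
    r_mult = pd.Series(mult).rank().to_numpy()
    r_mult = (r_mult - r_mult.mean())
    denom_m = np.sqrt((r_mult ** 2).sum())
    r_flag = pd.Series(flags).rank().to_numpy()
    r_flag = r_flag - r_flag.mean()
    denom_f = np.sqrt((r_flag ** 2).sum())
    if denom_m == 0 or denom_f == 0:
        return TrendTest(stratum_rho, 0.0, 1.0, n_perm)
    obs = float(r_mult @ r_flag / (denom_m * denom_f))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        rho = r_mult @ rng.permutation(r_flag) / (denom_m * denom_f)
        exceed += abs(rho) >= abs(obs) - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    return TrendTest(stratum_rho, obs, float(p), n_perm)
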