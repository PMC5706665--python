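"""Posterior summaries, Pr(biphasic), and pairwise significance comparisons.

Derived growth quantities are computed per retained draw and summarized
afterwards — medians of derived quantities are not functions of parameter
medians (median K2 != median K1 + median k in general), which is why the
per-draw route matters.

Two fits are compared by subtracting their pooled draw vectors index-wise
and measuring the proportion of differences greater than zero; proportions
above 97.5% or below 2.5% are flagged significant.  Exact zero differences
contribute one half, so comparing a fit with itself gives 0.5 and no flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorSamples

__all__ = [
    "QUANTITIES",
    "ALL_QUANTITIES",
    "FitSummary",
    "ComparisonResult",
    "derive_per_draw",
    "pr_biphasic",
    "summarize",
    "compare",
]

#: Output column order of the summary table (parameters interleaved with
#: derived quantities, a layout suited to side-by-side reporting).
QUANTITIES = (
    "K1", "k", "K2", "K_max", "B1", "B2", "M1", "m", "M2",
    "R_M1", "R_M2", "R_max", "M_Rmax",
)
ALL_QUANTITIES = QUANTITIES + ("alpha",)


def derive_per_draw(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-draw parameter and derived-quantity values, chains pooled.

    Columns: all of :data:`ALL_QUANTITIES` plus ``w``.  The switching rules
    are applied draw by draw: a draw's K_max is its own K1 or K1 + k
    according to its own w.
    """
    K1 = samples.pooled("K1")
    k = samples.pooled("k")
    B1 = samples.pooled("B1")
    B2 = samples.pooled("B2")
    M1 = samples.pooled("M1")
    m = samples.pooled("m")
    w = samples.pooled("w")
    alpha = samples.pooled("alpha")
    if K1.size == 0:
        raise ValueError("empty posterior sample set")

    biphasic = w >= 0.5
    K2 = K1 + k
    M2 = M1 + m

    # full-curve derivative at M1: first phase at its inflection (s1 = 1/2),
    # second phase evaluated a distance m before its inflection
    s2_at_m1 = expit(-B2 * m)
    R_M1 = (K1 - 1.0) * B1 * 0.25 + w * k * B2 * s2_at_m1 * (1.0 - s2_at_m1)
    # at M2: second phase at its inflection, first phase m days past its own
    s1_at_m2 = expit(B1 * m)
    R_M2 = (K1 - 1.0) * B1 * s1_at_m2 * (1.0 - s1_at_m2) + w * k * B2 * 0.25

    K_max = np.where(biphasic, K2, K1)
    R_max = np.where(biphasic, np.maximum(R_M1, R_M2), R_M1)
    M_Rmax = np.where(~biphasic | (B1 >= B2), M1, M2)

    return pd.DataFrame(
        {
            "K1": K1, "k": k, "K2": K2, "K_max": K_max,
            "B1": B1, "B2": B2, "M1": M1, "m": m, "M2": M2,
            "R_M1": R_M1, "R_M2": R_M2, "R_max": R_max, "M_Rmax": M_Rmax,
            "alpha": alpha, "w": w,
        }
    )


def pr_biphasic(samples: PosteriorSamples) -> float:
    """Posterior probability of biphasic growth: the mean of w, all chains pooled."""
    w = samples.pooled("w")
    if w.size == 0:
        raise ValueError("empty posterior sample set")
    return float(np.mean(w))


@dataclass
class FitSummary:
    """Medians and equal-tailed 95% credibility intervals for one fit.

    ``table`` is indexed by quantity name with columns ``median``, ``lo``,
    ``hi`` (2.5% and 97.5% quantiles, linear interpolation between order
    statistics).
    """

    strain: str
    treatment: str
    table: pd.DataFrame
    pr_biphasic: float

    def to_dataframe(self) -> pd.DataFrame:
        """One wide row per fit, quantities in the standard reporting order."""
        row: dict = {"strain": self.strain, "treatment": self.treatment}
        for q in self.table.index:
            row[f"{q}_median"] = self.table.loc[q, "median"]
            row[f"{q}_lo"] = self.table.loc[q, "lo"]
            row[f"{q}_hi"] = self.table.loc[q, "hi"]
        row["pr_biphasic"] = self.pr_biphasic
        return pd.DataFrame([row])


def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])  # linear interpolation
    return float(med), float(lo), float(hi)


def summarize(samples: PosteriorSamples) -> FitSummary:
    """Median and central 95% interval for every parameter and derived quantity."""
    per_draw = derive_per_draw(samples)
    rows = []
    for q in ALL_QUANTITIES:
        med, lo, hi = _quantiles(per_draw[q].to_numpy())
        rows.append({"quantity": q, "median": med, "lo": lo, "hi": hi})
    table = pd.DataFrame(rows).set_index("quantity")
    return FitSummary(
        strain=samples.strain,
        treatment=samples.treatment,
        table=table,
        pr_biphasic=pr_biphasic(samples),
    )


@dataclass
class ComparisonResult:
    """Posterior-difference test between two fits for one quantity."""

    quantity: str
    label_a: str
    label_b: str
    proportion_gt_zero: float
    significant: bool


def compare(
    samples_a: PosteriorSamples,
    samples_b: PosteriorSamples,
    quantity: str,
    seed: int = 0,
) -> ComparisonResult:
    """Proportion of pairwise (a - b) differences greater than zero.

    Chains are pooled, then equal-length draw vectors are paired index-wise;
    if lengths differ, the longer vector is subsampled without replacement
    (seeded).  Exact ties contribute one half.  The pair is flagged
    significant when the proportion exceeds 0.975 or falls below 0.025.
    """
    if quantity not in ALL_QUANTITIES and quantity != "w":
        raise ValueError(f"unknown quantity {quantity!r}")
    a = derive_per_draw(samples_a)[quantity].to_numpy()
    b = derive_per_draw(samples_b)[quantity].to_numpy()
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        if a.size > b.size:
            a = a[rng.choice(a.size, size=b.size, replace=False)]
        else:
            b = b[rng.choice(b.size, size=a.size, replace=False)]
    diff = a - b
    prop = float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))
    return ComparisonResult(
        quantity=quantity,
        label_a=f"{samples_a.strain}:{samples_a.treatment}",
        label_b=f"{samples_b.strain}:{samples_b.treatment}",
        proportion_gt_zero=prop,
        significant=bool(prop > 0.975 or prop < 0.025),
    )
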