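"""Per-gene differential-expression statistics for subgroup dichotomies.

Two statistics are computed on the posterior-normalized matrix for
every pairwise comparison of subgroups: the posterior-difference
statistic (difference of group-average Bayes posteriors, in [-1, 1],
sign giving the direction of regulation) and Cohen's D with pooled
standard deviation for unequal group sizes and variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Dichotomy",
    "D_MAX",
    "group_mean_posterior",
    "pdeg",
    "cohens_d",
    "dichotomy_table",
    "dichotomies_from_groups",
]

#: Cap for Cohen's D when the pooled standard deviation degenerates to zero
#: (posteriors saturating at 0/1 make this reachable).
D_MAX = 10.0


@dataclass(frozen=True)
class Dichotomy:
    """One group-vs-group comparison; positive statistics mean higher in a."""

    name_a: str
    name_b: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples_a) < 2 or len(self.samples_b) < 2:
            raise ValueError("each side of a dichotomy needs at least 2 samples")
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError(
                f"dichotomy {self.name_a} vs {self.name_b}: groups overlap"
            )

    @property
    def name(self) -> str:
        return f"{self.name_a}_vs_{self.name_b}"

    def swapped(self) -> "Dichotomy":
        return Dichotomy(self.name_b, self.name_a, self.samples_b, self.samples_a)


def group_mean_posterior(posteriors: pd.DataFrame, gene: str, samples) -> float:
    """Arithmetic mean of a gene's posteriors over a sample group."""
    samples = list(samples)
    if not samples:
        raise ValueError("group is empty")
    missing = set(samples) - set(posteriors.columns)
    if missing:
        raise KeyError(f"unknown sample ids: {sorted(missing)}")
    return float(posteriors.loc[gene, samples].mean())


def pdeg(posteriors: pd.DataFrame, gene: str, dichotomy: Dichotomy) -> float:
    """Difference of group-average posteriors; in [-1, 1], antisymmetric."""
    return group_mean_posterior(posteriors, gene, dichotomy.samples_a) - group_mean_posterior(
        posteriors, gene, dichotomy.samples_b
    )


def cohens_d(values_a, values_b) -> float:
    """Cohen's D with (n-1)-weighted pooled variance for unequal groups.

    Location-invariant, scale-invariant and antisymmetric.  When the
    pooled sd is zero the result is 0 for equal means and a capped
    +-``D_MAX`` sentinel otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Cohen's D needs at least 2 values per group")
    diff = a.mean() - b.mean()
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means; capping Cohen's D")
        return float(np.sign(diff) * D_MAX)
    return float(diff / np.sqrt(pooled_var))


def dichotomy_table(posteriors: pd.DataFrame, dichotomy: Dichotomy) -> pd.DataFrame:
    """Per-gene statistics for one dichotomy, in the input gene order.

    Columns: pdeg, cohen_d, mean_a, mean_b, n_a, n_b.
    """
    a = posteriors.loc[:, list(dichotomy.samples_a)].to_numpy(dtype=float)
    b = posteriors.loc[:, list(dichotomy.samples_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    n_a, n_b = a.shape[1], b.shape[1]
    pooled_var = (
        (n_a - 1) * a.var(axis=1, ddof=1) + (n_b - 1) * b.var(axis=1, ddof=1)
    ) / (n_a + n_b - 2)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / np.sqrt(pooled_var)
    degenerate = pooled_var == 0.0
    d[degenerate & (diff == 0.0)] = 0.0
    d[degenerate & (diff != 0.0)] = np.sign(diff[degenerate & (diff != 0.0)]) * D_MAX
    return pd.DataFrame(
        {
            "pdeg": diff,
            "cohen_d": d,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "n_a": n_a,
            "n_b": n_b,
        },
        index=posteriors.index.rename("gene"),
    )


def dichotomies_from_groups(
    group_members: dict[str, list[str]], pairs
) -> list[Dichotomy]:
    """Build dichotomies from a label -> members map, skipping tiny groups."""
    out = []
    for name_a, name_b in pairs:
        members_a = group_members.get(name_a, [])
        members_b = group_members.get(name_b, [])
        if len(members_a) < 2 or len(members_b) < 2:
            warnings.warn(
                f"skipping dichotomy {name_a} vs {name_b}: a side has fewer than 2 samples"
            )
            continue
        out.append(Dichotomy(name_a, name_b, tuple(members_a), tuple(members_b)))
    return out
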