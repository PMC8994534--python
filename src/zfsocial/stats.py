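"""Group comparisons: Tukey-Kramer HSD on group means and permutation tests.

The HSD path mirrors the comparisons applied to the three genotypes (wt,
het, mut) throughout the figures, with the Kramer unequal-n correction; the
permutation test is a distribution-free alternative for two-group and
paired contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class ComparisonResult:
    """Pairwise group comparison summary at alpha = 0.05."""

    groups: list[str]
    estimates: dict[str, float]
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, significant
    alpha: float = 0.05


def hsd_pairwise(values: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonResult:
    """Tukey-Kramer HSD over all group pairs.

    ``values`` maps group label to a 1-d array of observations; unequal
    group sizes get the Kramer correction via the studentized-range
    distribution.  Significance is p_adjusted < alpha (two-sided).
    """
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in values.items():
        if len(np.atleast_1d(v)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    labels = []
    data = []
    for g, v in values.items():
        v = np.asarray(v, dtype=float).ravel()
        labels.extend([g] * len(v))
        data.extend(v.tolist())
    res = pairwise_tukeyhsd(np.asarray(data), np.asarray(labels), alpha=alpha)
    table = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    pairwise = pd.DataFrame({
        "group1": table["group1"].astype(str),
        "group2": table["group2"].astype(str),
        "meandiff": res.meandiffs,
        "p_adj": res.pvalues,
        "significant": res.pvalues < alpha,
    })
    estimates = {g: float(np.mean(np.asarray(v, dtype=float))) for g, v in values.items()}
    return ComparisonResult(groups=sorted(values), estimates=estimates,
                            pairwise=pairwise, alpha=alpha)


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    paired: bool = False,
) -> float:
    """Two-sided permutation p-value for a difference in means.

    Unpaired: group labels are shuffled ``n_perm`` times.  Paired: the signs
    of the per-pair differences are flipped.  The p-value uses the add-one
    correction p = (1 + #{|T*| >= |T|}) / (n_perm + 1), so it is never
    exactly zero and is reproducible under a fixed seed.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        d = a - b
        obs = abs(d.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
        null = np.abs((signs * d).mean(axis=1))
    else:
        obs = abs(a.mean() - b.mean())
        # sorted pool + smaller-group split => p exactly invariant to label swap
        pooled = np.sort(np.concatenate([a, b]))
        nmin = min(len(a), len(b))
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = abs(perm[:nmin].mean() - perm[nmin:].mean())
    return float((1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1))
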