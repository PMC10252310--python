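"""Fisher's least significant difference with a compact letter display.

After a one-way ANOVA, two group means differ significantly at level α when

    |m_i − m_j| >= t(1 − α/2, df_E) · sqrt(MSE · (1/n_i + 1/n_j))

with MSE the pooled within-group mean square and df_E its residual degrees
of freedom.  Groups are then assigned letters by the insert-and-absorb
procedure: groups that do not share a letter are significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LsdResult:
    """Group means, ANOVA error terms, pairwise significance and letters."""

    means: dict
    n: dict
    mse: float
    df_resid: int
    alpha: float
    t_critical: float
    significant: pd.DataFrame      # boolean, groups x groups
    letters: dict                  # group -> letter string, e.g. "ab"

    def lsd(self, group_a, group_b) -> float:
        """The least significant difference for one pair (pairwise form;
        reduces to sqrt(2·MSE/n) scaling for equal group sizes)."""
        return self.t_critical * np.sqrt(
            self.mse * (1.0 / self.n[group_a] + 1.0 / self.n[group_b]))


def _letter_display(names: list, means: dict,
                    significant: pd.DataFrame) -> dict:
    """Insert-and-absorb compact letter display."""
    ordered = sorted(names, key=lambda g: -means[g])
    sets: list[set] = [set(ordered)]
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if not significant.loc[a, b]:
                continue
            for s in [s for s in sets if a in s and b in s]:
                sets.remove(s)
                sets.extend([s - {a}, s - {b}])
            # absorb sets contained in another
            sets = [s for s in sets
                    if s and not any(s < t for t in sets if t is not s)]
            # drop duplicates
            unique: list[set] = []
            for s in sets:
                if s not in unique:
                    unique.append(s)
            sets = unique
    sets.sort(key=lambda s: -max(means[g] for g in s))
    letters = {g: "" for g in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return letters


def lsd_compare(groups: dict, alpha: float = 0.05) -> LsdResult:
    """Compare group means by one-way ANOVA + Fisher LSD at level ``alpha``.

    ``groups`` maps a group name to its observation array; every group needs
    at least two observations and there must be at least two groups.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=np.float64).ravel() for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")

    n = {g: int(v.size) for g, v in arrays.items()}
    means = {g: float(v.mean()) for g, v in arrays.items()}
    n_total = sum(n.values())
    df_resid = n_total - len(names)
    sse = sum(float(np.sum((v - means[g]) ** 2)) for g, v in arrays.items())
    mse = sse / df_resid
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df_resid))

    sig = pd.DataFrame(False, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lsd = t_crit * np.sqrt(mse * (1.0 / n[a] + 1.0 / n[b]))
            diff = abs(means[a] - means[b])
            # diff > 0 guards the degenerate MSE = 0 case (identical groups)
            is_sig = diff >= lsd and diff > 0
            sig.loc[a, b] = sig.loc[b, a] = bool(is_sig)

    letters = _letter_display(names, means, sig)
    return LsdResult(means=means, n=n, mse=mse, df_resid=df_resid, alpha=alpha,
                     t_critical=t_crit, significant=sig, letters=letters)
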