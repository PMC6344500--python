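"""Between-subgroup effect-size contrasts.

Z = (log OR_1 - log OR_2) / sqrt(SE_1^2 + SE_2^2), standard normal under the
shared-effect null when the two subgroups are disjoint; two-sided p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTRAST_P = 5e-5


@dataclass
class EffectContrast:
    z: float
    p: float
    threshold: float = CONTRAST_P

    @property
    def significant(self) -> bool:
        return self.p < self.threshold


def effect_size_difference(beta1: float, se1: float, beta2: float, se2: float,
                           threshold: float = CONTRAST_P) -> EffectContrast:
    """Normal Z test for the difference of two independent log odds ratios."""
    vals = (beta1, se1, beta2, se2)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError(f"non-finite inputs {vals}")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta1 - beta2) / math.sqrt(se1 ** 2 + se2 ** 2)
    return EffectContrast(z=z, p=float(2 * stats.norm.sf(abs(z))),
                          threshold=threshold)


def contrast_scan(early, late, threshold: float = CONTRAST_P):
    """Per-variant contrasts between two scan tables sharing variant keys.

    ``early`` / ``late``: DataFrames with columns variant, beta, se (a
    ``ScanTable.table`` works directly). Returns ``(contrasts, only_one)``
    where ``contrasts`` has z, p and a flag at ``threshold`` for the shared
    variants and ``only_one`` lists variants present in a single table.
    """
    e = getattr(early, "table", early)[["variant", "beta", "se"]]
    l = getattr(late, "table", late)[["variant", "beta", "se"]]
    merged = e.merge(l, on="variant", suffixes=("_early", "_late"))
    only = sorted(set(e["variant"]).symmetric_difference(l["variant"]))
    if merged.empty:
        raise ValueError("no shared variants between the two scan tables")
    rows = []
    for _, r in merged.iterrows():
        if not np.isfinite([r.beta_early, r.se_early, r.beta_late, r.se_late]).all():
            rows.append({"variant": r.variant, "z": np.nan, "p": np.nan,
                         "significant": False})
            continue
        c = effect_size_difference(r.beta_early, r.se_early, r.beta_late, r.se_late,
                                   threshold)
        rows.append({"variant": r.variant, "z": c.z, "p": c.p,
                     "significant": c.significant})
    return pd.DataFrame(rows), only
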