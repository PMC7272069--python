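"""Shared light-weight statistical result container and FDR helper."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TestResult:
    """Outcome of a hypothesis test: method name, statistic, p-value, extras."""

    method: str
    statistic: float
    p_value: float
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
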