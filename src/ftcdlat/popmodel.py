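"""Left-brain-bias mixture model.

The population mixes a low-risk majority with a strong (default 90:10)
bias to left-hemisphere language and a high-risk minority with no bias
(50:50).  Risk, not individual laterality, carries the language-impairment
liability.  The module provides analytic expectations, Monte-Carlo
sampling, twin-concordance corollaries and model-expected case-control
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stats import ContingencyTable, linear_by_linear

__all__ = [
    "PopulationParams",
    "expected_laterality",
    "expected_left_given_risk",
    "simulate_population",
    "twin_concordance",
    "expected_case_control_table",
    "trend_test_power",
]


@dataclass
class PopulationParams:
    p_risk: float = 0.2
    bias_low: float = 0.9
    bias_high: float = 0.5
    p_impair_low: float = 0.05
    p_impair_high: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p_risk", "bias_low", "bias_high",
                     "p_impair_low", "p_impair_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_impair_high < self.p_impair_low:
            raise ValueError("p_impair_high must be >= p_impair_low")


def expected_laterality(params: PopulationParams) -> dict[str, float]:
    """Analytic P(left) overall and per risk group."""
    overall = ((1 - params.p_risk) * params.bias_low
               + params.p_risk * params.bias_high)
    return {
        "overall": overall,
        "low_risk": params.bias_low,
        "high_risk": params.bias_high,
    }


def expected_left_given_risk(params: PopulationParams) -> float:
    """Proportion of risk-carriers with typical left-hemisphere language."""
    return params.bias_high


def simulate_population(n: int, params: PopulationParams,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Independent draws of (risk_group, laterality, impaired) for n people."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    risk = rng.random(n) < params.p_risk
    bias = np.where(risk, params.bias_high, params.bias_low)
    left = rng.random(n) < bias
    p_imp = np.where(risk, params.p_impair_high, params.p_impair_low)
    impaired = rng.random(n) < p_imp
    return pd.DataFrame({
        "risk_group": np.where(risk, "high", "low"),
        "laterality": np.where(left, "left", "right"),
        "impaired": impaired,
    })


def twin_concordance(params: PopulationParams) -> dict[str, float]:
    """P(co-twins share laterality direction) per risk group.

    Co-twins share the risk group; directions are drawn independently
    given the group bias b, so concordance is b^2 + (1-b)^2 (0.5 at
    b = 0.5 — discordant and concordant pairs equally likely).
    """
    def conc(b: float) -> float:
        return b * b + (1 - b) * (1 - b)

    return {
        "low_risk": conc(params.bias_low),
        "high_risk": conc(params.bias_high),
    }


def _p_left_by_status(params: PopulationParams) -> tuple[float, float]:
    """(P(left | typical language), P(left | impaired)) via Bayes."""
    p_imp = (params.p_risk * params.p_impair_high
             + (1 - params.p_risk) * params.p_impair_low)
    p_typ = 1.0 - p_imp
    if p_imp > 0:
        p_risk_imp = params.p_risk * params.p_impair_high / p_imp
    else:
        p_risk_imp = 0.0
    if p_typ > 0:
        p_risk_typ = (params.p_risk * (1 - params.p_impair_high)) / p_typ
    else:
        p_risk_typ = 0.0
    p_left_imp = p_risk_imp * params.bias_high + (1 - p_risk_imp) * params.bias_low
    p_left_typ = p_risk_typ * params.bias_high + (1 - p_risk_typ) * params.bias_low
    return p_left_typ, p_left_imp


def expected_case_control_table(
    params: PopulationParams, n_typical: int, n_impaired: int,
    n_replicates: int = 0, rng: np.random.Generator | None = None,
) -> tuple[ContingencyTable, list[ContingencyTable]]:
    """Model-expected left/right counts by language status, plus optional
    Monte-Carlo replicate tables for power estimation."""
    if n_typical < 1 or n_impaired < 1:
        raise ValueError("group sizes must be >= 1")
    if n_impaired > 0 and params.p_impair_low == 0 and params.p_impair_high == 0:
        raise ValueError("impairment probability is zero in both groups")
    p_left_typ, p_left_imp = _p_left_by_status(params)
    expected = ContingencyTable(
        np.array([
            [n_typical * p_left_typ, n_typical * (1 - p_left_typ)],
            [n_impaired * p_left_imp, n_impaired * (1 - p_left_imp)],
        ]),
        row_labels=["typical", "impaired"],
        col_labels=["left", "right"],
    )
    reps: list[ContingencyTable] = []
    if n_replicates:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        lt = rng.binomial(n_typical, p_left_typ, size=n_replicates)
        li = rng.binomial(n_impaired, p_left_imp, size=n_replicates)
        for a, b in zip(lt, li):
            reps.append(ContingencyTable(
                np.array([[a, n_typical - a], [b, n_impaired - b]], dtype=float),
                row_labels=["typical", "impaired"],
                col_labels=["left", "right"],
            ))
    return expected, reps


def trend_test_power(params: PopulationParams, n_typical: int, n_impaired: int,
                     n_replicates: int = 2000, alpha: float = 0.05,
                     rng: np.random.Generator | None = None
                     ) -> tuple[float, float]:
    """Empirical power of the linear-by-linear test on replicate tables,
    with its Monte-Carlo standard error."""
    _, reps = expected_case_control_table(
        params, n_typical, n_impaired, n_replicates=n_replicates, rng=rng
    )
    hits = 0
    for tbl in reps:
        try:
            _, _, p = linear_by_linear(tbl)
        except ValueError:  # degenerate replicate (all-left etc.)
            continue
        if p < alpha:
            hits += 1
    power = hits / n_replicates
    mc_se = float(np.sqrt(power * (1 - power) / n_replicates))
    return power, mc_se
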