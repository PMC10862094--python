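"""Flynn (ILSI) and Rasmussen (DFVR) safe-addition formulas.

Both formulas compute FA, the maximum amount of a micronutrient that can be
added to each 100-kcal food portion without the highest consumers exceeding
the tolerable upper intake level (UL). All nutrient quantities are expressed
in IOM-RDA units: an intake in ug divided by the RDA (20 ug/day for
vitamin D), so UL = 100 ug/day is 5 RDA units and a 95th-percentile current
intake (CI95) of 1 ug/day is 0.05 RDA units.

Flynn (ILSI) — supplement intake is ignored by definition; the denominator
is the number of fortifiable 100-kcal portions for the highest energy
consumers, taken as a fixed fraction (default 50%) of 42 daily portions
(4200 kcal/day at the 95th percentile) scaled by PFF, the proportion of
marketable foods that can be fortified:

    FA_Flynn = (UL - CI95) / (fortified_fraction * portions * PFF)

Rasmussen (DFVR) — supplement intake SI is subtracted from the headroom and
the denominator uses the observed 95th-percentile energy intake EI95
(in 100-kcal portions) directly:

    FA_Rasmussen = (UL - (CI95 + SI)) / (EI95 * PFF)

When SI = 0 and EI95 equals fortified_fraction * portions the two formulas
coincide exactly.

Worked defaults (vitamin D): UL = 5, CI95 = 0.05, margin = 4.95 RDA units;
with PFF = 0.11 (8 fortifiable foods out of 70) Flynn gives
4.95 / (0.5 * 42 * 0.11) = 4.95 / 2.31 = 2.14 RDA units per 100-kcal
portion, i.e. 2.1 ug per 100 kcal at RDA = 20 ug — the headline safe
addition for the studied population.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, ParameterError
from .intake import IU_PER_UG

__all__ = [
    "DEFAULT_FORMULA_INPUTS",
    "FormulaInputs",
    "fa_to_ug_per_100kcal",
    "flynn_fa",
    "iu_to_ug",
    "margin",
    "rasmussen_fa",
    "round_half_up",
    "safe_addition_table",
    "ug_to_rda_units",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def iu_to_ug(x: float) -> float:
    """Convert vitamin D IU to ug (40 IU = 1 ug)."""
    if x < 0:
        raise DomainError("IU amount must be >= 0")
    return x / IU_PER_UG


def ug_to_rda_units(x: float, rda_ug: float) -> float:
    """Express an intake in multiples of the RDA."""
    if x < 0:
        raise DomainError("intake must be >= 0")
    if rda_ug <= 0:
        raise DomainError("rda_ug must be > 0")
    return x / rda_ug


def margin(ul: float, ci95: float) -> float:
    """Fortification headroom UL - CI95, in IOM-RDA units."""
    if ci95 < 0:
        raise DomainError("ci95 must be >= 0")
    if ul <= ci95:
        raise DomainError("no fortification headroom: ul must exceed ci95")
    return ul - ci95


@dataclass(frozen=True)
class FormulaInputs:
    """Inputs to the safe-addition formulas, in IOM-RDA units.

    ``portions`` (42 = 4200 kcal/day in 100-kcal portions) and
    ``fortified_fraction`` (0.5: half of the portions can carry the added
    nutrient) are configuration defaults, as is the 20 ug vitamin D RDA.
    """

    ul: float = 5.0
    ci95: float = 0.05
    si: float = 0.0  # supplement intake, RDA units (Rasmussen only)
    ei95: float = 18.8  # 95th-percentile energy, 100-kcal portions/day
    pff: float = 0.11  # proportion of marketable foods fortifiable
    portions: float = 42.0
    fortified_fraction: float = 0.5
    rda_ug: float = 20.0

    def validate(self) -> None:
        if self.ci95 < 0:
            raise ParameterError("ci95 must be >= 0")
        if self.ul <= self.ci95:
            raise ParameterError("ul must exceed ci95")
        if self.si < 0:
            raise ParameterError("si must be >= 0")
        if self.ei95 <= 0:
            raise ParameterError("ei95 must be > 0")
        if not (0 < self.pff <= 1):
            raise ParameterError("pff must lie in (0, 1]")
        if not (0 < self.fortified_fraction <= 1):
            raise ParameterError("fortified_fraction must lie in (0, 1]")
        if self.portions <= 0:
            raise ParameterError("portions must be > 0")
        if self.rda_ug <= 0:
            raise ParameterError("rda_ug must be > 0")

    def with_supplement_iu(self, iu: float) -> "FormulaInputs":
        """Return a copy with SI set from an IU/day dose."""
        si = ug_to_rda_units(iu_to_ug(iu), self.rda_ug)
        return FormulaInputs(
            ul=self.ul, ci95=self.ci95, si=si, ei95=self.ei95, pff=self.pff,
            portions=self.portions, fortified_fraction=self.fortified_fraction,
            rda_ug=self.rda_ug,
        )


DEFAULT_FORMULA_INPUTS = FormulaInputs()


def flynn_fa(inputs: FormulaInputs) -> float:
    """Flynn (ILSI) safe addition, RDA units per 100-kcal portion."""
    inputs.validate()
    return margin(inputs.ul, inputs.ci95) / (
        inputs.fortified_fraction * inputs.portions * inputs.pff
    )


def rasmussen_fa(inputs: FormulaInputs) -> float:
    """Rasmussen (DFVR) safe addition, RDA units per 100-kcal portion."""
    inputs.validate()
    headroom = inputs.ul - (inputs.ci95 + inputs.si)
    if headroom <= 0:
        raise DomainError(
            "no fortification headroom: ci95 + si must stay below ul"
        )
    return headroom / (inputs.ei95 * inputs.pff)


def fa_to_ug_per_100kcal(fa: float, rda_ug: float) -> float:
    """Convert a safe addition from RDA units to ug per 100-kcal portion."""
    if fa < 0:
        raise DomainError("fa must be >= 0")
    return fa * rda_ug


_MODELS = {"flynn": flynn_fa, "rasmussen": rasmussen_fa}


def safe_addition_table(
    pff_list: Iterable[float],
    scenarios: Sequence[tuple[str, float]] = (("flynn", 0.0),),
    base: FormulaInputs = DEFAULT_FORMULA_INPUTS,
) -> pd.DataFrame:
    """Safe-addition table over fortifiable-share values and scenarios.

    ``scenarios`` is a list of (model, si) pairs with model one of
    ``"flynn"`` / ``"rasmussen"`` and si the supplement intake in RDA
    units (Flynn ignores it by definition). PFF values are passed
    explicitly: column labels such as "10%" in published tables may stand
    for a different exact share (0.11 for 8 foods of 70), so the table
    never derives PFF from a label.

    Columns: model, si, pff, fa_rda_units, fa_percent_rda,
    fa_ug_per_100kcal; the last two are exact algebraic transforms of
    fa_rda_units (x100 and x rda_ug).
    """
    rows = []
    for model, si in scenarios:
        if model not in _MODELS:
            raise ParameterError(f"unknown model {model!r}; expected one of {sorted(_MODELS)}")
        for pff in pff_list:
            inputs = FormulaInputs(
                ul=base.ul, ci95=base.ci95, si=si, ei95=base.ei95, pff=pff,
                portions=base.portions, fortified_fraction=base.fortified_fraction,
                rda_ug=base.rda_ug,
            )
            try:
                fa = _MODELS[model](inputs)
            except (DomainError, ParameterError) as exc:
                raise DomainError(f"model {model!r} at pff={pff}: {exc}") from exc
            rows.append(
                {
                    "model": model,
                    "si": si,
                    "pff": pff,
                    "fa_rda_units": fa,
                    "fa_percent_rda": 100.0 * fa,
                    "fa_ug_per_100kcal": fa * base.rda_ug,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["model", "si", "pff", "fa_rda_units", "fa_percent_rda", "fa_ug_per_100kcal"],
    )
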