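"""Functionality / environmental-friendliness screening of derivatives.

Candidate derivatives are screened on DFT stability indicators (total
energy, HOMO-LUMO gap, lowest vibrational frequency) and the four
persistent-organic-pollutant axes: bio-toxicity (logLC50), bioaccumulation
(logBCF -> BCF), persistence (logt1/2) and long-range migration (logKOA).
All property values are upstream inputs (DFT / property-prediction output);
this module does the conversion, change-rate and rule bookkeeping.

Change-rate sign conventions follow the published table: for total energy,
logLC50 and logt1/2 the printed rate is ``100 (parent - new) / parent``
(a *decrease* in the property prints as a positive rate for logLC50, and the
energy rate inherits the sign of the signed a.u. values), while logKOA uses
the plain ``100 (new - parent) / parent``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningRules",
    "bcf_from_log",
    "property_change_rates",
    "screen",
]

# property column -> sign of (new - parent)/parent in the reported rate
_RATE_SIGN = {
    "energy_au": -1.0,
    "logLC50": -1.0,
    "logt12": -1.0,
    "logKOA": +1.0,
}


@dataclass
class ScreeningRules:
    """Default pass/fail rules.

    A derivative passes when its lowest vibrational frequency is positive
    (a true minimum, so the molecule can exist), its bioconcentration factor
    BCF stays below ``max_bcf``, its bio-toxicity indicator logLC50 moved by
    less than ``max_abs_toxicity_change`` percent, and its composite
    biodegradability improved by more than ``min_biodeg_gain`` percent.
    """

    max_bcf: float = 100.0
    max_abs_toxicity_change: float = 10.0
    min_biodeg_gain: float = 15.0


def bcf_from_log(logbcf: float) -> float:
    """Bioconcentration factor from its base-10 logarithm."""
    return float(10.0 ** logbcf)


def property_change_rates(records: pd.DataFrame,
                          parent_id: str = "DEP") -> pd.DataFrame:
    """Add ``*_rate`` columns (percent vs the parent row) and a BCF column.

    Rates are computed at full precision with the per-column sign
    conventions described in the module docstring.
    """
    if parent_id not in records.index:
        raise KeyError(f"parent row {parent_id!r} missing")
    out = records.copy()
    if "logBCF" in out.columns:
        out["BCF"] = [bcf_from_log(v) for v in out["logBCF"]]
    for col, sign in _RATE_SIGN.items():
        if col not in records.columns:
            continue
        parent = records.loc[parent_id, col]
        if parent == 0:
            raise ZeroDivisionError(f"parent {col} is zero")
        out[f"{col}_rate"] = [
            sign * 100.0 * (v - parent) / parent if idx != parent_id else np.nan
            for idx, v in records[col].items()
        ]
    return out


def screen(records: pd.DataFrame, biodeg_rates: pd.Series,
           rules: ScreeningRules | None = None,
           parent_id: str = "DEP") -> pd.DataFrame:
    """Apply the screening rules; returns verdicts with per-rule reasons.

    Parameters
    ----------
    records
        Property table indexed by derivative id (parent row included);
        missing derived columns (BCF, rates) are computed on the fly.
    biodeg_rates
        Percent change of the composite biodegradability vs the parent,
        indexed by derivative id (the parent itself maps to 0).
    """
    rules = rules or ScreeningRules()
    needed = {"BCF", "logLC50_rate"}
    if not needed <= set(records.columns):
        records = property_change_rates(records, parent_id=parent_id)
    rows = []
    for idx, rec in records.iterrows():
        reasons: list[str] = []
        try:
            if not rec["freq_cm1"] > 0:
                reasons.append("lowest frequency not positive")
            if not rec["BCF"] < rules.max_bcf:
                reasons.append(
                    f"BCF {rec['BCF']:.2f} >= {rules.max_bcf:g}")
            tox = 0.0 if idx == parent_id else rec["logLC50_rate"]
            if not abs(tox) < rules.max_abs_toxicity_change:
                reasons.append(
                    f"|logLC50 change| {abs(tox):.2f}% >= "
                    f"{rules.max_abs_toxicity_change:g}%")
            gain = 0.0 if idx == parent_id else float(biodeg_rates.get(idx, np.nan))
            if not gain > rules.min_biodeg_gain:
                reasons.append(
                    f"biodegradability change {gain:.2f}% <= "
                    f"{rules.min_biodeg_gain:g}%")
        except KeyError as exc:  # record-level failure, keep screening others
            reasons.append(f"missing field: {exc}")
        rows.append({"id": idx, "verdict": "pass" if not reasons else "fail",
                     "reasons": "; ".join(reasons)})
    return pd.DataFrame(rows).set_index("id")
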