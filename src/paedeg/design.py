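"""Derivative design bookkeeping for DEP substituent enumeration.

The field-QSAR contour maps suggest three modification rules for diethyl
phthalate (DEP): small-volume groups at the ring C1 position, electropositive
groups replacing the H on C1 ("H1"), and hydrophilic groups at the ester C2
position.  This module enumerates the resulting substitution catalogue and
computes the change-rate / ratio bookkeeping used to compare derivative
predictions against the parent compound.

Predicted activities are inputs (model output or published tables); no 3D
structures are generated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "C1_SMALL_VOLUME",
    "H1_ELECTROPOSITIVE",
    "C2_HYDROPHILIC",
    "SubstitutionScheme",
    "DerivativeRecord",
    "paper_scheme",
    "enumerate_derivatives",
    "change_rate",
    "ratio_decomposition",
    "compare_to_weights",
    "derivative_table",
]

#: Groups smaller than -CH2CH3, allowed at the ring C1 position.
C1_SMALL_VOLUME = ("-CH3", "-OH", "-H", "-CN", "-NH2", "-CHO")
#: Groups more electropositive than -H, allowed at the H1 position.
H1_ELECTROPOSITIVE = ("-CH3", "-CH2CH3", "-CH(CH3)2", "-C(CH3)3")
#: Hydrophilic groups allowed at the ester C2 position.
C2_HYDROPHILIC = ("-OH", "-CHO", "-COOH", "-NH2", "-COCH3", "-CONH2")

_ALLOWED = {
    "C1": set(C1_SMALL_VOLUME),
    "H1": set(H1_ELECTROPOSITIVE),
    "C2": set(C2_HYDROPHILIC) | {g + "x2" for g in C2_HYDROPHILIC},
}


@dataclass
class SubstitutionScheme:
    """A substitution catalogue.

    ``variants`` is an explicit list of substitution combos, each a tuple of
    ``(site, group)`` pairs (one pair for a single substitution, two for a
    double).  When ``variants`` is empty, single substitutions are enumerated
    from ``sites`` directly.  A group suffixed ``x2`` denotes the same group
    placed on both equivalent positions of the site.
    """

    sites: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    mode: str = "single"
    variants: list[tuple[tuple[str, str], ...]] = field(default_factory=list)
    parent_id: str = "DEP"


@dataclass
class DerivativeRecord:
    id: str
    substituents: tuple[tuple[str, str], ...]

    @property
    def label(self) -> str:
        return "-".join(f"{site}{grp}" for site, grp in self.substituents)


def paper_scheme() -> SubstitutionScheme:
    """The published 30-derivative catalogue for DEP.

    Four H1 electropositive singles, six C1 small-volume singles, six C2
    hydrophilic mono-substitutions, six C2 doubled substitutions and eight
    H1 x C2 (-COCH3 / -CONH2) double substitutions.
    """
    variants: list[tuple[tuple[str, str], ...]] = []
    variants += [(("H1", g),) for g in H1_ELECTROPOSITIVE]
    variants += [(("C1", g),) for g in C1_SMALL_VOLUME]
    variants += [(("C2", g),) for g in C2_HYDROPHILIC]
    variants += [(("C2", g + "x2"),) for g in C2_HYDROPHILIC]
    for c2 in ("-COCH3", "-CONH2"):
        variants += [(("H1", g), ("C2", c2)) for g in H1_ELECTROPOSITIVE]
    return SubstitutionScheme(
        sites=[("H1", H1_ELECTROPOSITIVE), ("C1", C1_SMALL_VOLUME),
               ("C2", C2_HYDROPHILIC)],
        mode="double",
        variants=variants,
    )


def enumerate_derivatives(scheme: SubstitutionScheme) -> list[DerivativeRecord]:
    """Expand a scheme into derivative records ``<parent>-1 .. <parent>-N``."""
    variants = scheme.variants
    if not variants:
        variants = [((site, g),) for site, groups in scheme.sites
                    for g in groups]
    records = []
    for k, combo in enumerate(variants, start=1):
        for site, grp in combo:
            allowed = _ALLOWED.get(site)
            if allowed is None:
                raise ValueError(f"unknown substitution site {site!r}")
            if grp not in allowed:
                raise ValueError(
                    f"substituent {grp!r} is not in the allowed set for "
                    f"site {site}")
        records.append(DerivativeRecord(f"{scheme.parent_id}-{k}", combo))
    return records


def change_rate(new_value: float, parent_value: float) -> float:
    """Percent change ``100 (new - parent) / parent`` (full precision)."""
    if parent_value == 0:
        raise ZeroDivisionError("parent value is zero; change rate undefined")
    return 100.0 * (new_value - parent_value) / parent_value


def ratio_decomposition(endpoint_change_rates) -> np.ndarray:
    """Shares (in %) of per-endpoint change rates: ``100 r_j / sum r``.

    Defined only when every endpoint improved (all rates positive).
    """
    rates = np.asarray(endpoint_change_rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("ratio decomposition requires all-positive change rates")
    return 100.0 * rates / rates.sum()


def compare_to_weights(ratio, weights) -> float:
    """L1 distance between a ratio triple and entropy weights (both in %).

    ``weights`` may be fractions summing to 1 or percents summing to 100.
    Used to rank derivatives by how closely their per-enzyme improvement
    shares track the entropy weights of the composite index.
    """
    ratio = np.asarray(ratio, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.isclose(weights.sum(), 1.0, atol=0.01):
        weights = 100.0 * weights
    return float(np.abs(ratio - weights).sum())


def derivative_table(predictions: pd.DataFrame, parent_id: str = "DEP",
                     value_columns: list[str] | None = None) -> pd.DataFrame:
    """Compute change rates and ratio triples for a prediction table.

    ``predictions`` must be indexed by derivative id and contain the parent
    row; the first value column is treated as the composite score and the
    remaining ones as per-endpoint scores.  Change rates are computed against
    the parent row at full precision; a ``ratio`` string column (shares of
    the per-endpoint rates, 2 d.p.) is emitted where all endpoint rates are
    positive, else left empty.
    """
    if parent_id not in predictions.index:
        raise KeyError(f"parent row {parent_id!r} missing from predictions")
    if value_columns is None:
        value_columns = [c for c in predictions.columns
                         if pd.api.types.is_numeric_dtype(predictions[c])]
    parent = predictions.loc[parent_id, value_columns]
    out = predictions.copy()
    for col in value_columns:
        out[f"{col}_rate"] = [
            change_rate(v, parent[col]) if idx != parent_id else np.nan
            for idx, v in predictions[col].items()
        ]
    endpoint_cols = value_columns[1:]
    ratios = []
    for idx in predictions.index:
        if idx == parent_id or not endpoint_cols:
            ratios.append("")
            continue
        rates = np.array([out.loc[idx, f"{c}_rate"] for c in endpoint_cols])
        if np.any(rates <= 0):
            ratios.append("")
        else:
            shares = ratio_decomposition(rates)
            ratios.append(":".join(f"{s:.2f}" for s in shares))
    out["ratio"] = ratios
    return out
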