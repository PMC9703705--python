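"""Gas-exchange normalization and source-sink statistics.

Panicle gas exchange is measured in a custom cylindrical chamber that
encloses the whole inflorescence, so the instrument reports whole-organ
fluxes; dividing by the projected panicle area (PPA, in cm², converted to
m²) puts panicle carbon assimilation A and apparent transpiration E on the
same per-unit-area basis as the flag-leaf chamber values.  Water use
efficiency is WUE = A / E.  Percent change contrasts heat-stressed against
control means, percent fertility scores filled versus completely sterile
seeds, and a pairwise Pearson panel links the digital traits to the
gas-exchange traits within a genotype × treatment × timepoint stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FertilityCounts",
    "normalize_flux",
    "wue",
    "percent_change",
    "percent_fertility",
    "pearson_panel",
    "GasExchangeNormalizer",
]

CM2_PER_M2 = 1e4


@dataclass
class FertilityCounts:
    """Counts of fully developed (filled) and completely sterile seeds."""

    n_filled: int
    n_sterile: int

    def __post_init__(self) -> None:
        if self.n_filled < 0 or self.n_sterile < 0:
            raise ValueError("seed counts must be non-negative")
        if self.n_filled + self.n_sterile < 1:
            raise ValueError("at least one scored seed is required")


def normalize_flux(raw_flux: float, area_cm2: float) -> float:
    """Convert a whole-organ flux (amount s⁻¹) to a per-m² flux.

    ``area_cm2`` is the normalization area — the leaf chamber aperture for
    leaves, the PPA for panicles.  The cm²→m² factor is applied once here so
    panicle fluxes match the leaf-chamber per-area convention.
    """
    if area_cm2 <= 0:
        raise ValueError(f"normalization area must be positive, got {area_cm2}")
    return raw_flux / (area_cm2 / CM2_PER_M2)


def wue(A: float, E: float) -> float:
    """Water use efficiency: carbon assimilation over apparent transpiration."""
    if E == 0:
        raise ZeroDivisionError("WUE undefined: transpiration E is zero")
    return A / E


def percent_change(treated: float, control: float) -> float:
    """Signed percent change of a treated value relative to its control."""
    if control == 0:
        raise ZeroDivisionError("percent change undefined: control is zero")
    return 100.0 * (treated - control) / control


def percent_fertility(counts: FertilityCounts) -> float:
    """Percent fertility: 100 × filled / (filled + completely sterile)."""
    return 100.0 * counts.n_filled / (counts.n_filled + counts.n_sterile)


def pearson_panel(
    traits_table: pd.DataFrame, min_replicates: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation panel over a replicate × trait table.

    Returns ``(r, p)``: the symmetric correlation matrix with unit diagonal
    and the matching two-sided p-values from the t-transform of r at n-2
    degrees of freedom.  Pairs with fewer than ``min_replicates`` complete
    observations, or with a zero-variance trait, are flagged NaN rather than
    silently zeroed.  Callers stratify by genotype × treatment × timepoint
    before calling.
    """
    num = traits_table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = num[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < min_replicates:
                continue
            if i == j:
                if np.std(x) > 0:
                    r[i, j], p[i, j] = 1.0, 0.0
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


class GasExchangeNormalizer(TransformerMixin, BaseEstimator):
    """Normalize gas-exchange records to per-area fluxes and derive WUE.

    scikit-learn transformer over a records DataFrame with columns
    ``tissue`` (leaf/panicle), ``A_raw``, ``E_raw``, ``area_cm2`` and
    arbitrary label columns (genotype, treatment, dap, ...).  ``transform``
    appends per-m² ``A`` and ``E`` and ``wue = A/E``.

    Parameters
    ----------
    pre_normalized : bool
        If true, ``A_raw``/``E_raw`` are already per-area (the leaf-chamber
        instrument default) and are copied through unchanged; the area column
        is then ignored for those rows.
    """

    def __init__(self, pre_normalized: bool = False):
        self.pre_normalized = pre_normalized

    def fit(self, X, y=None) -> "GasExchangeNormalizer":
        self._validate(X)
        return self

    @staticmethod
    def _validate(X: pd.DataFrame) -> None:
        required = {"A_raw", "E_raw"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"gas-exchange table missing columns: {sorted(missing)}")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._validate(X)
        out = X.copy()
        if self.pre_normalized:
            out["A"] = out["A_raw"]
            out["E"] = out["E_raw"]
        else:
            if "area_cm2" not in out.columns:
                raise ValueError("raw fluxes need an 'area_cm2' column to normalize by")
            if (out["area_cm2"] <= 0).any():
                raise ValueError("normalization areas must be positive")
            factor = out["area_cm2"] / CM2_PER_M2
            out["A"] = out["A_raw"] / factor
            out["E"] = out["E_raw"] / factor
        with np.errstate(divide="ignore", invalid="ignore"):
            out["wue"] = np.where(out["E"] != 0, out["A"] / out["E"], np.nan)
        return out

    @staticmethod
    def percent_change_table(
        normalized: pd.DataFrame,
        value: str = "A",
        treatment_col: str = "treatment",
        control_label: str = "control",
        group_cols: tuple = ("tissue", "genotype", "dap"),
    ) -> pd.DataFrame:
        """Mean percent change of each treated cell versus its control cell."""
        rows = []
        for keys, grp in normalized.groupby(list(group_cols)):
            ctrl = grp.loc[grp[treatment_col] == control_label, value].mean()
            for treat, sub in grp.groupby(treatment_col):
                if treat == control_label:
                    continue
                rows.append(
                    dict(
                        zip(group_cols, keys if isinstance(keys, tuple) else (keys,)),
                        treatment=treat,
                        percent_change=percent_change(sub[value].mean(), ctrl),
                    )
                )
        return pd.DataFrame(rows)
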