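"""Covariate standardization and collinearity screening.

Site covariates enter the occupancy linear predictor on the z-scale so that
slopes are directly comparable (effect per standard deviation). The stored
transform parameters are reused verbatim when projecting the model onto a
prediction grid, which is the only coherent way to keep the grid and the
training design on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: The six site covariates used on the occupancy side of the model.
SITE_COVARIATES = [
    "tree_cover",
    "dist_water",
    "dist_road",
    "elevation",
    "ruggedness",
    "dist_settlement",
]


class ZeroVarianceError(ValueError):
    """A covariate column is constant and cannot be z-scored."""


class InsufficientDataError(ValueError):
    """Too few rows for the requested statistic."""


@dataclass
class StandardizedCovariates:
    """Z-scored covariate table plus the transform needed to undo/reapply it.

    Attributes
    ----------
    data : pandas.DataFrame
        Copy of the input table with the standardized columns replaced by
        their z-scores; non-numeric columns (station_id, survey, ...) pass
        through untouched.
    transform_params : dict[str, tuple[float, float]]
        ``column -> (mean, sd)`` with the sample SD (n-1 denominator).
    """

    data: pd.DataFrame
    transform_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def inverse_transform(self) -> pd.DataFrame:
        """Recover the raw-scale table from the stored (mean, sd) pairs."""
        out = self.data.copy()
        for col, (mean, sd) in self.transform_params.items():
            out[col] = out[col] * sd + mean
        return out

    def apply_to(self, table: pd.DataFrame) -> pd.DataFrame:
        """Standardize new data (e.g. a prediction grid) with the stored params."""
        out = table.copy()
        for col, (mean, sd) in self.transform_params.items():
            if col in out.columns:
                out[col] = (out[col] - mean) / sd
        return out


def z_transform(
    table: pd.DataFrame, columns: list[str] | None = None
) -> StandardizedCovariates:
    """Z-score covariate columns with the sample SD (n-1 denominator).

    Parameters
    ----------
    table : pandas.DataFrame
        One row per stacked site.
    columns : list of str, optional
        Columns to standardize. Defaults to the six site covariates present
        in the table, plus ``year`` when present (year used as an occupancy
        term is treated as a numeric covariate).

    Raises
    ------
    ZeroVarianceError
        If a requested column is constant, naming the column.
    """
    if columns is None:
        columns = [c for c in SITE_COVARIATES if c in table.columns]
        if (
            "year" in table.columns
            and pd.api.types.is_numeric_dtype(table["year"])
            and table["year"].nunique() > 1
        ):
            columns.append("year")
    data = table.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = np.asarray(table[col], dtype=float)
        if np.unique(x).size < 2:
            raise ZeroVarianceError(f"covariate {col!r} has zero variance")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        # year stays raw (it is a site key); its z-score goes to year_z
        target = "year_z" if col == "year" else col
        data[target] = (x - mean) / sd
        params[target] = (mean, sd)
    return StandardizedCovariates(data=data, transform_params=params)


@dataclass
class CorrelationScreen:
    """Spearman rank-correlation screen between covariate pairs."""

    rho: pd.DataFrame
    threshold: float
    flagged_pairs: list[tuple[str, str, float]]

    @property
    def any_flagged(self) -> bool:
        return len(self.flagged_pairs) > 0


def spearman_screen(
    table: pd.DataFrame,
    threshold: float = 0.70,
    columns: list[str] | None = None,
) -> CorrelationScreen:
    """Flag covariate pairs with Spearman |rho| at or above ``threshold``.

    Rank correlations (ties handled by midranks) are invariant to strictly
    monotone transforms, so the screen looks at monotone association rather
    than linearity.
    """
    if columns is None:
        columns = [c for c in SITE_COVARIATES if c in table.columns]
    sub = table[columns].astype(float)
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need at least 3 rows for a correlation screen, got {len(sub)}"
        )
    if len(columns) == 1:
        rho = np.ones((1, 1))
    elif len(columns) == 2:
        r, _ = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho, _ = stats.spearmanr(sub.to_numpy())
    rho_df = pd.DataFrame(rho, index=columns, columns=columns)
    flagged = []
    for i, a in enumerate(columns):
        for j in range(i + 1, len(columns)):
            b = columns[j]
            r = float(rho_df.iloc[i, j])
            if abs(r) >= threshold:
                flagged.append((a, b, r))
    return CorrelationScreen(rho=rho_df, threshold=threshold, flagged_pairs=flagged)
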