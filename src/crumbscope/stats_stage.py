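"""Cubic-polynomial curve estimation between image metrics and oil content.

Image-derived metrics (porosity, penetrated oil by image analysis) and
the solvent-extraction oil value (POsox) are non-linearly related across
formulations, so each pairwise relationship is summarized by an
ordinary-least-squares cubic

    y = a3 x^3 + a2 x^2 + a1 x + a0,      R^2 = 1 - SS_res / SS_tot

fitted on formulation means (six points per bran/product group: the
control plus five bran levels).  Because the predictor/response
orientation of published "A vs. B" labels is ambiguous, every pair is
fitted in both orientations and both R^2 values are reported.

The design matrix is built on standardized x internally for numerical
stability; coefficients are mapped back to the raw basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CubicFit",
    "fit_cubic",
    "pearson_r",
    "build_relationship_matrix",
    "load_metrics_table",
    "load_reference_metrics",
    "METRIC_COLUMNS",
]

#: Metric columns among which pairwise relationships are fitted.
METRIC_COLUMNS = ("porosity_pct", "poia_pct", "posox_pct")

REQUIRED_COLUMNS = (
    "bran_type",
    "bran_concentration_g",
    "product_type",
    "poia_pct",
    "posox_pct",
    "porosity_pct",
)


@dataclass(frozen=True)
class CubicFit:
    """A fitted third-order polynomial with its goodness of fit.

    Coefficients are in the raw basis, highest order first:
    ``y = a3 x^3 + a2 x^2 + a1 x + a0``.
    """

    a3: float
    a2: float
    a1: float
    a0: float
    r2: float
    n: int
    predictor_name: str = "x"
    response_name: str = "y"

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a3, self.a2, self.a1, self.a0)

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))

    def equation(self) -> str:
        return (
            f"{self.response_name} = {self.a3:+.6g}*x^3 {self.a2:+.6g}*x^2 "
            f"{self.a1:+.6g}*x {self.a0:+.6g}  (x = {self.predictor_name})"
        )


def fit_cubic(
    x,
    y,
    predictor_name: str = "x",
    response_name: str = "y",
) -> CubicFit:
    """Ordinary-least-squares cubic polynomial fit.

    Requires at least five points (four parameters) and a
    non-degenerate predictor.  R^2 is computed on the fitting data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 points to fit a cubic, got {n}")
    sd = x.std()
    if sd == 0:
        raise ValueError("predictor is constant: cubic fit undefined")
    if np.unique(x).size < 4:
        raise np.linalg.LinAlgError(
            "fewer than 4 distinct predictor values: design is rank deficient"
        )

    # standardized basis for conditioning; map back to raw coefficients
    z = (x - x.mean()) / sd
    cz = np.polyfit(z, y, 3)
    poly_z = np.polynomial.Polynomial(cz[::-1])
    shift = np.polynomial.Polynomial([-x.mean() / sd, 1.0 / sd])
    poly_raw = poly_z(shift)
    coeffs = np.zeros(4)
    coeffs[: poly_raw.coef.size] = poly_raw.coef  # ascending order
    a0, a1, a2, a3 = coeffs

    yhat = np.polyval([a3, a2, a1, a0], x)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CubicFit(
        a3=float(a3),
        a2=float(a2),
        a1=float(a1),
        a0=float(a0),
        r2=r2,
        n=n,
        predictor_name=predictor_name,
        response_name=response_name,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    Raises on fewer than three points or a zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    from scipy import stats

    return float(stats.pearsonr(x, y).statistic)


def load_metrics_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a metrics table CSV.

    Required columns: ``bran_type, bran_concentration_g, product_type,
    poia_pct, posox_pct, porosity_pct``; an ``fd`` column is optional.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table is missing columns {missing}")
    for col in METRIC_COLUMNS:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{col} must lie in [0, 100]")
    if "fd" in df.columns:
        vals = df["fd"].dropna()
        if ((vals < 2) | (vals > 3)).any():
            raise ValueError("fd must lie in [2, 3]")
    return df


def load_reference_metrics() -> pd.DataFrame:
    """Formulation-mean reference metrics shipped with the package.

    Porosity, POia and POsox formulation means (with the crust
    roughness index ``fd``) for oat- and wheat-bran dough and batter at
    0-20 g bran, as published for the fried-dough study this package
    operationalizes.  The control row is repeated within each bran
    group because the groups were measured in separate batches.
    """
    ref = resources.files("crumbscope").joinpath("data/table1_metrics.csv")
    with resources.as_file(ref) as path:
        return load_metrics_table(path)


def build_relationship_matrix(
    table: pd.DataFrame,
    group_cols: tuple[str, str] = ("bran_type", "product_type"),
) -> pd.DataFrame:
    """All pairwise cubic fits per formulation group, both orientations.

    For each group (bran type x product type, needing at least five
    formulations) the three pairs among porosity, POia and POsox are
    each fitted with either variable as predictor.  Degenerate fits
    (constant predictor) are flagged with NaN coefficients rather than
    raised.

    Returns a tidy frame with one row per (group, predictor, response).
    """
    missing = [c for c in (*group_cols, *METRIC_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table is missing columns {missing}")

    records = []
    for keys, grp in table.groupby(list(group_cols), sort=True):
        if len(grp) < 5:
            raise ValueError(
                f"group {keys} has {len(grp)} formulations; at least 5 required"
            )
        for i, a in enumerate(METRIC_COLUMNS):
            for b in METRIC_COLUMNS[i + 1 :]:
                for pred, resp in ((a, b), (b, a)):
                    base = dict(zip(group_cols, keys))
                    base.update(predictor=pred, response=resp, n=len(grp))
                    try:
                        fit = fit_cubic(
                            grp[pred].to_numpy(),
                            grp[resp].to_numpy(),
                            predictor_name=pred,
                            response_name=resp,
                        )
                        base.update(
                            a3=fit.a3, a2=fit.a2, a1=fit.a1, a0=fit.a0,
                            r2=fit.r2, degenerate=False,
                        )
                    except (ValueError, np.linalg.LinAlgError):
                        base.update(
                            a3=np.nan, a2=np.nan, a1=np.nan, a0=np.nan,
                            r2=np.nan, degenerate=True,
                        )
                    records.append(base)
    return pd.DataFrame.from_records(records)
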