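"""Absolute protein quantification from quantitative western blots.

A dilution series of a recombinant standard (known molecule numbers) gives a
linear standard curve intensity = a + b * molecules.  An unknown band's
molecule count follows by inverse regression, with a first-order
(delta-method) standard error propagated from the coefficient covariance and
the residual scatter.  The endogenous abundance per cell then follows from
the signal ratio between the endogenous and the ectopically expressed
protein detected on the same blot, with coefficients of variation combined
in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StandardCurve", "AbundanceEstimate", "InversePrediction",
           "fit_standard_curve", "inverse_predict", "endogenous_abundance"]


@dataclass(frozen=True)
class StandardCurve:
    slope: float          # intensity per molecule
    intercept: float      # intensity
    residual_sd: float    # intensity units, n-2 degrees of freedom
    n: int
    covariance: np.ndarray  # 2x2, order (intercept, slope)

    def predict(self, molecules):
        return self.intercept + self.slope * np.asarray(molecules, dtype=float)


@dataclass(frozen=True)
class InversePrediction:
    molecules: float
    se: float
    valid: bool  # False when the intensity does not exceed the intercept


@dataclass(frozen=True)
class AbundanceEstimate:
    molecules_per_cell: float
    cv: float

    def __post_init__(self):
        if self.molecules_per_cell <= 0 or self.cv < 0:
            raise ValueError("abundance must be positive with nonnegative CV")


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least squares line through (molecules, intensity) pairs.

    Requires at least three points with distinct molecule values; the
    residual SD uses n-2 degrees of freedom and the coefficient covariance
    is ``sigma^2 (X'X)^{-1}``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three (molecules, intensity) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("molecule values are degenerate (all equal)")
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(x) - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return StandardCurve(slope=float(coef[1]), intercept=float(coef[0]),
                         residual_sd=float(np.sqrt(sigma2)), n=len(x),
                         covariance=cov)


def inverse_predict(curve: StandardCurve, intensity: float) -> InversePrediction:
    """Molecules from a measured intensity via the fitted standard curve.

    Point estimate ``(intensity - intercept) / slope``; the SE combines the
    new observation's residual scatter with the coefficient covariance by
    first-order error propagation:

        Var(x) = (sigma^2 + V_aa + x^2 V_bb + 2 x V_ab) / slope^2.

    Estimates at or below zero are flagged invalid.
    """
    if curve.slope <= 0:
        raise ValueError("inverse prediction requires a positive slope")
    x_hat = (float(intensity) - curve.intercept) / curve.slope
    V = curve.covariance
    var = (curve.residual_sd ** 2 + V[0, 0] + x_hat ** 2 * V[1, 1]
           + 2.0 * x_hat * V[0, 1]) / curve.slope ** 2
    # roundoff in (intensity - intercept) is magnified by 1/slope
    tiny = 1e-9 * (abs(curve.intercept) + abs(float(intensity))) / curve.slope
    return InversePrediction(molecules=x_hat, se=float(np.sqrt(max(var, 0.0))),
                             valid=x_hat > tiny)


def endogenous_abundance(ratio_endo_to_ectopic: float,
                         ectopic_molecules_in_lysate: float, n_cells: float,
                         cvs=(0.0, 0.0, 0.0)) -> AbundanceEstimate:
    """Endogenous molecules per cell from the endogenous/ectopic signal ratio.

    ``molecules/cell = ratio * ectopic_molecules / n_cells``; the CV of the
    estimate combines the input CVs in quadrature.
    """
    if ratio_endo_to_ectopic <= 0 or ectopic_molecules_in_lysate <= 0 \
            or n_cells <= 0:
        raise ValueError("all quantification inputs must be positive")
    value = ratio_endo_to_ectopic * ectopic_molecules_in_lysate / n_cells
    cv = float(np.sqrt(np.sum(np.asarray(cvs, dtype=float) ** 2)))
    return AbundanceEstimate(molecules_per_cell=float(value), cv=cv)
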