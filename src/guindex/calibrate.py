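"""Retention-time → glucose-unit-index calibration curves.

The glucose unit index (GUI) of each ladder rung is regressed on its
retention time with either a polynomial (default cubic) or a
logarithmic model: y = b0 + b1 f(x) + ... + bn f(x)^n with f(x) = x or
log(x).  The least-squares coefficients solve the normal equations
b = (X^T X)^-1 X^T y by Gauss-Jordan elimination; the design abscissa
is mean-centered and scaled first because a raw minute-scale cubic
Vandermonde matrix is badly conditioned.  Reported coefficients are
back-transformed to the raw time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationModel", "CalibrationError", "fit", "rt_to_gui", "gauss_jordan_solve"]


class CalibrationError(ValueError):
    """Calibration cannot proceed (too few rungs, singular system, ...)."""


@dataclass(frozen=True)
class CalibrationModel:
    kind: str  # "polynomial" | "logarithmic"
    order: int
    coefficients: np.ndarray  # b0..bn on the raw (uncentered) abscissa
    r_squared: float
    fit_points: tuple[tuple[float, float], ...]  # (rt, gu)
    # internal, numerically stable representation
    _center: float = 0.0
    _scale: float = 1.0
    _scaled_coefficients: np.ndarray | None = None

    @property
    def rt_range(self) -> tuple[float, float]:
        rts = [p[0] for p in self.fit_points]
        return (min(rts), max(rts))


def gauss_jordan_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a x = b by Gauss-Jordan elimination with partial pivoting."""
    a = np.array(a, dtype=float)
    b = np.array(b, dtype=float)
    n = a.shape[0]
    aug = np.hstack([a, b.reshape(n, -1)])
    for col in range(n):
        piv = col + int(np.argmax(np.abs(aug[col:, col])))
        if np.abs(aug[piv, col]) < 1e-12 * max(1.0, np.abs(aug).max()):
            raise CalibrationError(
                "normal equations are singular or ill-conditioned "
                "(duplicate retention times or fit order too high)"
            )
        if piv != col:
            aug[[col, piv]] = aug[[piv, col]]
        aug[col] /= aug[col, col]
        for r in range(n):
            if r != col:
                aug[r] -= aug[r, col] * aug[col]
    return aug[:, n:].squeeze(axis=-1) if b.ndim == 1 else aug[:, n:]


def fit(
    points: list[tuple[float, float]],
    kind: str = "polynomial",
    order: int = 3,
) -> CalibrationModel:
    """Least-squares calibration fit of GUI against retention time.

    ``points`` are (rt minutes, gu) pairs; requires at least order+1
    distinct retention times.  The logarithmic kind substitutes log(rt)
    for rt in the design (all rts must be positive).
    """
    if order < 1:
        raise CalibrationError("fit order must be >= 1")
    if kind not in ("polynomial", "logarithmic"):
        raise CalibrationError(f"unknown fit kind {kind!r}")
    pts = [(float(r), float(g)) for r, g in points]
    if len({r for r, _ in pts}) < order + 1:
        raise CalibrationError(
            f"need at least {order + 1} distinct retention times for order "
            f"{order}, got {len({r for r, _ in pts})}"
        )
    x = np.array([r for r, _ in pts])
    y = np.array([g for _, g in pts])
    if kind == "logarithmic":
        if np.any(x <= 0):
            raise CalibrationError("logarithmic fit requires all rts > 0")
        x = np.log(x)

    center = float(x.mean())
    scale = float(x.std()) or 1.0
    z = (x - center) / scale
    design = np.vander(z, order + 1, increasing=True)
    beta_z = gauss_jordan_solve(design.T @ design, design.T @ y)

    pred = design @ beta_z
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # back-transform to the raw abscissa: p(z) with z = (x - c)/s
    p = np.polynomial.Polynomial(beta_z)
    raw = p(np.polynomial.Polynomial([-center / scale, 1.0 / scale]))
    coef = np.zeros(order + 1)
    coef[: len(raw.coef)] = raw.coef

    return CalibrationModel(
        kind=kind,
        order=order,
        coefficients=coef,
        r_squared=r2,
        fit_points=tuple(pts),
        _center=center,
        _scale=scale,
        _scaled_coefficients=beta_z,
    )


def rt_to_gui(model: CalibrationModel, rt: float | np.ndarray) -> float | np.ndarray:
    """Map retention time (minutes) to a calibrated GUI value.

    Extrapolation beyond the fitted rt range is permitted; callers that
    report results flag it via ``is_extrapolation``.
    """
    x = np.asarray(rt, dtype=float)
    if model.kind == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic model requires rt > 0")
        x = np.log(x)
    z = (x - model._center) / model._scale
    out = np.polynomial.polynomial.polyval(z, model._scaled_coefficients)
    return float(out) if np.isscalar(rt) else out


def is_extrapolation(model: CalibrationModel, rt: float) -> bool:
    lo, hi = model.rt_range
    return rt < lo or rt > hi
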