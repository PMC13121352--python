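"""Busscher power-law model of soil penetration resistance.

Penetration resistance is modelled as Qp = a * BD^b * w^c, with Qp in MPa,
BD the bulk density (Mg m^-3) and w the water content. On sensible soils
b > 0 (denser soil resists more) and c < 0 (wetter soil resists less).

The water-content variable is gravimetric (kg kg^-1) by default, matching
the published per-structure parameter sets below; a volumetric variant can
be selected when fitting one's own data.

Fitting is nonlinear least squares (Levenberg-Marquardt, i.e. damped
Gauss-Newton) initialised from the exact ordinary-least-squares solution of
the log-linear form log Qp = log a + b log BD + c log w, which shares the
power law's fixed points and is itself the exact solution on noise-free
data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DegenerateDesignError, DomainError, InvalidInputError
from .soil_state import Structure

#: Published per-structure parameter sets (a, b, c) for the study Oxisol.
FIELD_BUSSCHER_ABC = (0.0201, 4.5602, -3.3804)
PACKED_BUSSCHER_ABC = (0.0286, 2.8134, -3.2738)


@dataclass
class BusscherParams:
    """Fitted (a, b, c) with diagnostics.

    ``r2`` follows the ratio convention 1 - SS_resid/SS_regression used in
    the published parameter tables; ``r2_classic`` is the conventional
    1 - SSE/SST. ``rmse`` is in MPa.
    """

    a: float
    b: float
    c: float
    structure: Optional[Structure] = None
    se_a: Optional[float] = None
    se_b: Optional[float] = None
    se_c: Optional[float] = None
    r2: Optional[float] = None
    r2_classic: Optional[float] = None
    rmse: Optional[float] = None
    water_content_variable: str = "gravimetric"
    n: Optional[int] = None

    def __post_init__(self):
        if self.a <= 0:
            raise InvalidInputError("Busscher coefficient a must be > 0")
        if self.b <= 0 or self.c >= 0:
            warnings.warn(
                f"unusual Busscher exponents (b={self.b}, c={self.c}); on sensible "
                "soils b > 0 and c < 0",
                stacklevel=2,
            )

    def to_json(self) -> str:
        d = asdict(self)
        if self.structure is not None:
            d["structure"] = self.structure.value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BusscherParams":
        d = json.loads(text)
        if d.get("structure"):
            d["structure"] = Structure.coerce(d["structure"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(**d)


FIELD_BUSSCHER = BusscherParams(*FIELD_BUSSCHER_ABC, structure=Structure.FIELD)
PACKED_BUSSCHER = BusscherParams(*PACKED_BUSSCHER_ABC, structure=Structure.PACKED)


def predict_qp(params: BusscherParams, bulk_density, water_content):
    """Calculated penetration resistance Qp = a * BD^b * w^c (MPa).

    Vectorised over bulk_density and water_content. w must be strictly
    positive: with c < 0 the power law is singular at w = 0.
    """
    bd = np.asarray(bulk_density, dtype=float)
    w = np.asarray(water_content, dtype=float)
    if np.any(bd <= 0):
        raise InvalidInputError("bulk_density must be > 0")
    if np.any(w <= 0):
        raise DomainError(
            "water_content must be > 0: the power law is singular at w = 0 "
            "because the water-content exponent is negative"
        )
    out = params.a * bd**params.b * w**params.c
    return float(out) if out.ndim == 0 else out


def _loglinear_ols(bd: np.ndarray, w: np.ndarray, qp: np.ndarray) -> np.ndarray:
    """Exact OLS solution of log qp = log a + b log BD + c log w."""
    X = np.column_stack([np.ones_like(bd), np.log(bd), np.log(w)])
    coef, *_ = np.linalg.lstsq(X, np.log(qp), rcond=None)
    return np.array([np.exp(coef[0]), coef[1], coef[2]])


def fit_busscher(
    bulk_density: Sequence[float],
    water_content: Sequence[float],
    measured_qp: Sequence[float],
    structure: Optional[Structure] = None,
    init: Optional[tuple] = None,
    seed: int = 0,
    water_content_variable: str = "gravimetric",
    xtol: float = 1e-10,
    max_iter: int = 200,
) -> BusscherParams:
    """Fit (a, b, c) by Levenberg-Marquardt on the MPa scale.

    Requires at least 6 samples spanning at least 2 distinct bulk densities
    and 2 distinct water contents; otherwise the three parameters are not
    identifiable. ``init`` overrides the default log-linear OLS start.
    ``seed`` is accepted for interface uniformity; the fit itself is
    deterministic given data and start.
    """
    del seed  # deterministic: single start from the log-linear OLS solution
    bd = np.asarray(bulk_density, dtype=float)
    w = np.asarray(water_content, dtype=float)
    qp = np.asarray(measured_qp, dtype=float)
    if not (bd.shape == w.shape == qp.shape):
        raise InvalidInputError("bulk_density, water_content and measured_qp must have equal length")
    if bd.size < 6:
        raise DegenerateDesignError(f"need >= 6 samples to fit 3 parameters, got {bd.size}")
    if np.unique(bd).size < 2 or np.unique(w).size < 2:
        raise DegenerateDesignError("need >= 2 distinct bulk densities and >= 2 distinct water contents")
    if np.any(qp <= 0) or np.any(bd <= 0) or np.any(w <= 0):
        raise InvalidInputError("bulk density, water content and Qp must all be positive")

    x0 = np.asarray(init, dtype=float) if init is not None else _loglinear_ols(bd, w, qp)
    if x0[0] <= 0:
        x0[0] = qp.mean()

    def resid(p):
        return p[0] * bd ** p[1] * w ** p[2] - qp

    sol = least_squares(resid, x0, method="lm", xtol=xtol, ftol=1e-12, gtol=1e-12, max_nfev=max_iter * 10)
    if not sol.success:
        raise ConvergenceError(
            f"Busscher fit did not converge: {sol.message}", last_iterate=tuple(sol.x)
        )
    a, b, c = sol.x

    res = resid(sol.x)
    n, p = qp.size, 3
    sse = float(res @ res)
    pred = predict_qp(BusscherParams(max(a, np.finfo(float).tiny), b, c), bd, w)
    ss_reg = float(np.sum((pred - qp.mean()) ** 2))
    sst = float(np.sum((qp - qp.mean()) ** 2))
    # standard errors from the Jacobian at the solution
    se = np.full(3, np.nan)
    if n > p:
        s2 = sse / (n - p)
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass
    return BusscherParams(
        a=float(a),
        b=float(b),
        c=float(c),
        structure=structure,
        se_a=float(se[0]),
        se_b=float(se[1]),
        se_c=float(se[2]),
        r2=1.0 - sse / ss_reg if ss_reg > 0 else None,
        r2_classic=1.0 - sse / sst if sst > 0 else None,
        rmse=float(np.sqrt(sse / n)),
        water_content_variable=water_content_variable,
        n=n,
    )
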