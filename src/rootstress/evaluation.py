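"""Model agreement metrics and the fit/validation split protocol.

Metrics follow the usual agronomy conventions: RMSE (response units, ideal
0), coefficient of residual mass CRM = (sum O - sum P)/sum O (ideal 0;
positive = the model underestimates), Pearson correlation r (ideal 1), and
the classic Willmott index of agreement

    d = 1 - sum (P_i - O_i)^2 / sum (|P_i - Obar| + |O_i - Obar|)^2,

which is bounded above by 1 and reaches 1 only when predictions equal
observations. Standard deviations in r use the population (1/n) convention
in both numerator and denominator, so the ratio is convention-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedMetricError


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise InvalidInputError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size == 0:
        raise InvalidInputError("empty input")
    return o, p


def rmse(observed, predicted) -> float:
    """Root mean square error, sqrt(mean((P - O)^2))."""
    o, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def crm(observed, predicted) -> float:
    """Coefficient of residual mass, (sum O - sum P) / sum O."""
    o, p = _pair(observed, predicted)
    so = o.sum()
    if so == 0:
        raise UndefinedMetricError("CRM undefined: observed values sum to zero")
    return float((so - p.sum()) / so)


def pearson_r(observed, predicted) -> float:
    """Pearson correlation, cov(O, P) / (sd(O) sd(P))."""
    o, p = _pair(observed, predicted)
    if o.size < 2:
        raise InvalidInputError("need at least 2 pairs")
    so, sp = o.std(), p.std()
    if so == 0 or sp == 0:
        raise UndefinedMetricError("correlation undefined: zero variance")
    cov = np.mean((o - o.mean()) * (p - p.mean()))
    return float(np.clip(cov / (so * sp), -1.0, 1.0))


def willmott_d(observed, predicted) -> float:
    """Classic Willmott index of agreement (bounded above by 1)."""
    o, p = _pair(observed, predicted)
    obar = o.mean()
    denom = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    if denom == 0:
        raise UndefinedMetricError("Willmott d undefined: zero potential error")
    return float(1.0 - np.sum((p - o) ** 2) / denom)


@dataclass
class EvaluationReport:
    """The four agreement metrics on a held-out set.

    A metric that is undefined on the data (e.g. r for a constant
    predictor) is stored as None and its name listed in ``flags``.
    """

    n: int
    rmse: Optional[float]
    crm: Optional[float]
    r: Optional[float]
    d: Optional[float]
    flags: list = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = []

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def evaluate_predictions(observed, predicted) -> EvaluationReport:
    """All four metrics at once; undefined metrics are flagged, not zeroed."""
    o, p = _pair(observed, predicted)
    values, flags = {}, []
    for name, fn in (("rmse", rmse), ("crm", crm), ("r", pearson_r), ("d", willmott_d)):
        try:
            values[name] = fn(o, p)
        except UndefinedMetricError:
            values[name] = None
            flags.append(name)
    return EvaluationReport(n=o.size, flags=flags, **values)


def evaluate_model(
    predict: Callable[[pd.DataFrame], np.ndarray],
    validation: pd.DataFrame,
    observed_col: str,
) -> EvaluationReport:
    """Evaluate a fitted model on a held-out table.

    ``predict`` maps the validation frame to a prediction vector; the
    observations are read from ``observed_col``.
    """
    if len(validation) == 0:
        raise InvalidInputError("validation set is empty")
    if observed_col not in validation.columns:
        raise InvalidInputError(f"column {observed_col!r} not in validation table")
    return evaluate_predictions(validation[observed_col].to_numpy(dtype=float), np.asarray(predict(validation), dtype=float))


def split_fit_validate(
    samples: pd.DataFrame,
    fit_fraction: float = 0.7,
    stratify_by: Optional[str] = "matric_potential",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified fit/validation partition.

    Within each stratum a seeded permutation assigns round(fraction * n)
    rows to the fit set, so per-stratum proportions are within one sample of
    the target and the partition is disjoint, exhaustive and reproducible.
    Strata smaller than 2 go wholly to the fit set. ``stratify_by=None``
    treats the whole table as one stratum.
    """
    if not (0 < fit_fraction < 1):
        raise InvalidInputError("fit_fraction must be in (0, 1)")
    if stratify_by is not None and stratify_by not in samples.columns:
        raise InvalidInputError(f"stratification column {stratify_by!r} not present")
    rng = np.random.default_rng(seed)
    fit_idx = []
    groups = list(
        samples.groupby(stratify_by, sort=True).indices.items()
        if stratify_by is not None
        else [(None, np.arange(len(samples)))]
    )
    small = [(k, np.asarray(i)) for k, i in groups if np.asarray(i).size < 2]
    big = [(k, np.asarray(i)) for k, i in groups if np.asarray(i).size >= 2]
    for _, idx in small:  # too small to split: whole stratum to the fit set
        fit_idx.extend(idx.tolist())
    if big:
        sizes = np.array([idx.size for _, idx in big])
        quotas = fit_fraction * sizes
        base = np.clip(np.floor(quotas).astype(int), 1, sizes - 1)
        # largest-remainder allocation so the overall split hits
        # round(fraction * n) while each stratum stays within one sample
        # of its own target
        target_total = int(round(fit_fraction * sizes.sum()))
        order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
        for j in order:
            if base.sum() >= target_total:
                break
            if base[j] < sizes[j] - 1:
                base[j] += 1
        for j in order[::-1]:
            if base.sum() <= target_total:
                break
            if base[j] > 1:
                base[j] -= 1
        for (_, idx), n_fit in zip(big, base):
            perm = rng.permutation(idx)
            fit_idx.extend(perm[:n_fit].tolist())
    mask = np.zeros(len(samples), dtype=bool)
    mask[fit_idx] = True
    return samples.iloc[mask.nonzero()[0]].copy(), samples.iloc[(~mask).nonzero()[0]].copy()
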