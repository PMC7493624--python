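"""Model-evaluation statistics for emergence courses.

Predicted and observed cumulative emergence (in % of sown seeds) are
compared with three standard crop-model criteria:

* model efficiency ``EF = 1 - sum((P - O)^2) / sum((O - Obar)^2)``,
  1 for a perfect prediction, 0 when the model does no better than the
  observed mean, unbounded below;
* root mean square error of prediction ``RMSEP = sqrt(mean((P - O)^2))``,
  in the units of the compared variable;
* mean deviation ``MD = mean(P - O)``; a negative value indicates that
  predictions sit mostly below the observations.

Final emergence rates are additionally summarised into quality classes:
poor (< 50%), good (50-75%) and very good (> 75%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError


@dataclass
class EvaluationStats:
    EF: float
    RMSEP: float
    MD: float
    n: int


@dataclass
class EmergenceClassSummary:
    """Frequencies (%) of final-emergence quality classes."""

    poor: float        # < 50 %
    good: float        # 50-75 %
    very_good: float   # > 75 %

    def as_dict(self) -> dict[str, float]:
        return {"poor": self.poor, "good": self.good, "very_good": self.very_good}


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    O = np.asarray(observed, dtype=float)
    P = np.asarray(predicted, dtype=float)
    if O.shape != P.shape or O.ndim != 1:
        raise InputError("observed and predicted must be 1-D series of equal length")
    return O, P


def model_efficiency(observed, predicted) -> float:
    """EF = 1 - sum((P-O)^2) / sum((O-Obar)^2)."""
    O, P = _paired(observed, predicted)
    if len(O) < 2:
        raise InputError("EF needs at least 2 paired points")
    denom = float(np.sum((O - O.mean()) ** 2))
    if denom == 0.0:
        raise InputError("EF undefined: observed values have zero variance")
    return float(1.0 - np.sum((P - O) ** 2) / denom)


def rmsep(observed, predicted) -> float:
    """Root mean square error of prediction."""
    O, P = _paired(observed, predicted)
    if len(O) < 1:
        raise InputError("RMSEP needs at least 1 paired point")
    return float(np.sqrt(np.mean((P - O) ** 2)))


def mean_deviation(observed, predicted) -> float:
    """Mean of (predicted - observed); negative = model under-predicts."""
    O, P = _paired(observed, predicted)
    if len(O) < 1:
        raise InputError("MD needs at least 1 paired point")
    return float(np.mean(P - O))


def evaluate_course(observed, predicted) -> EvaluationStats:
    """All three criteria for one predicted-vs-observed emergence course."""
    O, P = _paired(observed, predicted)
    return EvaluationStats(
        EF=model_efficiency(O, P),
        RMSEP=rmsep(O, P),
        MD=mean_deviation(O, P),
        n=len(O),
    )


def classify_emergence(final_rates: Sequence[float]) -> EmergenceClassSummary:
    """Frequencies of poor (<50), good (50-75) and very good (>75) rates.

    The class boundaries 50 and 75 belong to "good" (the poor class is
    strictly below 50%).
    """
    rates = np.asarray(final_rates, dtype=float)
    if rates.size == 0:
        raise InputError("empty rate list")
    if np.any((rates < 0) | (rates > 100)):
        raise InputError("rates must lie in [0, 100]")
    n = rates.size
    poor = float(100.0 * np.sum(rates < 50) / n)
    good = float(100.0 * np.sum((rates >= 50) & (rates <= 75)) / n)
    very_good = float(100.0 * np.sum(rates > 75) / n)
    return EmergenceClassSummary(poor=poor, good=good, very_good=very_good)


def align_courses(
    observed_at_days: Sequence[tuple[int, float]],
    simulated_daily: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Pair field observations at irregular days with the daily simulated curve.

    ``observed_at_days`` holds (day, observed value) pairs, day 1 being the
    first day after sowing; the simulated value is read directly at each
    observation day (no interpolation is needed at daily resolution).
    Returns (observed, predicted) arrays sorted by day.
    """
    sim = np.asarray(simulated_daily, dtype=float)
    pairs = sorted(observed_at_days)
    if not pairs:
        return np.array([]), np.array([])
    O, P = [], []
    for day, value in pairs:
        if day < 1 or day > len(sim):
            raise InputError(f"observation day {day} beyond the simulated horizon")
        O.append(value)
        P.append(sim[day - 1])
    return np.asarray(O), np.asarray(P)


def cumulative_degree_days(daily_mean_temp, Tb: float) -> np.ndarray:
    """Cumulative degree-days above ``Tb`` since sowing.

    Days colder than the base temperature contribute zero (clamped), so the
    cumulative sum never decreases.
    """
    T = np.asarray(daily_mean_temp, dtype=float)
    return np.cumsum(np.clip(T - Tb, 0.0, None))
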