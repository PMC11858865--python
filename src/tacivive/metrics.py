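"""PK summary metrics (AUC0-144h, Cmax, Tmax) and the fold-error criterion.

Model performance is judged on study means: the fold error of a metric is the
ratio of the larger of (mean observed, mean simulated) to the smaller, so it
is always >= 1 and symmetric in its arguments.  A fold error <= 1.25 denotes
good model performance, <= 2 acceptable, and anything larger a failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pbpk import PKProfile

__all__ = [
    "PKMetrics",
    "compute_metrics",
    "fold_error",
    "performance_class",
    "summarize_metrics",
    "metrics_table",
]

AUC_WINDOW_H = 144.0


@dataclass(frozen=True)
class PKMetrics:
    """Per-profile exposure metrics.

    ``truncated`` flags a profile shorter than the 144-h window (metrics are
    then computed on the available span).
    """

    auc_0_144: float  # ng·h/mL
    cmax: float       # ng/mL
    tmax: float       # h
    truncated: bool = False


def compute_metrics(profile: PKProfile) -> PKMetrics:
    """Trapezoidal AUC over [0, 144] h, peak concentration and its (first)
    time of occurrence."""
    t = profile.times
    c = profile.conc_blood
    truncated = t[-1] < AUC_WINDOW_H - 1e-9
    mask = t <= AUC_WINDOW_H + 1e-9
    auc = float(np.trapezoid(c[mask], t[mask]))
    i_max = int(np.argmax(c))  # argmax returns the first maximum: tie -> earlier
    return PKMetrics(auc_0_144=auc, cmax=float(c[i_max]), tmax=float(t[i_max]),
                     truncated=bool(truncated))


def fold_error(mean_obs: float, mean_sim: float) -> float:
    """Ratio of the larger to the smaller of two (positive) study means,
    rounded to two decimals."""
    if mean_obs <= 0 or mean_sim <= 0:
        raise ValueError("fold_error requires positive means")
    return round(max(mean_obs, mean_sim) / min(mean_obs, mean_sim), 2)


def performance_class(fe: float) -> str:
    """Classify a fold error: <=1.25 good, <=2 acceptable, else fail."""
    if fe < 1:
        raise ValueError("fold error must be >= 1")
    if fe <= 1.25:
        return "good"
    if fe <= 2.0:
        return "acceptable"
    return "fail"


def summarize_metrics(profiles: Iterable[PKProfile]) -> pd.DataFrame:
    """Per-subject metrics plus a mean/sd summary, as a tidy frame."""
    rows = []
    for p in profiles:
        m = compute_metrics(p)
        rows.append({"subject_id": p.subject_id, "auc_0_144": m.auc_0_144,
                     "cmax": m.cmax, "tmax": m.tmax})
    return pd.DataFrame(rows)


def metrics_table(
    observed: pd.DataFrame,
    simulated: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Build a study-level report: mean +/- SD per metric for the observed
    study and each simulation arm, with fold errors and performance classes.

    ``observed`` and each entry of ``simulated`` are frames as returned by
    :func:`summarize_metrics`.
    """
    metrics = ["auc_0_144", "cmax", "tmax"]
    rows = []
    for metric in metrics:
        obs_mean = observed[metric].mean()
        row = {"metric": metric,
               "observed_mean": obs_mean,
               "observed_sd": observed[metric].std(ddof=1)}
        for arm, frame in simulated.items():
            sim_mean = frame[metric].mean()
            fe = fold_error(obs_mean, sim_mean)
            row[f"{arm}_mean"] = sim_mean
            row[f"{arm}_sd"] = frame[metric].std(ddof=1)
            row[f"{arm}_fold_error"] = fe
            row[f"{arm}_class"] = performance_class(fe)
        rows.append(row)
    return pd.DataFrame(rows)
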