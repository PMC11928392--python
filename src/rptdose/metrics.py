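"""Discrepancy metrics between the two dosimetry methods.

Given per-patient dose pairs (STPD vs MTPD, the reference), three
summary metrics are reported per organ and cycle:

    RMSE = sqrt(mean((STPD_i - MTPD_i)^2))                       [Gy]
    MPE  = mean((STPD_i - MTPD_i) / MTPD_i) * 100                [%]
    RPD_i = (STPD_i - MTPD_i) / ((STPD_i + MTPD_i)/2) * 100      [%]

with the tabulated RPD being the arithmetic mean of the pairwise
values.  Pairs whose STPD was dropped by the Hänscheid window filter
are excluded from that cycle's metrics and counted in an attrition log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rptdose.metrics")


class UnpairedInputError(ValueError):
    """STPD and MTPD vectors differ in length."""


@dataclass(frozen=True)
class MetricReport:
    """STPD-vs-MTPD discrepancy summary for one organ × cycle."""

    organ: str
    cycle: int
    rmse: float
    mpe: float
    rpd: float
    pd_values: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def _paired(stpd, mtpd) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(stpd, dtype=float)
    m = np.asarray(mtpd, dtype=float)
    if s.shape != m.shape or s.ndim != 1:
        raise UnpairedInputError("unpaired input")
    if s.size == 0:
        raise UnpairedInputError("unpaired input")
    return s, m


def rmse(stpd, mtpd) -> float:
    """Root-mean-squared error between paired dose vectors, Gy."""
    s, m = _paired(stpd, mtpd)
    return float(np.sqrt(np.mean((s - m) ** 2)))


def mpe(stpd, mtpd) -> float:
    """Mean percentage error relative to MTPD, percent."""
    s, m = _paired(stpd, mtpd)
    if np.any(m == 0):
        raise ZeroDivisionError("undefined relative error")
    return float(np.mean((s - m) / m) * 100.0)


def rpd_pairs(stpd, mtpd) -> np.ndarray:
    """Per-pair relative percentage difference (symmetric denominator)."""
    s, m = _paired(stpd, mtpd)
    denom = (s + m) / 2.0
    if np.any(denom == 0):
        raise ZeroDivisionError("undefined RPD")
    return (s - m) / denom * 100.0


def rpd(stpd, mtpd) -> float:
    """Mean relative percentage difference over pairs, percent."""
    return float(np.mean(rpd_pairs(stpd, mtpd)))


def percentage_difference_series(doses: pd.DataFrame, organ: str,
                                 cumulative: bool = True) -> pd.DataFrame:
    """Per-cycle distribution of (STPD−MTPD)/MTPD·100 for one organ.

    Returns one row per cycle with mean, standard deviation and count —
    the numbers behind an error-bar plot of STPD deviation over cycles.
    Cycles with no complete pair are omitted.
    """
    rows = []
    for cycle, pairs in _iter_pairs(doses, organ, cumulative):
        pd_vals = (pairs["STPD"] - pairs["MTPD"]) / pairs["MTPD"] * 100.0
        rows.append({
            "organ": organ, "cycle": cycle,
            "pd_mean": float(pd_vals.mean()),
            "pd_sd": float(pd_vals.std(ddof=1)) if len(pd_vals) > 1 else 0.0,
            "n": int(len(pd_vals)),
        })
    return pd.DataFrame(rows, columns=["organ", "cycle", "pd_mean", "pd_sd", "n"])


def _iter_pairs(doses: pd.DataFrame, organ: str, cumulative: bool):
    """Yield (cycle, wide frame of per-patient STPD/MTPD dose pairs)."""
    value = "cumulative_gy" if cumulative else "dose_gy"
    sub = doses[doses["organ"] == organ]
    for cycle, grp in sub.groupby("cycle", sort=True):
        wide = grp.pivot_table(index="patient_id", columns="method",
                               values=value, aggfunc="first")
        if not {"MTPD", "STPD"} <= set(wide.columns):
            continue
        n_dropped = int(wide[["MTPD", "STPD"]].isna().any(axis=1).sum())
        if n_dropped:
            logger.info("attrition: organ=%s cycle=%d dropped %d unpaired patients",
                        organ, cycle, n_dropped)
        wide = wide.dropna(subset=["MTPD", "STPD"])
        if len(wide):
            yield int(cycle), wide


def metric_report(doses: pd.DataFrame, cumulative: bool = True) -> pd.DataFrame:
    """Per organ × cycle RMSE/MPE/RPD table from a long dose frame.

    ``cumulative`` compares cumulative doses at each cycle (default);
    set False to compare per-cycle increments.
    """
    rows = []
    for organ in sorted(doses["organ"].unique()):
        for cycle, wide in _iter_pairs(doses, organ, cumulative):
            s, m = wide["STPD"].to_numpy(), wide["MTPD"].to_numpy()
            rows.append(MetricReport(
                organ=organ, cycle=cycle,
                rmse=rmse(s, m), mpe=mpe(s, m), rpd=rpd(s, m),
                pd_values=tuple((s - m) / m * 100.0), n=len(s),
            ))
    return pd.DataFrame([
        {"organ": r.organ, "cycle": r.cycle, "rmse": r.rmse,
         "mpe": r.mpe, "rpd": r.rpd, "n": r.n}
        for r in rows
    ], columns=["organ", "cycle", "rmse", "mpe", "rpd", "n"])
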