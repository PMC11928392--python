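"""Absorbed-dose estimation: multi- vs single-time-point methods.

MTPD (multi-time-point dosimetry) integrates the fitted time-activity
curve to the time-integrated concentration and converts it to absorbed
dose assuming local deposition of the nuclide's electron energy — a
good approximation for ¹⁷⁷Lu, whose beta range (~mm) is small against
organ dimensions.  Cross-organ photon dose is neglected.

STPD (single-time-point dosimetry) uses the Hänscheid approximation:
one scan at time t surrogates the time integral as c(t)·2t/ln2, exact
when t equals the effective half-life of a mono-exponential washout.
Scans are only eligible when 0.75·T_eff < t < 2.5·T_eff (strict), which
bounds the mono-exponential error to about ±12%.

Both concentrations are per gram, so dose_gy = Ã · K with

    K = 3.6e9 decays/(MBq·h) · E_MeV · 1.602e-13 J/MeV · 1e3 g/kg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .kinetics import (
    LN2,
    ORGANS,
    ActivitySample,
    FitTable,
    KineticFit,
    NuclideSpec,
    LU177,
    curve_integral,
    population_teff,
)

logger = logging.getLogger("rptdose.dosimetry")

#: Hänscheid eligibility window as multiples of T_eff (strict bounds).
WINDOW_LO = 0.75
WINDOW_HI = 2.5


class DuplicateDoseError(ValueError):
    """Two doses for the same (patient, cycle, organ, method)."""


@dataclass(frozen=True)
class DoseResult:
    """One absorbed-dose estimate for organ × cycle × method.

    ``scan_time_h`` is the single scan used and is present only for
    STPD results.
    """

    patient_id: str
    cycle: int
    organ: str
    method: str  # "MTPD" | "STPD"
    dose_gy: float
    scan_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("MTPD", "STPD"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.dose_gy < 0:
            raise ValueError("dose_gy must be >= 0")
        if self.method == "MTPD" and self.scan_time_h is not None:
            raise ValueError("MTPD results carry no scan time")
        if self.method == "STPD" and self.scan_time_h is None:
            raise ValueError("STPD results must carry the scan time used")


@dataclass(frozen=True)
class CycleRecord:
    """Administered activity for one treatment cycle."""

    patient_id: str
    cycle: int
    injected_gbq: float
    cumulative_gbq: float

    def __post_init__(self) -> None:
        if not self.injected_gbq > 0:
            raise ValueError("injected_gbq must be > 0")
        if self.cumulative_gbq < self.injected_gbq:
            raise ValueError("cumulative_gbq must include the cycle's injection")


def kerma_factor(nuclide: NuclideSpec = LU177) -> float:
    """Gy per (MBq·h/g) under local energy deposition."""
    return 3.6e9 * nuclide.mean_energy_per_decay_MeV * 1.602e-13 * 1e3


def mtpd_dose(
    fit: KineticFit,
    nuclide: NuclideSpec = LU177,
    density_g_per_ml: float = 1.0,
    *,
    patient_id: str = "",
    cycle: int = 1,
    organ: str = "tumor",
) -> DoseResult:
    """Multi-time-point absorbed dose from a fitted curve.

    ``density_g_per_ml`` converts per-millilitre concentrations to the
    per-gram basis of the dose factor; leave at 1.0 for MBq/g input.
    """
    integral = curve_integral(fit) / density_g_per_ml
    dose = integral * kerma_factor(nuclide)
    return DoseResult(patient_id, cycle, organ, "MTPD", dose)


def stpd_hanscheid(
    sample: ActivitySample,
    nuclide: NuclideSpec = LU177,
    density_g_per_ml: float = 1.0,
) -> DoseResult:
    """Single-time-point (Hänscheid) absorbed dose from one scan.

    The time integral is approximated as c(t)·2t/ln2 and converted as
    in :func:`mtpd_dose`.
    """
    if not sample.time_h > 0:
        raise ValueError("invalid scan time")
    surrogate = sample.conc * 2.0 * sample.time_h / LN2 / density_g_per_ml
    dose = surrogate * kerma_factor(nuclide)
    return DoseResult(
        sample.patient_id, sample.cycle, sample.organ, "STPD",
        dose, scan_time_h=sample.time_h,
    )


def window_filter(scan_time_h: float, teff_h: float) -> bool:
    """True iff 0.75·T_eff < t < 2.5·T_eff (strict inequalities)."""
    if not (scan_time_h > 0 and teff_h > 0):
        raise ValueError("invalid window query")
    return WINDOW_LO * teff_h < scan_time_h < WINDOW_HI * teff_h


def hanscheid_ratio(x: float | np.ndarray):
    """Analytic STPD/MTPD ratio 2^(1−x)·x for mono-exponential washout,
    with x = t/T_eff.  Equals 1 at x = 1; its maximum 2^(1−1/ln2)/ln2
    (~+6.15%) occurs at x = 1/ln2."""
    x = np.asarray(x, dtype=float)
    return 2.0 ** (1.0 - x) * x


def select_stpd_sample(
    samples: Iterable[ActivitySample], teff_h: float
) -> ActivitySample | None:
    """The window-eligible sample with scan time closest to T_eff.

    Scanning at exactly t = T_eff makes the Hänscheid surrogate exact
    for mono-exponential washout, so proximity to T_eff minimizes the
    analytic error.  Returns None when no scan falls in the window.
    """
    eligible = [s for s in samples if window_filter(s.time_h, teff_h)]
    if not eligible:
        return None
    return min(eligible, key=lambda s: abs(s.time_h - teff_h))


def cumulative_doses(results: Iterable[DoseResult]) -> pd.DataFrame:
    """Running dose sums over cycles per patient × organ × method.

    Returns a frame with per-cycle ``dose_gy`` and running
    ``cumulative_gy``; the final row of each group is the MTPD_total /
    STPD_total aggregate.
    """
    rows = [
        {
            "patient_id": r.patient_id, "cycle": r.cycle, "organ": r.organ,
            "method": r.method, "dose_gy": r.dose_gy,
            "scan_time_h": r.scan_time_h,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "cycle", "organ", "method", "dose_gy", "scan_time_h"],
    )
    if df.empty:
        df["cumulative_gy"] = pd.Series(dtype=float)
        return df
    if df.duplicated(["patient_id", "cycle", "organ", "method"]).any():
        raise DuplicateDoseError("duplicate dose")
    df = df.sort_values(["patient_id", "organ", "method", "cycle"]).reset_index(drop=True)
    df["cumulative_gy"] = df.groupby(["patient_id", "organ", "method"])["dose_gy"].cumsum()
    return df


def total_doses(doses: pd.DataFrame) -> pd.DataFrame:
    """MTPD_total / STPD_total per patient × organ (last cumulative sum)."""
    idx = doses.groupby(["patient_id", "organ", "method"])["cycle"].idxmax()
    out = doses.loc[idx, ["patient_id", "organ", "method", "cycle", "cumulative_gy"]]
    return out.rename(columns={"cycle": "n_cycles", "cumulative_gy": "total_gy"}).reset_index(drop=True)


def dose_per_unit_activity(dose_gy: float, injected_gbq: float) -> float:
    """Absorbed dose normalised by administered activity, Gy/GBq."""
    if injected_gbq == 0:
        raise ZeroDivisionError("division by zero activity")
    return dose_gy / injected_gbq


# ---------------------------------------------------------------------------
# Pipeline: fits + scans + injections -> dose table
# ---------------------------------------------------------------------------

def run_dosimetry(
    activity: pd.DataFrame,
    fits: FitTable,
    cycles: pd.DataFrame,
    nuclide: NuclideSpec = LU177,
    density_g_per_ml: float = 1.0,
    per_patient_teff: bool = False,
) -> pd.DataFrame:
    """Compute MTPD and window-filtered STPD doses for a whole cohort.

    The Hänscheid window is applied organ-wise with the *population*
    effective half-life (median over all fitted curves of that organ),
    mirroring a quality-control step done once per cohort; set
    ``per_patient_teff`` to use each curve's own T_eff instead.

    Returns the long-format dose table with cumulative sums and
    per-unit-activity columns.
    """
    pop_teff = {
        organ: population_teff(
            [f for (p, c, o), f in fits.items() if o == organ], organ
        )
        for organ in sorted({o for (_, _, o) in fits})
    }
    logger.info("population T_eff (h): %s",
                {k: round(v, 2) for k, v in pop_teff.items()})

    grouped = {
        (str(k[0]), int(k[1]), str(k[2])): g
        for k, g in activity.groupby(["patient_id", "cycle", "organ"])
    }
    results: list[DoseResult] = []
    n_rejected = 0
    for key in sorted(fits):
        pid, cycle, organ = key
        fit = fits[key]
        results.append(
            mtpd_dose(fit, nuclide, density_g_per_ml,
                      patient_id=pid, cycle=cycle, organ=organ)
        )
        grp = grouped.get(key)
        if grp is None:
            continue
        samples = [
            ActivitySample(pid, cycle, organ, float(r.time_h), float(r.conc_mbq_per_g))
            for r in grp.itertuples()
        ]
        teff = fit.teff_h if per_patient_teff else pop_teff[organ]
        chosen = select_stpd_sample(samples, teff)
        if chosen is None:
            n_rejected += 1
            logger.debug("no eligible STPD scan for %s (T_eff %.1f h)", key, teff)
            continue
        results.append(stpd_hanscheid(chosen, nuclide, density_g_per_ml))
    logger.info("STPD: %d organ-cycles had no window-eligible scan", n_rejected)

    doses = cumulative_doses(results)
    cyc = cycles[["patient_id", "cycle", "injected_gbq", "cumulative_gbq"]]
    doses = doses.merge(cyc, on=["patient_id", "cycle"], how="left")
    doses["gy_per_gbq"] = doses["dose_gy"] / doses["injected_gbq"]
    return doses


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

CYCLE_COLUMNS = ["patient_id", "cycle", "injected_gbq", "cumulative_gbq"]
DOSE_COLUMNS = ["patient_id", "cycle", "organ", "method", "dose_gy",
                "scan_time_h", "cumulative_gy", "injected_gbq", "gy_per_gbq"]


def read_cycles_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CYCLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cycles CSV missing columns: {sorted(missing)}")
    df = df[CYCLE_COLUMNS].copy()
    df["cycle"] = df["cycle"].astype(int)
    if (df["injected_gbq"] <= 0).any():
        raise ValueError("injected_gbq must be > 0")
    mono = df.sort_values(["patient_id", "cycle"]).groupby("patient_id")["cumulative_gbq"]
    if (mono.diff().dropna() < 0).any():
        raise ValueError("cumulative_gbq must be nondecreasing in cycle")
    return df


def write_doses_csv(doses: pd.DataFrame, path) -> None:
    cols = [c for c in DOSE_COLUMNS if c in doses.columns]
    doses[cols].to_csv(path, index=False)


def read_doses_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"patient_id", "cycle", "organ", "method", "dose_gy", "cumulative_gy"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"doses CSV missing columns: {sorted(missing)}")
    df["cycle"] = df["cycle"].astype(int)
    return df
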