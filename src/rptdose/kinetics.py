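"""Organ time-activity kinetics for ¹⁷⁷Lu radiopharmaceutical therapy.

SPECT-derived activity concentrations c(t) (MBq per gram of tissue) for
one organ and treatment cycle are modelled as mono-exponential washout

    c(t) = A · exp(-λ t)

or as an uptake–washout bi-exponential

    c(t) = A₁ · exp(-λ₁ t) - A₂ · exp(-λ₂ t),      λ₂ > λ₁,

fitted by least squares and integrated in closed form to the
time-integrated concentration (MBq·h/g) that absorbed-dose estimation
requires.  The effective half-life is taken from the terminal washout
phase, T_eff = ln2 / λ₁.

Concentrations are decay-corrected to acquisition time, i.e. they still
include physical decay, so every admissible washout rate is bounded
below by the physical decay constant of the nuclide.  Time is in hours
with injection at t = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger("rptdose.kinetics")

LN2 = math.log(2.0)

#: Organs tracked by the pipeline.
ORGANS = ("kidneys", "liver", "spleen", "bone_marrow", "tumor")

#: Upper bound for any fitted rate (1/h); faster components are not
#: resolvable from scans hours apart.
RATE_CEILING_PER_H = 10.0

#: Key identifying one fitted curve: (patient_id, cycle, organ).
FitKey = tuple[str, int, str]
FitTable = dict[FitKey, "KineticFit"]


class InsufficientTimePointsError(ValueError):
    """Fewer distinct time points than the model has parameters."""


class EmptyCurveError(ValueError):
    """All measured concentrations are zero."""


class NonIntegrableCurveError(ValueError):
    """A fitted rate is non-positive; the curve has no finite integral."""


class UnsortedSamplesError(ValueError):
    """Samples are not in strictly increasing time order."""


class NoFitsError(ValueError):
    """A population summary was requested for an empty fit list."""


@dataclass(frozen=True)
class ActivitySample:
    """One decay-corrected activity-concentration measurement.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    cycle : int
        Treatment cycle, 1-based.
    organ : str
        One of :data:`ORGANS`.
    time_h : float
        Hours post-injection, > 0.
    conc : float
        Activity concentration in MBq per gram of tissue, >= 0.
    """

    patient_id: str
    cycle: int
    organ: str
    time_h: float
    conc: float

    def __post_init__(self) -> None:
        if self.cycle < 1:
            raise ValueError(f"cycle must be positive, got {self.cycle}")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if not self.time_h > 0:
            raise ValueError(f"time_h must be > 0, got {self.time_h}")
        if self.conc < 0 or not math.isfinite(self.conc):
            raise ValueError(f"conc must be finite and >= 0, got {self.conc}")


@dataclass(frozen=True)
class NuclideSpec:
    """Physical constants of the therapeutic nuclide.

    Defaults are ¹⁷⁷Lu: half-life 159.5 h and ~0.147 MeV mean energy
    deposited locally per decay (beta spectrum plus conversion/Auger
    electrons; the small photon component is excluded because it is not
    absorbed locally).
    """

    physical_half_life_h: float = 159.5
    mean_energy_per_decay_MeV: float = 0.147

    def __post_init__(self) -> None:
        if not self.physical_half_life_h > 0:
            raise ValueError("physical_half_life_h must be > 0")
        if not self.mean_energy_per_decay_MeV > 0:
            raise ValueError("mean_energy_per_decay_MeV must be > 0")

    @property
    def lambda_phys_per_h(self) -> float:
        """Physical decay constant, 1/h."""
        return LN2 / self.physical_half_life_h


LU177 = NuclideSpec()


@dataclass(frozen=True)
class KineticFit:
    """A fitted exponential time-activity model for one organ/cycle.

    ``amplitudes`` and ``rates`` hold one pair for ``model_kind="mono"``
    and two for ``"biexp"`` (slow/washout first, fast/uptake second; the
    second amplitude enters with a minus sign).  ``teff_h`` is the
    effective half-life derived from the terminal washout rate.
    """

    model_kind: Literal["mono", "biexp"]
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    teff_h: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        n = 1 if self.model_kind == "mono" else 2
        if len(self.amplitudes) != n or len(self.rates) != n:
            raise ValueError(
                f"{self.model_kind} fit needs {n} amplitude/rate pair(s)"
            )
        if any(r <= 0 for r in self.rates):
            raise ValueError("all rates must be > 0")
        if self.model_kind == "biexp" and self.rates[1] <= self.rates[0]:
            raise ValueError("biexp requires fast rate > slow rate")

    def __call__(self, t):
        """Evaluate the fitted curve at time ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        if self.model_kind == "mono":
            return self.amplitudes[0] * np.exp(-self.rates[0] * t)
        a1, a2 = self.amplitudes
        l1, l2 = self.rates
        return a1 * np.exp(-l1 * t) - a2 * np.exp(-l2 * t)

    def model_integral(self, t_upper: float) -> float:
        """Closed-form integral of the fitted curve over [0, t_upper]."""
        signs = (1.0,) if self.model_kind == "mono" else (1.0, -1.0)
        return float(
            sum(
                s * a / r * (1.0 - math.exp(-r * t_upper))
                for s, a, r in zip(signs, self.amplitudes, self.rates)
            )
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _mono_seed(t: np.ndarray, c: np.ndarray, lam_lo: float) -> tuple[float, float]:
    """Log-linear regression seed on the strictly positive samples."""
    pos = c > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(c[pos]), 1)
        lam = float(np.clip(-slope, lam_lo, RATE_CEILING_PER_H))
        amp = float(np.exp(intercept))
    else:
        lam, amp = lam_lo, float(c.max())
    return max(amp, 1e-12), lam


def _fit_mono(t: np.ndarray, c: np.ndarray, lam_lo: float) -> KineticFit:
    amp0, lam0 = _mono_seed(t, c, lam_lo)

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - c

    sol = least_squares(
        resid,
        x0=[amp0, lam0],
        bounds=([0.0, lam_lo], [np.inf, RATE_CEILING_PER_H]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    amp, lam = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    return KineticFit("mono", (amp,), (lam,), LN2 / lam, rss, len(t))


def _project_biexp(t: np.ndarray, c: np.ndarray, l1: float, l2: float):
    """For fixed rates, solve the amplitudes by linear least squares."""
    design = np.column_stack([np.exp(-l1 * t), -np.exp(-l2 * t)])
    coef, _, _, _ = np.linalg.lstsq(design, c, rcond=None)
    resid = design @ coef - c
    return coef, resid


def _fit_biexp(t: np.ndarray, c: np.ndarray, lam_lo: float) -> KineticFit | None:
    """Variable-projection biexp fit; None when no admissible optimum."""
    # seed the slow rate from the tail (last two positive points)
    pos = np.flatnonzero(c > 0)
    if len(pos) >= 2 and c[pos[-1]] < c[pos[-2]]:
        i, j = pos[-2], pos[-1]
        l1_seed = math.log(c[i] / c[j]) / (t[j] - t[i])
    else:
        l1_seed = 2.0 * lam_lo
    l1_seed = float(np.clip(l1_seed, lam_lo, 1.0))

    def resid(u):
        l1 = lam_lo + math.exp(u[0])
        l2 = l1 + math.exp(u[1])
        _, r = _project_biexp(t, c, l1, min(l2, RATE_CEILING_PER_H))
        return r

    scale = float(np.sum(c**2))
    best = None
    # fast-rate starts spanning uptake phases peaking minutes to ~a day
    l2_starts = [5.0 * l1_seed, 0.15, 0.5, 1.5]
    for l2_0 in l2_starts:
        if l2_0 <= l1_seed:
            continue
        u0 = [math.log(max(l1_seed - lam_lo, 1e-8)), math.log(l2_0 - l1_seed)]
        sol = least_squares(resid, x0=u0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            l1 = lam_lo + math.exp(sol.x[0])
            l2 = min(l1 + math.exp(sol.x[1]), RATE_CEILING_PER_H)
            coef, _ = _project_biexp(t, c, l1, l2)
            best = (rss, l1, l2, float(coef[0]), float(coef[1]))
            if rss < 1e-14 * scale:  # interpolating fit found
                break

    if best is None:
        return None
    rss, l1, l2, a1, a2 = best
    # admissibility: positive washout amplitude, non-negative uptake
    # amplitude, genuinely separated rates, positive total integral
    if a1 <= 0 or a2 < 0 or (l2 - l1) < 1e-3 * l1 or a1 / l1 - a2 / l2 <= 0:
        return None
    return KineticFit("biexp", (a1, a2), (l1, l2), LN2 / l1, rss, len(t))


def fit_kinetics(
    samples: Iterable[ActivitySample],
    nuclide: NuclideSpec = LU177,
    model_kind: Literal["mono", "biexp"] = "biexp",
    teff_kind: Literal["terminal", "area"] = "terminal",
) -> KineticFit:
    """Fit an exponential washout model to one organ/cycle curve.

    ``model_kind="biexp"`` requests the uptake–washout model but falls
    back to mono-exponential when the bi-exponential fit is degenerate:
    inadmissible parameters (negative amplitude, collapsed rates) or an
    RSS reduction below 1% relative to the mono fit.

    ``teff_kind`` selects how T_eff is reduced from a bi-exponential
    fit: ``"terminal"`` (default) uses the slow washout rate,
    ``"area"`` uses the area-equivalent half-life ln2·∫c/c_peak.

    Raises
    ------
    InsufficientTimePointsError
        Fewer distinct samples than the model requires (2 mono, 3 biexp).
    EmptyCurveError
        All concentrations are zero.
    """
    samples = sorted(samples, key=lambda s: s.time_h)
    t = np.array([s.time_h for s in samples], dtype=float)
    c = np.array([s.conc for s in samples], dtype=float)

    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate time points")
    n_min = 2 if model_kind == "mono" else 3
    if len(t) < n_min:
        raise InsufficientTimePointsError("insufficient time points")
    if np.all(c == 0):
        raise EmptyCurveError("empty curve")

    lam_lo = nuclide.lambda_phys_per_h
    mono = _fit_mono(t, c, lam_lo)
    fit = mono
    if model_kind == "biexp":
        # a mono fit that already explains the data to numerical noise
        # cannot be meaningfully improved by two more parameters
        scale = float(np.sum(c**2))
        if mono.rss > 1e-12 * scale:
            biexp = _fit_biexp(t, c, lam_lo)
            if biexp is not None and biexp.rss < 0.99 * mono.rss:
                fit = biexp
            else:
                logger.debug("biexp degenerate, falling back to mono")

    if teff_kind == "area" and fit.model_kind == "biexp":
        teff = LN2 * curve_integral(fit) / _peak_concentration(fit)
        fit = KineticFit(
            fit.model_kind, fit.amplitudes, fit.rates, teff, fit.rss, fit.n_points
        )
    return fit


def _peak_concentration(fit: KineticFit) -> float:
    if fit.model_kind == "mono":
        return fit.amplitudes[0]
    a1, a2 = fit.amplitudes
    l1, l2 = fit.rates
    if a2 <= 0 or l2 * a2 <= l1 * a1:
        return a1 - a2
    t_peak = math.log((l2 * a2) / (l1 * a1)) / (l2 - l1)
    return float(fit(max(t_peak, 0.0)))


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def curve_integral(fit: KineticFit) -> float:
    """Closed-form ∫₀^∞ c(t) dt in MBq·h/g.

    Mono: A/λ.  Biexp: A₁/λ₁ − A₂/λ₂ (positive because λ₂ > λ₁ and the
    curve is an admissible uptake–washout shape).
    """
    if any(r <= 0 for r in fit.rates):
        raise NonIntegrableCurveError("non-integrable curve")
    signs = (1.0,) if fit.model_kind == "mono" else (1.0, -1.0)
    total = sum(s * a / r for s, a, r in zip(signs, fit.amplitudes, fit.rates))
    if total < 0:
        raise NonIntegrableCurveError("non-integrable curve")
    return float(total)


def numeric_integral(samples: Iterable[ActivitySample], fit: KineticFit) -> float:
    """Piecewise integral over the observed samples with analytic
    head and tail.

    The head [0, t_first] uses the fitted model in closed form; the
    body applies the pharmacokinetic lin-up/log-down rule (linear
    trapezoid on rising or zero segments, log-trapezoid on declining
    ones, which is exact for exponential washout between samples); the
    tail beyond the last sample extrapolates the observed concentration
    with the fitted terminal rate, c(t_last)/λ_slow.  Serves as an
    independent cross-check of :func:`curve_integral`.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise InsufficientTimePointsError("insufficient time points")
    t = np.array([s.time_h for s in samples], dtype=float)
    c = np.array([s.conc for s in samples], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise UnsortedSamplesError("unsorted samples")

    head = fit.model_integral(float(t[0]))  # closed form on [0, t_first]
    body = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0:  # log-trapezoid on the declining phase
            body += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            body += dt * (c0 + c1) / 2.0
    tail = float(c[-1]) / fit.rates[0]
    return head + body + tail


def population_teff(
    fits: Iterable[KineticFit],
    organ: str | None = None,
    stat: Literal["median", "mean"] = "median",
) -> float:
    """Population effective half-life (hours) across patients/cycles."""
    values = [f.teff_h for f in fits]
    if not values:
        raise NoFitsError(f"no fits{f' for {organ}' if organ else ''}")
    return float(np.median(values) if stat == "median" else np.mean(values))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

ACTIVITY_COLUMNS = ["patient_id", "cycle", "organ", "time_h", "conc_mbq_per_g"]


def read_activity_csv(path) -> pd.DataFrame:
    """Read an activity-sample table; validates schema and invariants."""
    df = pd.read_csv(path)
    missing = set(ACTIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    df = df[ACTIVITY_COLUMNS].copy()
    df["cycle"] = df["cycle"].astype(int)
    bad_organ = ~df["organ"].isin(ORGANS)
    if bad_organ.any():
        row = df.index[bad_organ][0]
        raise ValueError(f"unknown organ {df.loc[row, 'organ']!r} at row {row}")
    if (df["time_h"] <= 0).any():
        raise ValueError("time_h must be > 0")
    if (df["conc_mbq_per_g"] < 0).any():
        raise ValueError("conc_mbq_per_g must be >= 0")
    dup = df.duplicated(["patient_id", "cycle", "organ", "time_h"])
    if dup.any():
        raise ValueError("duplicate (patient, cycle, organ, time) sample")
    return df


def samples_from_frame(df: pd.DataFrame) -> list[ActivitySample]:
    return [
        ActivitySample(str(r.patient_id), int(r.cycle), r.organ,
                       float(r.time_h), float(r.conc_mbq_per_g))
        for r in df.itertuples()
    ]


def fit_all(
    activity: pd.DataFrame,
    nuclide: NuclideSpec = LU177,
    model_kind: Literal["mono", "biexp"] = "biexp",
) -> FitTable:
    """Fit every (patient, cycle, organ) curve in an activity table.

    Curves that cannot be fitted (too few points, all-zero) are skipped
    with a warning so one bad curve does not abort a cohort run.
    """
    fits: FitTable = {}
    for key, grp in activity.groupby(["patient_id", "cycle", "organ"], sort=True):
        key = (str(key[0]), int(key[1]), str(key[2]))
        try:
            fits[key] = fit_kinetics(samples_from_frame(grp), nuclide, model_kind)
        except (InsufficientTimePointsError, EmptyCurveError) as exc:
            logger.warning("skipping %s: %s", key, exc)
    logger.info("fitted %d curves", len(fits))
    return fits


def fits_to_frame(fits: FitTable) -> pd.DataFrame:
    rows = []
    for (pid, cycle, organ), f in sorted(fits.items()):
        a = f.amplitudes
        r = f.rates
        rows.append({
            "patient_id": pid, "cycle": cycle, "organ": organ,
            "model_kind": f.model_kind,
            "a1": a[0], "a2": a[1] if len(a) > 1 else np.nan,
            "lambda1": r[0], "lambda2": r[1] if len(r) > 1 else np.nan,
            "teff_h": f.teff_h, "rss": f.rss, "n_points": f.n_points,
        })
    return pd.DataFrame(rows)


def fits_from_frame(df: pd.DataFrame) -> FitTable:
    fits: FitTable = {}
    for r in df.itertuples():
        if r.model_kind == "mono":
            amps, rates = (float(r.a1),), (float(r.lambda1),)
        else:
            amps = (float(r.a1), float(r.a2))
            rates = (float(r.lambda1), float(r.lambda2))
        fits[(str(r.patient_id), int(r.cycle), str(r.organ))] = KineticFit(
            r.model_kind, amps, rates, float(r.teff_h), float(r.rss), int(r.n_points)
        )
    return fits


def write_fits_csv(fits: FitTable, path) -> None:
    fits_to_frame(fits).to_csv(path, index=False)


def read_fits_csv(path) -> FitTable:
    return fits_from_frame(pd.read_csv(path))
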