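"""Clinical endpoints and the dose–outcome statistical battery.

Endpoints
---------
* PSA decline rate (PSA_t − PSA_baseline)/PSA_baseline; a confirmed
  decline of at least 50% (rate ≤ −0.5) defines a good biochemical
  response.
* Anemia grading from hemoglobin against CTCAE v5.0 bands: grade 1
  below the lower limit of normal down to 10 g/dL, grade 2 in
  [8, 10), grade 3 below 8; grades 4–5 need explicit clinical flags.
* Overall survival from first administration, right-censored.

Statistics
----------
Spearman rank correlations of dose with outcome for each dosimetry
method, compared by the Fisher Z-transformed test

    z_i = atanh(rho_i),   Z = (z1 − z2) / sqrt(1/(n1−3) + 1/(n2−3)),

with a two-sided normal p-value.  The classical test assumes two
independent samples; since both methods are measured on the same
observations, Steiger's dependent-correlation variant is provided as
an option (the independent form is the default).  Group contrasts use
the Mann–Whitney U test, survival uses univariate Cox regression
(Breslow ties) and Kaplan–Meier curves via lifelines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter

logger = logging.getLogger("rptdose.outcomes")

#: Default lower limit of normal for hemoglobin, g/dL (adult male).
HGB_LLN_G_DL = 13.0


@dataclass(frozen=True)
class OutcomeRecord:
    """Per-patient clinical endpoints."""

    patient_id: str
    psa_baseline: float
    psa_series: tuple[float, ...]
    hgb_series: tuple[float, ...]
    anemia_grade: int
    os_days: float
    os_event: bool

    def __post_init__(self) -> None:
        if not self.psa_baseline > 0:
            raise ValueError("psa_baseline must be > 0")
        if not 0 <= self.anemia_grade <= 5:
            raise ValueError("anemia_grade must be in 0..5")
        if not self.os_days > 0:
            raise ValueError("os_days must be > 0")


@dataclass(frozen=True)
class CorrelationComparison:
    """Two correlation coefficients and their Fisher-Z contrast."""

    rho1: float
    rho2: float
    n1: int
    n2: int
    z_stat: float
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox proportional-hazards estimate."""

    beta: float
    hr: float
    se: float
    p_value: float
    covariate_label: str

    def __post_init__(self) -> None:
        if not math.isclose(self.hr, math.exp(self.beta), rel_tol=1e-9):
            raise ValueError("hr must equal exp(beta)")


# ---------------------------------------------------------------------------
# Endpoint construction
# ---------------------------------------------------------------------------

def psa_decline_rate(psa_baseline: float, psa_t: float) -> float:
    """(PSA_t − baseline)/baseline; negative values are declines."""
    if not psa_baseline > 0:
        raise ValueError("invalid baseline")
    if psa_t < 0:
        raise ValueError("psa must be >= 0")
    return (psa_t - psa_baseline) / psa_baseline


def classify_response(decline_rate: float) -> str:
    """'good' for a PSA decrease of at least 50%, else 'poor'."""
    if not math.isfinite(decline_rate):
        raise ValueError("decline rate must be finite")
    return "good" if decline_rate <= -0.5 else "poor"


def anemia_grade(
    hgb_g_dl: float,
    lln_g_dl: float = HGB_LLN_G_DL,
    life_threatening: bool = False,
    fatal: bool = False,
) -> int:
    """CTCAE v5.0 anemia grade from hemoglobin.

    Hemoglobin alone caps the grade at 3; grades 4 and 5 require the
    explicit clinical flags.
    """
    if not hgb_g_dl > 0:
        raise ValueError("invalid measurement")
    if fatal:
        return 5
    if life_threatening:
        return 4
    if hgb_g_dl >= lln_g_dl:
        return 0
    if hgb_g_dl >= 10.0:
        return 1
    if hgb_g_dl >= 8.0:
        return 2
    return 3


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value from the t approximation with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fisher_z_compare(rho1: float, n1: int, rho2: float, n2: int) -> CorrelationComparison:
    """Fisher Z-transformed test for two independent correlations."""
    for rho in (rho1, rho2):
        if abs(rho) >= 1:
            raise ValueError("infinite transform")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per sample")
    z1, z2 = math.atanh(rho1), math.atanh(rho2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = p_from_z(z_stat)
    return CorrelationComparison(rho1, rho2, n1, n2, z_stat, p)


def steiger_z_compare(rho1: float, rho2: float, rho12: float, n: int) -> CorrelationComparison:
    """Steiger's test for two dependent correlations sharing a variable.

    ``rho12`` is the correlation between the two predictors (here the
    two dose methods) on the same n observations.
    """
    for rho in (rho1, rho2):
        if abs(rho) >= 1:
            raise ValueError("infinite transform")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = math.atanh(rho1), math.atanh(rho2)
    rm2 = (rho1**2 + rho2**2) / 2.0
    f = min((1.0 - rho12) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z_stat = (z1 - z2) * math.sqrt((n - 3.0) / (2.0 * (1.0 - rho12) * h))
    return CorrelationComparison(rho1, rho2, n, n, z_stat, p_from_z(z_stat))


def p_from_z(z: float) -> float:
    """Two-sided p-value from a standard-normal statistic."""
    return float(2.0 * stats.norm.sf(abs(z)))


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U (exact for small untied samples, else normal
    approximation with tie correction)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    small = (a.size + b.size) <= 20
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

#: |beta| beyond which the partial likelihood is treated as monotone
#: (perfect separation); the estimate is capped there with a warning.
_COX_BETA_CAP = 20.0


def breslow_partial_loglik(beta: float, times, events, covariate) -> float:
    """Breslow log partial likelihood of a univariate Cox model.

    Each event contributes beta·x_i − log Σ_{j: t_j >= t_i} exp(beta·x_j);
    tied event times simply repeat the common denominator.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


def cox_univariate(times, events, covariate, label: str = "dose") -> CoxResult:
    """Univariate Cox proportional-hazards fit.

    Maximizes the Breslow partial likelihood by Newton–Raphson with
    step halving; the Wald p-value uses the observed information.
    Monotone likelihood (perfect separation) is flagged with a warning
    and beta is capped at ±20.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 subjects")
    if not e.any():
        raise ValueError("no events")
    if np.all(x == x[0]):
        raise ValueError("constant covariate")

    center = float(x.mean())  # location shift leaves beta invariant
    xc = x - center
    order = np.argsort(-t)  # reverse time: risk sets are prefixes
    ts, es, xs = t[order], e[order], xc[order]
    ex_idx = np.flatnonzero(es)

    def score_info(beta: float) -> tuple[float, float, float]:
        shift = float(np.max(beta * xs))  # overflow-safe exponentials
        with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
            w = np.exp(beta * xs - shift)
            s0 = np.cumsum(w)
            s1 = np.cumsum(w * xs)
            s2 = np.cumsum(w * xs**2)
            # risk set of an event at ts[i] = all j with t_j >= t_i; with
            # descending sort and ties, take the last index of the tie run
            hi = np.searchsorted(-ts, -ts[ex_idx], side="right") - 1
            mean = s1[hi] / s0[hi]
            ll = float(np.sum(beta * xs[ex_idx] - np.log(s0[hi]) - shift))
            u = float(np.sum(xs[ex_idx] - mean))
            info = float(np.sum(s2[hi] / s0[hi] - mean**2))
        return ll, u, info

    # monotone likelihood: the log partial likelihood is concave, so a
    # still-positive score at +cap (or negative at -cap) means the
    # maximizer lies at or beyond the admissible boundary
    _, u_hi, _ = score_info(_COX_BETA_CAP)
    _, u_lo, _ = score_info(-_COX_BETA_CAP)
    if u_hi > 0 or u_lo < 0:
        beta = _COX_BETA_CAP if u_hi > 0 else -_COX_BETA_CAP
        warnings.warn("monotone partial likelihood: beta capped", stacklevel=2)
        _, _, info = score_info(beta)
        se = 1.0 / math.sqrt(info) if info > 0 else math.inf
        p = p_from_z(beta / se) if math.isfinite(se) and se > 0 else float("nan")
        return CoxResult(beta=float(beta), hr=math.exp(beta), se=float(se),
                         p_value=p, covariate_label=label)

    beta = 0.0
    ll, u, info = score_info(beta)
    capped = False
    for _ in range(60):
        if not info > 0:  # flat or numerically degenerate curvature
            break
        step = u / info
        new = beta + step
        if abs(new) > _COX_BETA_CAP:
            new = math.copysign(_COX_BETA_CAP, new)
            capped = True
        new_ll, new_u, new_info = score_info(new)
        halvings = 0
        while not (new_ll >= ll - 1e-12) and halvings < 30:
            new = (beta + new) / 2.0
            new_ll, new_u, new_info = score_info(new)
            halvings += 1
        converged = abs(new - beta) < 1e-10 * (1.0 + abs(beta))
        beta, ll, u, info = new, new_ll, new_u, new_info
        if converged:
            break
    if capped and abs(beta) >= _COX_BETA_CAP * 0.999:
        warnings.warn("monotone partial likelihood: beta capped", stacklevel=2)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    p = p_from_z(beta / se) if math.isfinite(se) and se > 0 else float("nan")
    return CoxResult(beta=float(beta), hr=math.exp(beta), se=float(se),
                     p_value=p, covariate_label=label)


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate, right-censoring respected.

    Returns a frame with columns ``time`` and ``survival`` (the step
    function's value from each time onward, starting at S(0) = 1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    return sf


# ---------------------------------------------------------------------------
# Full dose-vs-outcome battery
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = ["patient_id", "cycle", "psa", "hgb", "os_days", "os_event"]


def read_outcomes_csv(path) -> pd.DataFrame:
    """Read the per-patient-cycle outcome table.

    Cycle 0 rows carry the pre-therapy baseline PSA/Hgb; OS columns are
    repeated per row.
    """
    df = pd.read_csv(path)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcomes CSV missing columns: {sorted(missing)}")
    df = df[OUTCOME_COLUMNS].copy()
    df["cycle"] = df["cycle"].astype(int)
    df["os_event"] = df["os_event"].astype(bool)
    if (df.loc[df["cycle"] == 0, "psa"] <= 0).any():
        raise ValueError("baseline PSA must be > 0")
    return df


@dataclass
class AnalysisReport:
    """All statistics of one dose-vs-outcome comparison run."""

    psa_corr: dict | None = None
    anemia_corr: dict | None = None
    utest: dict | None = None
    cox: list[CoxResult] = field(default_factory=list)
    km: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = []
        for name, block in (("PSA decline rate vs tumor dose", self.psa_corr),
                            ("Anemia grade vs bone-marrow dose", self.anemia_corr)):
            if not block:
                continue
            cmp_ = block["fisher"]
            lines.append(
                f"{name}: MTPD rho = {block['rho_mtpd']:.2f} (p = {block['p_mtpd']:.2g}), "
                f"STPD rho = {block['rho_stpd']:.2f} (p = {block['p_stpd']:.2g}); "
                f"Fisher Z = {cmp_.z_stat:.2f}, p = {cmp_.p_value:.2f} "
                f"(n = {cmp_.n1}/{cmp_.n2})"
            )
        if self.utest:
            for method, (u, p) in self.utest.items():
                lines.append(f"U-test tumor {method} by PSA response: U = {u:.1f}, p = {p:.2g}")
        for r in self.cox:
            lines.append(
                f"Cox OS ~ {r.covariate_label}: HR = {r.hr:.2f} "
                f"(beta = {r.beta:.3f}, se = {r.se:.3f}, p = {r.p_value:.3g})"
            )
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def _decline_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per patient-cycle PSA decline rate and anemia grade."""
    base = outcomes[outcomes["cycle"] == 0].set_index("patient_id")
    rows = []
    for r in outcomes[outcomes["cycle"] > 0].itertuples():
        if r.patient_id not in base.index:
            logger.warning("no baseline row for patient %s", r.patient_id)
            continue
        b = base.loc[r.patient_id]
        rows.append({
            "patient_id": r.patient_id, "cycle": int(r.cycle),
            "decline_rate": psa_decline_rate(float(b.psa), float(r.psa)),
            "anemia_grade": anemia_grade(float(r.hgb)),
            "os_days": float(r.os_days), "os_event": bool(r.os_event),
        })
    return pd.DataFrame(rows)


def _dose_outcome_join(doses: pd.DataFrame, decline: pd.DataFrame,
                       organ: str) -> pd.DataFrame:
    sub = doses[doses["organ"] == organ]
    wide = sub.pivot_table(index=["patient_id", "cycle"], columns="method",
                           values="cumulative_gy", aggfunc="first").reset_index()
    return wide.merge(decline, on=["patient_id", "cycle"], how="inner")


def run_comparison_analysis(
    doses: pd.DataFrame,
    outcomes: pd.DataFrame,
    min_cycles_for_cox: int = 5,
    dependent_fisher: bool = False,
) -> AnalysisReport:
    """The full dose-vs-outcome battery for one cohort.

    * Spearman of cycle-wise cumulative tumor dose vs that cycle's PSA
      decline rate, per method, with a Fisher-Z comparison;
    * the same for cumulative bone-marrow dose vs anemia grade;
    * Mann–Whitney U of tumor doses between good/poor PSA responders;
    * univariate Cox of OS on total tumor dose (raw and log), patients
      with at least ``min_cycles_for_cox`` cycles;
    * Kaplan–Meier curves split at the median MTPD total.
    """
    report = AnalysisReport()
    decline = _decline_table(outcomes)
    if decline.empty:
        report.warnings.append("no outcome observations after join")
        return report

    def corr_block(organ: str, endpoint: str) -> dict | None:
        joined = _dose_outcome_join(doses, decline, organ)
        if not {"MTPD", "STPD"} <= set(joined.columns):
            report.warnings.append(f"{organ}: single-method input, comparison skipped")
            return None
        joined = joined.dropna(subset=["MTPD", "STPD", endpoint])
        if len(joined) < 4:
            report.warnings.append(f"{organ}: too few paired observations")
            return None
        rho_m, p_m = spearman(joined["MTPD"], joined[endpoint])
        rho_s, p_s = spearman(joined["STPD"], joined[endpoint])
        n = len(joined)
        if dependent_fisher:
            rho12, _ = spearman(joined["MTPD"], joined["STPD"])
            cmp_ = steiger_z_compare(rho_m, rho_s, rho12, n)
        else:
            cmp_ = fisher_z_compare(rho_m, n, rho_s, n)
        return {"rho_mtpd": rho_m, "p_mtpd": p_m,
                "rho_stpd": rho_s, "p_stpd": p_s,
                "n": n, "fisher": cmp_, "joined": joined}

    psa_block = corr_block("tumor", "decline_rate")
    report.psa_corr = psa_block
    report.anemia_corr = corr_block("bone_marrow", "anemia_grade")

    # U-test: tumor doses by responder class (cycle-level observations)
    if psa_block is not None:
        joined = psa_block["joined"]
        good = joined["decline_rate"] <= -0.5
        if good.any() and (~good).any():
            report.utest = {
                m: mann_whitney_u(joined.loc[good, m], joined.loc[~good, m])
                for m in ("MTPD", "STPD")
            }
        else:
            report.warnings.append("one-sided responder split, U-test skipped")

    # Cox on per-patient totals, patients with enough cycles
    tumor = doses[doses["organ"] == "tumor"]
    totals = tumor.pivot_table(index="patient_id", columns="method",
                               values="cumulative_gy", aggfunc="max")
    n_cycles = tumor.groupby("patient_id")["cycle"].max()
    surv = decline.groupby("patient_id")[["os_days", "os_event"]].first()
    totals = totals.join(n_cycles.rename("n_cycles")).join(surv).dropna()
    subset = totals[totals["n_cycles"] >= min_cycles_for_cox]
    for method in ("MTPD", "STPD"):
        if method not in subset.columns:
            continue
        for log_transform in (False, True):
            df = subset.copy()
            label = f"{method}_total"
            x = df[method]
            if log_transform:
                keep = x > 0
                if (~keep).any():
                    report.warnings.append(
                        f"{label}: {(~keep).sum()} zero doses excluded from log Cox")
                df, x = df[keep], np.log(x[keep])
                label = f"log_{label}"
            try:
                report.cox.append(
                    cox_univariate(df["os_days"], df["os_event"], x, label))
            except ValueError as exc:
                report.warnings.append(f"Cox {label}: {exc}")

    # Kaplan-Meier by MTPD_total median split
    if "MTPD" in totals.columns and len(totals) >= 2:
        median = totals["MTPD"].median()
        hi = totals["MTPD"] > median
        report.km = {
            "high_dose": kaplan_meier(totals.loc[hi, "os_days"], totals.loc[hi, "os_event"])
            if hi.any() else None,
            "low_dose": kaplan_meier(totals.loc[~hi, "os_days"], totals.loc[~hi, "os_event"])
            if (~hi).any() else None,
            "median_split_gy": float(median),
        }
    return report
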