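"""Tertile-stratified Kaplan–Meier / log-rank survival analysis and
multivariate Cox proportional hazards.

Per miRNA, patients are split into expression tertiles (top vs bottom
third, middle discarded) and the two tails are compared with the
Mantel–Haenszel log-rank test, overall and within each smoking stratum.
Only miRNAs detectably expressed (RPKM >= 1) in at least two thirds of
the stratum's patients are assessed.  Multivariate Cox models combine
log2(RPKM+1) expression with age, sex, ethnicity, stage and smoking
status; the partial likelihood uses Breslow's tie convention and is
maximized by Newton–Raphson.

When a merged multi-cohort dataset is analyzed, tertiles are computed
within each cohort of origin and then pooled for the log-rank test, so
systematic platform-level RPKM differences between cohorts do not
masquerade as expression strata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist

from . import stats
from .dataio import ExpressionMatrix, SampleRecord, SMOKING_GROUPS

STRATA = ("ALL",) + SMOKING_GROUPS


def detectability_gate(
    m: ExpressionMatrix,
    patient_samples: Sequence[str],
    floor: float = 1.0,
) -> list[str]:
    """miRNAs detectably expressed in at least two thirds of patients.

    The threshold is ``ceil(2n/3)`` patients with RPKM >= ``floor``.
    """
    sub = m.subset_samples(list(patient_samples)).data.to_numpy()
    n = sub.shape[1]
    need = math.ceil(2 * n / 3)
    ok = (sub >= floor).sum(axis=1) >= need
    return [mid for mid, keep in zip(m.mirna_ids, ok) if keep]


def tertile_split(values: pd.Series) -> tuple[list[str], list[str]]:
    """Bottom and top expression tertiles (middle third discarded).

    ``values`` is indexed by patient id.  Patients are sorted ascending
    by (value, patient id) — the id makes tie order deterministic — and
    the first and last ``floor(n/3)`` form the low and high tails.
    """
    n = len(values)
    if n < 6:
        raise ValueError("tertile split needs >= 6 patients")
    if values.nunique() == 1:
        warnings.warn("all expression values tied; tertiles split by patient id",
                      stacklevel=2)
    order = sorted(values.index, key=lambda p: (values[p], p))
    size = n // 3
    return order[:size], order[-size:]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censoring at an event time is conventionally ordered after the
    events (censored subjects remain in the risk set for that time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival time")
    uniq = np.unique(t[e])
    s = 1.0
    surv = []
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int((e & (t == u)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KMCurve(times=uniq, survival=np.array(surv))


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> stats.TestResult:
    """Mantel–Haenszel (log-rank) test, 1 df.

    Sums observed-minus-expected events in group A over the pooled event
    times, with the hypergeometric variance term; zero total events give
    p = 1 by convention.
    """
    ta, ea = (np.asarray(group_a[0], float), np.asarray(group_a[1], bool))
    tb, eb = (np.asarray(group_b[0], float), np.asarray(group_b[1], bool))
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(times[events])
    if event_times.size == 0:
        return stats.TestResult(0.0, 1.0, "logrank", (ta.size, tb.size))
    o_minus_e = 0.0
    var = 0.0
    obs_a = 0.0
    for u in event_times:
        at_risk = times >= u
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int((events & (times == u)).sum())
        d_a = int((events & (times == u) & in_a).sum())
        obs_a += d_a
        e_a = d * n_a / n_tot
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
    if var == 0:
        return stats.TestResult(0.0, 1.0, "logrank", (ta.size, tb.size))
    chi2 = o_minus_e ** 2 / var
    p = float(chi2_dist.sf(chi2, 1))
    return stats.TestResult(float(chi2), p, "logrank", (ta.size, tb.size),
                            details={"o_minus_e": o_minus_e, "var": var,
                                     "observed_a": obs_a})


# ---------------------------------------------------------------------------
# per-miRNA tertile survival scan

def _patient_table(meta: Sequence[SampleRecord]) -> pd.DataFrame:
    """One row per patient with a tumor sample and survival data."""
    rows = []
    for r in meta:
        if r.tissue == "tumor" and r.surv_time is not None:
            rows.append((r.patient_id, r.sample_id, r.smoking, r.cohort,
                         r.surv_time, bool(r.event)))
    df = pd.DataFrame(rows, columns=["patient_id", "sample_id", "smoking",
                                     "cohort", "time", "event"])
    return df.set_index("patient_id")


def survival_scan(
    m: ExpressionMatrix,
    meta: Sequence[SampleRecord],
    strata: Sequence[str] = STRATA,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Tertile log-rank scan per miRNA, overall and per smoking stratum.

    Within each stratum: detectability gate, tertile split (within
    cohort of origin, then pooled), log-rank of bottom vs top tertile,
    Benjamini–Hochberg within the stratum.  ``direction`` records which
    tertile's KM curve lies lower at the median follow-up time.  Strata
    with fewer than 6 patients are skipped with a warning.
    """
    patients = _patient_table(meta)
    results = []
    for stratum in strata:
        sub = patients if stratum == "ALL" else patients[patients["smoking"] == stratum]
        if len(sub) < 6:
            warnings.warn(f"stratum {stratum} has {len(sub)} patients; skipped",
                          stacklevel=2)
            continue
        eligible = detectability_gate(m, list(sub["sample_id"]), floor)
        med_t = float(np.median(sub["time"]))
        rows = []
        expr_all = m.subset_samples(list(sub["sample_id"])).data
        for mirna in eligible:
            expr = pd.Series(expr_all.loc[mirna].to_numpy(), index=sub.index)
            low, high = [], []
            for _, chunk in expr.groupby(sub["cohort"], sort=True):
                if len(chunk) < 6:
                    continue  # tiny cohort: no within-cohort split possible
                lo, hi = tertile_split(chunk)
                low.extend(lo)
                high.extend(hi)
            if len(low) == 0 or len(high) == 0:
                continue
            a = (sub.loc[low, "time"], sub.loc[low, "event"])
            b = (sub.loc[high, "time"], sub.loc[high, "event"])
            res = logrank_test(a, b)
            km_low = km_estimate(*a)
            km_high = km_estimate(*b)
            direction = ("low" if km_low.at(med_t) < km_high.at(med_t)
                         else "high" if km_high.at(med_t) < km_low.at(med_t)
                         else "tie")
            rows.append((mirna, stratum, len(high), len(low),
                         res.statistic, res.p_value, direction))
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=["mirna_id", "stratum", "n_high",
                                         "n_low", "logrank_chi2", "p",
                                         "direction"])
        df["bh_q"] = stats.benjamini_hochberg(df["p"].to_numpy())
        results.append(df)
    if not results:
        return pd.DataFrame(columns=["mirna_id", "stratum", "n_high", "n_low",
                                     "logrank_chi2", "p", "direction", "bh_q"])
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)

@dataclass(frozen=True)
class CoxResult:
    coef: pd.Series
    se: pd.Series
    p: pd.Series
    converged: bool
    n: int
    n_events: int
    loglik: float


def coxph_fit(
    x: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Cox proportional-hazards fit via Newton–Raphson.

    Breslow's approximation handles tied event times.  Wald standard
    errors and p-values come from the inverse observed information.
    Zero-variance covariates are rejected by name; non-convergence
    within ``max_iter`` iterations is flagged on the result.
    """
    xm = x.to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n, p = xm.shape
    if n != t.size or n != e.size:
        raise ValueError("design, times and events must align")
    const = [c for c, s in zip(x.columns, xm.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"zero-variance covariate(s): {const}")
    # center for numerical stability; coefficients are unaffected
    center = xm.mean(axis=0)
    xm = xm - center

    order = np.argsort(-t, kind="stable")  # descending time
    xm, t, e = xm[order], t[order], e[order]

    beta = np.zeros(p)
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = xm @ beta
        eta -= eta.max()
        w = np.exp(eta)
        # cumulative sums over the risk set (descending time order)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * xm, axis=0)
        s2 = np.cumsum(w[:, None, None] * (xm[:, :, None] * xm[:, None, :]),
                       axis=0)
        # risk set of subject i = all with time >= t_i: last index with t >= t_i
        idx = np.searchsorted(-t, -t, side="right") - 1
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        ev = np.where(e)[0]
        for i in ev:
            j = idx[i]
            m1 = s1[j] / s0[j]
            ll += eta[i] - math.log(s0[j])
            grad += xm[i] - m1
            info += s2[j] / s0[j] - np.outer(m1, m1)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if abs(ll - loglik) < tol and np.abs(step).max() < math.sqrt(tol):
            loglik = ll
            converged = True
            break
        loglik = ll
    se = np.sqrt(np.diag(np.linalg.inv(info))) if converged else np.full(p, np.nan)
    z = beta / se
    pvals = 2 * norm_dist.sf(np.abs(z))
    cols = list(x.columns)
    return CoxResult(
        coef=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        p=pd.Series(pvals, index=cols),
        converged=converged,
        n=n, n_events=int(e.sum()), loglik=float(loglik),
    )


_STAGE_ORD = {"I": 1, "II": 2, "III": 3, "IV": 4}


def build_cox_design(
    meta: Sequence[SampleRecord],
    expression: pd.Series | None = None,
    floor_log: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix for the multivariate Cox model (complete cases).

    Covariates: miRNA expression as log2(RPKM+1) (optional), age, sex
    (one-hot, reference M), ethnicity (one-hot, first level reference),
    ordinal stage, smoking status (one-hot, reference CS).  Returns
    ``(X, times, events)`` over tumor samples with survival data.
    """
    rows = []
    for r in meta:
        if r.tissue != "tumor" or r.surv_time is None:
            continue
        expr = None
        if expression is not None:
            if r.sample_id not in expression.index:
                continue
            v = expression[r.sample_id]
            expr = math.log2(v + 1.0) if floor_log else v
        if r.age is None or r.sex == "unknown" or r.stage == "unknown":
            continue
        rows.append({
            "sample_id": r.sample_id,
            "expression": expr,
            "age": r.age,
            "sex_F": 1.0 if r.sex == "F" else 0.0,
            "ethnicity": r.ethnicity,
            "stage": float(_STAGE_ORD[r.stage]),
            "smoking_FS": 1.0 if r.smoking == "FS" else 0.0,
            "smoking_NS": 1.0 if r.smoking == "NS" else 0.0,
            "time": r.surv_time,
            "event": float(bool(r.event)),
        })
    df = pd.DataFrame(rows).set_index("sample_id")
    if expression is None:
        df = df.drop(columns=["expression"])
    eth_levels = sorted(df["ethnicity"].unique())
    for lvl in eth_levels[1:]:  # first level is the reference
        df[f"ethnicity_{lvl}"] = (df["ethnicity"] == lvl).astype(float)
    df = df.drop(columns=["ethnicity"])
    times = df.pop("time").to_numpy()
    events = df.pop("event").to_numpy().astype(bool)
    return df, times, events


def expression_covariate_manova(
    expression: pd.Series,
    meta: Sequence[SampleRecord],
    covariates: Sequence[str] = ("smoking", "sex", "stage", "ethnicity"),
    n_bins: int = 3,
) -> pd.DataFrame:
    """Association of a miRNA's expression with clinical covariates.

    Expression (log2(RPKM+1), per tumor sample) is the response in a
    one-way analysis per covariate via :func:`stats.manova_wilks`.
    Numeric covariates (age, pack-years) are discretized into
    ``n_bins`` quantile bins for grouping.  Single-level covariates are
    skipped with a warning.
    """
    by_id = {r.sample_id: r for r in meta}
    ids = [s for s in expression.index if s in by_id]
    y = np.log2(expression[ids].to_numpy(dtype=float) + 1.0)
    rows = []
    for cov in covariates:
        raw = [getattr(by_id[s], cov) for s in ids]
        if all(v is None for v in raw):
            warnings.warn(f"covariate {cov!r} all-missing; skipped", stacklevel=2)
            continue
        if isinstance(next(v for v in raw if v is not None), (int, float)):
            vals = np.array([np.nan if v is None else float(v) for v in raw])
            ok = ~np.isnan(vals)
            if ok.sum() < 6:
                warnings.warn(f"covariate {cov!r} too sparse; skipped", stacklevel=2)
                continue
            qs = np.quantile(vals[ok], np.linspace(0, 1, n_bins + 1)[1:-1])
            groups = np.digitize(vals, qs).astype(object)
            groups[~ok] = None
        else:
            groups = np.array([v if v not in (None, "unknown") else None
                               for v in raw], dtype=object)
        keep = np.array([g is not None for g in groups])
        glab = groups[keep].astype(str)
        if np.unique(glab).size < 2:
            warnings.warn(f"covariate {cov!r} single-level; skipped", stacklevel=2)
            continue
        res = stats.manova_wilks(y[keep][:, None], glab)
        rows.append((cov, float(res.per_response_f[0]),
                     float(res.per_response_p[0]), int(keep.sum())))
    return pd.DataFrame(rows, columns=["covariate", "F", "p", "n"])
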