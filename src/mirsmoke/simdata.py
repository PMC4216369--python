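"""Synthetic cohort generator with planted ground truth.

Emulates the statistical shape of a paired tumor/normal miRNA-seq cohort
stratified by smoking status: heavy-tailed (log-normal) RPKM values, a
block of rows below the 1-RPKM detection floor, tumor effects that are
mostly overexpression, smoking-group-specific planted miRNAs with a
recurrence ("penetrance") fraction, smoke-response patterns in normal
tissue that are reversible or irreversible after smoking cessation, and
survival times whose hazard scales with the expression of a designated
prognostic miRNA.

The generator is deterministic: one ``numpy`` PCG64 stream seeded from
``SimulationConfig.seed`` drives every draw, so identical configurations
produce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dataio import ExpressionMatrix, SampleRecord, SMOKING_GROUPS


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SmokeResponseConfig:
    """Planted normal-tissue smoke-response rows.

    ``n_up``/``n_down`` rows are shifted in current-smoker normals
    relative to never-smoker normals.  Of those, ``n_reversible`` have
    former-smoker normals back at the never-smoker level, and
    ``n_irreversible`` keep the full shift in former-smoker normals;
    any remainder carries an intermediate former-smoker shift
    (``fold ** partial_exponent``) and is labelled ``partial`` in the
    ground truth — by construction its reversibility is boundary-
    dependent, emulating real cohorts where only a subset of
    smoke-responsive miRNAs classify cleanly.
    """

    n_up: int = 25
    n_down: int = 12
    n_reversible: int = 2
    n_irreversible: int = 15
    fold: float = 4.0
    partial_exponent: float = 0.4

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CS": 43, "FS": 24, "NS": 27})
    n_mirna: int = 1372
    baseline_log_mean: float = 2.5       # natural-log RPKM of detectable rows
    baseline_log_sd: float = 1.5
    frac_undetectable: float = 445 / 1372
    planted_shared: tuple[int, int] = (196, 36)         # (over, under), all groups
    planted_partial: tuple[int, int] = (56, 12)         # (over, under), 2 of 3 groups
    planted_specific: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"CS": (14, 11), "FS": (12, 2), "NS": (26, 1)})
    tumor_fc: float = 4.0
    penetrance: float = 0.5
    smoke_response: SmokeResponseConfig = field(default_factory=SmokeResponseConfig)
    noise_log_sd: float = 0.2
    surv_baseline_hazard: float = 0.02   # events / month
    surv_loghr: float = 0.7              # per SD of log2(RPKM+1) of prognostic miRNA
    censor_rate: float = 0.3
    cohort_tag: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.penetrance <= 1):
            raise ConfigError("penetrance must lie in (0, 1]")
        if not (0 <= self.frac_undetectable < 1):
            raise ConfigError("frac_undetectable must lie in [0, 1)")
        if self.smoke_response.n_reversible + self.smoke_response.n_irreversible \
                > self.smoke_response.n_total:
            raise ConfigError("reversible + irreversible exceeds smoke-response rows")
        if self.n_planted + self.n_undetectable > self.n_mirna:
            raise ConfigError("planted + undetectable rows exceed n_mirna")
        for g in self.n_per_group:
            if g not in SMOKING_GROUPS:
                raise ConfigError(f"unknown smoking group {g!r}")

    @property
    def n_undetectable(self) -> int:
        return int(round(self.frac_undetectable * self.n_mirna))

    @property
    def n_planted(self) -> int:
        n = sum(self.planted_shared) + sum(self.planted_partial)
        n += sum(o + u for o, u in self.planted_specific.values())
        n += self.smoke_response.n_total
        return n


@dataclass(frozen=True)
class GroundTruth:
    """Planted-row labels; the answer key for recovery scoring."""

    #: miRNA -> (pattern, direction); pattern in {"shared","CS","FS","NS"},
    #: direction in {"over","under"}
    tumor_labels: Mapping[str, tuple[str, str]]
    #: miRNA -> (direction in {"up","down"},
    #:           class in {"reversible","irreversible","partial"})
    smoke_labels: Mapping[str, tuple[str, str]]
    #: miRNA -> true log hazard ratio per SD of log2(RPKM+1)
    prognostic: Mapping[str, float]
    undetectable: frozenset[str]
    mirna_ids: tuple[str, ...]

    def specific(self, group: str, direction: str) -> set[str]:
        return {m for m, (g, d) in self.tumor_labels.items()
                if g == group and d == direction}

    def label_of(self, mirna: str) -> str:
        if mirna in self.tumor_labels:
            g, d = self.tumor_labels[mirna]
            return f"{g}-{d}"
        if mirna in self.undetectable:
            return "undetectable"
        return "null"


@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: Mapping[str, float]
    fdp: float
    n_calls: int


def _censor_horizon(hazard: float, target: float) -> float:
    """Administrative-censoring horizon giving the target censored fraction.

    With entry uniform over ``[0, a]`` before an administrative cutoff,
    the censoring time is Uniform(0, a) and the censored fraction under
    an exponential event model with rate ``h`` is ``(1 - e^{-ha})/(ha)``;
    solve for ``a``.
    """
    if target <= 0:
        return math.inf
    if target >= 1:
        raise ConfigError("censor_rate must be < 1")

    def frac(a: float) -> float:
        return (1 - math.exp(-hazard * a)) / (hazard * a) - target

    return brentq(frac, 1e-9 / hazard, 1e4 / hazard)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleRecord], GroundTruth]:
    """Generate a paired tumor/normal cohort with planted effects."""
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.smoke_response

    # ---- patients and samples -------------------------------------------
    patients: list[tuple[str, str]] = []      # (patient_id, group)
    for g in SMOKING_GROUPS:
        for i in range(cfg.n_per_group.get(g, 0)):
            patients.append((f"P-{g}{i:03d}", g))
    n_pat = len(patients)
    tumor_ids = [f"{p}-T" for p, _ in patients]
    normal_ids = [f"{p}-N" for p, _ in patients]
    sample_ids = tumor_ids + normal_ids
    groups = np.array([g for _, g in patients])

    # ---- row layout ------------------------------------------------------
    mirna_ids = [f"sim-mir-{i:04d}" for i in range(cfg.n_mirna)]
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        rows = list(range(cursor, cursor + n))
        cursor += n
        return rows

    undetectable_rows = take(cfg.n_undetectable)
    shared_over = take(cfg.planted_shared[0])
    shared_under = take(cfg.planted_shared[1])
    # partial rows: altered in exactly two groups, cycling over group pairs
    group_pairs = [("CS", "FS"), ("CS", "NS"), ("FS", "NS")]
    partial_rows: list[tuple[int, tuple[str, str], str]] = []
    for direction, count in zip(("over", "under"), cfg.planted_partial):
        for j, r in enumerate(take(count)):
            partial_rows.append((r, group_pairs[j % 3], direction))
    specific_rows: dict[str, tuple[list[int], list[int]]] = {}
    for g in SMOKING_GROUPS:
        o, u = cfg.planted_specific.get(g, (0, 0))
        specific_rows[g] = (take(o), take(u))
    smoke_up = take(sr.n_up)
    smoke_down = take(sr.n_down)

    # reversibility classes drawn over the combined up+down smoke rows
    smoke_all = smoke_up + smoke_down
    rev_rows = smoke_all[: sr.n_reversible]
    irrev_rows = smoke_all[sr.n_reversible: sr.n_reversible + sr.n_irreversible]
    smoke_partial = smoke_all[sr.n_reversible + sr.n_irreversible:]

    # ---- baseline expression --------------------------------------------
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                 size=cfg.n_mirna))
    baseline = np.maximum(baseline, 2.0)  # detectable rows clear the floor
    # planted rows sit in the clearly detectable regime: a 4-fold drop from
    # a near-floor baseline saturates at the detection floor and carries no
    # recoverable signal, which no real recurrently-altered miRNA would show
    planted_rows = list(range(len(undetectable_rows), cursor))
    if planted_rows:
        baseline[planted_rows] = np.maximum(baseline[planted_rows], 10.0)
    if undetectable_rows:
        baseline[undetectable_rows] = rng.uniform(0.001, 0.1,
                                                  size=len(undetectable_rows))

    # multiplicative log-normal sample noise
    noise = np.exp(rng.normal(0.0, cfg.noise_log_sd,
                              size=(cfg.n_mirna, 2 * n_pat)))
    values = baseline[:, None] * noise
    tumor_cols = np.arange(n_pat)                # columns 0..n_pat-1
    normal_cols = np.arange(n_pat, 2 * n_pat)

    # ---- tumor effects (shared + group-specific, Bernoulli penetrance) ---
    def apply_tumor_effect(rows: Iterable[int], factor: float,
                           group: str | None) -> None:
        # exactly round(penetrance * n) carriers per planted row, so the
        # configured recurrence fraction is realized in every row rather
        # than fluctuating binomially around it
        pat_mask = np.ones(n_pat, bool) if group is None else (groups == group)
        idx = np.where(pat_mask)[0]
        k = int(round(cfg.penetrance * idx.size))
        for r in rows:
            carriers = rng.choice(idx, size=k, replace=False)
            values[r, tumor_cols[carriers]] *= factor

    apply_tumor_effect(shared_over, cfg.tumor_fc, None)
    apply_tumor_effect(shared_under, 1.0 / cfg.tumor_fc, None)
    for r, pair, direction in partial_rows:
        factor = cfg.tumor_fc if direction == "over" else 1.0 / cfg.tumor_fc
        for g in pair:
            apply_tumor_effect([r], factor, g)
    for g in SMOKING_GROUPS:
        over_rows, under_rows = specific_rows[g]
        apply_tumor_effect(over_rows, cfg.tumor_fc, g)
        apply_tumor_effect(under_rows, 1.0 / cfg.tumor_fc, g)

    # ---- smoke-response effects (tissue-wide per smoking group) ----------
    # Shifts apply to BOTH tissues of the affected group so that the
    # CSN-vs-NSN contrast sees them while paired tumor/normal folds do not.
    cs_pat = np.where(groups == "CS")[0]
    fs_pat = np.where(groups == "FS")[0]

    def shift_group(rows: list[int], pat: np.ndarray, factor: float) -> None:
        cols = np.concatenate([tumor_cols[pat], normal_cols[pat]])
        for r in rows:
            values[r, cols] *= factor

    for rows, up in ((smoke_up, True), (smoke_down, False)):
        base = sr.fold if up else 1.0 / sr.fold
        shift_group(rows, cs_pat, base)
        shift_group([r for r in rows if r in irrev_rows], fs_pat, base)
        part = base ** sr.partial_exponent
        shift_group([r for r in rows if r in smoke_partial], fs_pat, part)

    # keep the undetectable block strictly below the floor
    if undetectable_rows:
        values[undetectable_rows] = np.minimum(values[undetectable_rows], 0.999)

    # ---- survival --------------------------------------------------------
    prognostic_row = shared_over[0] if shared_over else None
    surv_time = np.full(n_pat, np.nan)
    event = np.zeros(n_pat, bool)
    if prognostic_row is not None and cfg.surv_baseline_hazard > 0:
        expr = np.log2(values[prognostic_row, tumor_cols] + 1.0)
        z = (expr - expr.mean()) / (expr.std() if expr.std() > 0 else 1.0)
        hazard = cfg.surv_baseline_hazard * np.exp(cfg.surv_loghr * z)
        t_event = rng.exponential(1.0 / hazard)
        horizon = _censor_horizon(cfg.surv_baseline_hazard, cfg.censor_rate)
        if math.isinf(horizon):
            surv_time, event = t_event, np.ones(n_pat, bool)
        else:
            c = rng.uniform(0, horizon, size=n_pat)
            event = t_event <= c
            surv_time = np.minimum(t_event, c)

    # ---- clinical covariates --------------------------------------------
    ages = np.clip(rng.normal(65, 8, size=n_pat), 40, 88).round(1)
    sexes = rng.choice(["M", "F"], size=n_pat)
    stages = rng.choice(["I", "II", "III", "IV"], size=n_pat,
                        p=[0.60, 0.25, 0.10, 0.05])
    records: list[SampleRecord] = []
    for i, (pid, g) in enumerate(patients):
        if g == "NS":
            ethnicity = "Asian" if rng.random() < 0.6 else "Caucasian"
            pack_years: float | None = 0.0
            years_quit = None
        else:
            ethnicity = "Caucasian" if rng.random() < 0.85 else "Asian"
            pack_years = float(np.round(rng.gamma(4.0, 10.0), 1))
            pack_years = max(pack_years, 0.5)
            years_quit = (float(np.round(rng.uniform(1, 30), 1))
                          if g == "FS" else None)
        st = float(np.round(surv_time[i], 2)) if np.isfinite(surv_time[i]) else None
        ev = bool(event[i]) if st is not None else None
        common = dict(patient_id=pid, smoking=g, age=float(ages[i]),
                      sex=str(sexes[i]), stage=str(stages[i]),
                      ethnicity=ethnicity, pack_years=pack_years,
                      years_quit=years_quit, surv_time=st, event=ev,
                      cohort=cfg.cohort_tag)
        records.append(SampleRecord(sample_id=tumor_ids[i], tissue="tumor", **common))
        records.append(SampleRecord(sample_id=normal_ids[i], tissue="normal", **common))

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=mirna_ids, columns=sample_ids))

    # ---- ground truth ----------------------------------------------------
    tumor_labels: dict[str, tuple[str, str]] = {}
    for r in shared_over:
        tumor_labels[mirna_ids[r]] = ("shared", "over")
    for r in shared_under:
        tumor_labels[mirna_ids[r]] = ("shared", "under")
    for r, pair, direction in partial_rows:
        tumor_labels[mirna_ids[r]] = ("+".join(pair), direction)
    for g in SMOKING_GROUPS:
        over_rows, under_rows = specific_rows[g]
        for r in over_rows:
            tumor_labels[mirna_ids[r]] = (g, "over")
        for r in under_rows:
            tumor_labels[mirna_ids[r]] = (g, "under")
    smoke_labels: dict[str, tuple[str, str]] = {}
    for r in smoke_all:
        direction = "up" if r in set(smoke_up) else "down"
        if r in rev_rows:
            cls = "reversible"
        elif r in irrev_rows:
            cls = "irreversible"
        else:
            cls = "partial"
        smoke_labels[mirna_ids[r]] = (direction, cls)
    prognostic = ({mirna_ids[prognostic_row]: cfg.surv_loghr}
                  if prognostic_row is not None else {})
    truth = GroundTruth(
        tumor_labels=tumor_labels,
        smoke_labels=smoke_labels,
        prognostic=prognostic,
        undetectable=frozenset(mirna_ids[r] for r in undetectable_rows),
        mirna_ids=tuple(mirna_ids),
    )
    return matrix, records, truth


def score_recovery(
    called: Mapping[str, str],
    truth_labels: Mapping[str, str],
    universe: Iterable[str],
    ignore_truth: frozenset[str] = frozenset(),
) -> RecoveryScore:
    """Per-label sensitivity and false-discovery proportion of a call set.

    ``called`` maps miRNA -> predicted label; ``truth_labels`` maps
    miRNA -> planted label (rows absent from it are nulls).  Rows whose
    truth label is in ``ignore_truth`` count toward neither sensitivity
    nor FDP.  Empty call sets score sensitivity 0 and, by convention,
    FDP 0.
    """
    universe = set(universe)
    stray = set(called) - universe
    if stray:
        raise ValueError(f"calls outside miRNA universe: {sorted(stray)[:5]}")
    if set(truth_labels) - universe:
        raise ValueError("truth labels outside miRNA universe")

    sens: dict[str, float] = {}
    labels = {lbl for lbl in truth_labels.values() if lbl not in ignore_truth}
    for lbl in sorted(labels):
        planted = [m for m, t in truth_labels.items() if t == lbl]
        hit = sum(1 for m in planted if called.get(m) == lbl)
        sens[lbl] = hit / len(planted)

    n_calls = false = 0
    for m, lbl in called.items():
        t = truth_labels.get(m, "null")
        if t in ignore_truth:
            continue
        n_calls += 1
        if lbl != t:
            false += 1
    fdp = false / n_calls if n_calls else 0.0
    return RecoveryScore(sensitivity=sens, fdp=fdp, n_calls=n_calls)
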