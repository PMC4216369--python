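"""Differential-expression calling, smoking-status specificity,
reversibility, and external-cohort validation.

Four layers of evidence are computed from RPKM tables:

1. **Smoke-response DE** between two unpaired normal-tissue groups
   (canonically current-smoker vs never-smoker normals): a 10,000-
   permutation test per miRNA on log2(RPKM+1), Benjamini–Hochberg
   corrected, combined with an average fold-change criterion
   (> 2 or < 0.5 on detection-floored group means).
2. **Recurrence calls** within each smoking group's matched pairs: a
   paired Wilcoxon signed-rank test on per-pair log2 folds (B-H across
   the group's miRNA family) AND a fold change beyond 2 / 0.5 in at
   least 25% of the group's tumors.
3. **Specificity**: per direction, a miRNA meeting the recurrence
   criteria in exactly one smoking group is smoking-status-specific;
   in all three it is shared; in two, partial.
4. **Reversibility** in former-smoker normals: a smoke-responsive miRNA
   (DE in CS vs NS normals) is irreversible if the FS-vs-NS normal
   contrast is DE in the same direction, reversible if that contrast
   fails the DE criteria, and not-smoke-responsive (with a warning
   record) if it flips direction.

Fold changes use the detection floor: both numerator and denominator
are raised to ``max(value, 1.0)`` before dividing, consistent with
treating RPKM < 1 as not expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .dataio import ExpressionMatrix, PairedCohort, SMOKING_GROUPS


@dataclass(frozen=True)
class AnalysisConfig:
    q_threshold: float = 0.05
    fc_over: float = 2.0
    recurrence_frac: float = 0.25
    n_perm: int = 10000
    validation_min_freq_diff: float = 0.15
    detection_floor: float = 1.0
    seed: int = 0

    @property
    def fc_under(self) -> float:
        return 1.0 / self.fc_over


def fold_change(tumor_rpkm: float, normal_rpkm: float, floor: float = 1.0) -> float:
    """Detection-floored expression ratio ``max(t, floor) / max(n, floor)``."""
    if tumor_rpkm < 0 or normal_rpkm < 0:
        raise ValueError("RPKM values must be non-negative")
    return max(tumor_rpkm, floor) / max(normal_rpkm, floor)


def _floored(a: np.ndarray, floor: float) -> np.ndarray:
    return np.maximum(a, floor)


def smoke_response_de(
    m: ExpressionMatrix,
    group_a_samples: list[str],
    group_b_samples: list[str],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Per-miRNA permutation DE between two unpaired sample groups.

    Returns a DataFrame indexed by miRNA with columns ``p``, ``q``,
    ``mean_fold`` (ratio of detection-floored group means, A over B)
    and ``status`` in {"over", "under", "none"}.
    """
    if len(group_a_samples) < 2 or len(group_b_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = m.subset_samples(group_a_samples).data.to_numpy()
    b = m.subset_samples(group_b_samples).data.to_numpy()
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    _, p = stats.permutation_test_matrix(la, lb, n_perm=cfg.n_perm, seed=cfg.seed)
    q = stats.benjamini_hochberg(p)
    fold = (_floored(a, cfg.detection_floor).mean(axis=1)
            / _floored(b, cfg.detection_floor).mean(axis=1))
    status = np.where(
        (q < cfg.q_threshold) & (fold > cfg.fc_over), "over",
        np.where((q < cfg.q_threshold) & (fold < cfg.fc_under), "under", "none"))
    return pd.DataFrame(
        {"p": p, "q": q, "mean_fold": fold, "status": status},
        index=pd.Index(m.mirna_ids, name="mirna_id"))


def pair_folds(
    cohort: PairedCohort, m: ExpressionMatrix, floor: float = 1.0
) -> pd.DataFrame:
    """Per-pair detection-floored tumor/normal fold changes (miRNA x pair)."""
    t = _floored(m.subset_samples(cohort.tumor_ids).data.to_numpy(), floor)
    n = _floored(m.subset_samples(cohort.normal_ids).data.to_numpy(), floor)
    return pd.DataFrame(t / n, index=m.mirna_ids,
                        columns=[p for p, _, _ in cohort.pairs])


def recurrence_calls(
    cohort: PairedCohort,
    m: ExpressionMatrix,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Recurrence ("penetrance") DE calls for one smoking group.

    For every miRNA: Wilcoxon signed-rank on per-pair log2 folds, with
    Benjamini–Hochberg applied across the whole miRNA family of this
    group, plus the fold-recurrence criterion (fold > 2 or < 0.5 in at
    least 25% of pairs, inclusive).  ``direction`` is assigned only when
    both criteria hold; if both tails pass the larger frequency wins and
    an exact tie yields "none".
    """
    if cohort.n_pairs < 4:
        raise ValueError("recurrence calling needs >= 4 pairs")
    folds = pair_folds(cohort, m, cfg.detection_floor)
    log_folds = np.log2(folds.to_numpy())
    pvals = np.array([
        stats.wilcoxon_signed_rank(row).p_value for row in log_folds])
    q = stats.benjamini_hochberg(pvals)
    freq_over = (folds.to_numpy() > cfg.fc_over).mean(axis=1)
    freq_under = (folds.to_numpy() < cfg.fc_under).mean(axis=1)
    sig = q < cfg.q_threshold
    over_ok = sig & (freq_over >= cfg.recurrence_frac)
    under_ok = sig & (freq_under >= cfg.recurrence_frac)
    direction = np.full(len(folds), "none", dtype=object)
    only_over = over_ok & (~under_ok | (freq_over > freq_under))
    only_under = under_ok & (~over_ok | (freq_under > freq_over))
    direction[only_over] = "over"
    direction[only_under] = "under"
    direction[over_ok & under_ok & (freq_over == freq_under)] = "none"
    return pd.DataFrame(
        {"group": cohort.group, "wilcoxon_p": pvals, "bh_q": q,
         "freq_over": freq_over, "freq_under": freq_under,
         "direction": direction},
        index=pd.Index(m.mirna_ids, name="mirna_id"))


def classify_specificity(
    calls_by_group: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Smoking-status specificity pattern per (miRNA, direction).

    A miRNA meeting the recurrence criteria in exactly one group is
    ``"<group>-specific"``; in all three, ``shared-all``; in two,
    ``partial``.  A miRNA may carry one call per direction (e.g. under
    in CS tumors and over in NS tumors).
    """
    missing = set(SMOKING_GROUPS) - set(calls_by_group)
    if missing:
        raise ValueError(f"missing recurrence calls for groups {sorted(missing)}")
    index = calls_by_group[SMOKING_GROUPS[0]].index
    for g in SMOKING_GROUPS[1:]:
        if not calls_by_group[g].index.equals(index):
            raise ValueError("recurrence tables index different miRNA sets")
    rows = []
    for direction in ("over", "under"):
        hit = {g: calls_by_group[g]["direction"] == direction
               for g in SMOKING_GROUPS}
        n_groups = sum(hit.values())  # elementwise over miRNAs
        for mirna in index:
            k = int(n_groups[mirna])
            if k == 0:
                continue
            if k == 3:
                pattern = "shared-all"
            elif k == 2:
                pattern = "partial"
            else:
                g = next(g for g in SMOKING_GROUPS if hit[g][mirna])
                pattern = f"{g}-specific"
            rows.append((mirna, direction, pattern, k))
    return pd.DataFrame(rows, columns=["mirna_id", "direction", "pattern",
                                       "n_groups"])


@dataclass(frozen=True)
class SpecificitySummary:
    """Headline counts of the specificity classification."""

    n_over: int            # miRNAs over in >= 1 group
    n_under: int
    n_shared_over: int     # over in all three groups
    n_shared_under: int
    n_specific: dict = field(default_factory=dict)  # group -> (over, under)

    @property
    def n_total(self) -> int:
        return self.n_over + self.n_under

    @property
    def pct_overexpressed(self) -> float:
        return 100.0 * self.n_over / self.n_total if self.n_total else 0.0

    @property
    def pct_shared_over(self) -> float:
        return 100.0 * self.n_shared_over / self.n_over if self.n_over else 0.0

    @property
    def pct_shared_under(self) -> float:
        return 100.0 * self.n_shared_under / self.n_under if self.n_under else 0.0

    @property
    def n_specific_total(self) -> int:
        return sum(o + u for o, u in self.n_specific.values())


def summarize_specificity(spec: pd.DataFrame) -> SpecificitySummary:
    """Aggregate a specificity table into the headline counts/ratios."""
    over = spec[spec["direction"] == "over"]
    under = spec[spec["direction"] == "under"]
    n_specific = {}
    for g in SMOKING_GROUPS:
        pat = f"{g}-specific"
        n_specific[g] = (int((over["pattern"] == pat).sum()),
                         int((under["pattern"] == pat).sum()))
    return SpecificitySummary(
        n_over=len(over),
        n_under=len(under),
        n_shared_over=int((over["pattern"] == "shared-all").sum()),
        n_shared_under=int((under["pattern"] == "shared-all").sum()),
        n_specific=n_specific,
    )


def classify_reversibility(
    csn_de: pd.DataFrame,
    fsn_de: pd.DataFrame,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Reversible vs irreversible smoke-response classification.

    ``csn_de`` is the CS-normal vs NS-normal DE table, ``fsn_de`` the
    FS-normal vs NS-normal table (both from :func:`smoke_response_de`).
    Smoke-responsive miRNAs (CSN status != none) are irreversible when
    the FSN contrast is DE in the same direction, reversible when the
    FSN contrast fails the DE criteria, and demoted to
    not-smoke-responsive with a warning flag when the FSN contrast is DE
    in the opposite direction.
    """
    if not csn_de.index.equals(fsn_de.index):
        raise ValueError("DE tables index different miRNA sets")
    cls = np.full(len(csn_de), "not-smoke-responsive", dtype=object)
    conflict = np.zeros(len(csn_de), dtype=bool)
    cs_status = csn_de["status"].to_numpy()
    fs_status = fsn_de["status"].to_numpy()
    responsive = cs_status != "none"
    same = responsive & (fs_status == cs_status)
    opposite = responsive & (fs_status != "none") & (fs_status != cs_status)
    reversible = responsive & (fs_status == "none")
    cls[same] = "irreversible"
    cls[reversible] = "reversible"
    conflict[opposite] = True
    if conflict.any():
        warnings.warn(
            f"{int(conflict.sum())} miRNA(s) DE in opposite directions in "
            "CS- and FS-normal contrasts; classified not-smoke-responsive",
            stacklevel=2)
    return pd.DataFrame(
        {"class": cls, "csn_status": cs_status, "fsn_status": fs_status,
         "csn_fold": csn_de["mean_fold"], "fsn_fold": fsn_de["mean_fold"],
         "direction_conflict": conflict},
        index=csn_de.index)


def disruption_frequencies(
    tumors: ExpressionMatrix,
    pooled_normal_mean: pd.Series,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Per-miRNA disruption counts in an external (unpaired) tumor set.

    Each tumor's fold change is computed against the pooled mean of the
    matching-smoking-status normal samples (both sides detection-
    floored); a tumor is disrupted when the fold passes > 2 or < 0.5.
    Returns ``k_over``, ``k_under``, ``n`` per miRNA.
    """
    vals = _floored(tumors.data.to_numpy(), cfg.detection_floor)
    ref = _floored(pooled_normal_mean.reindex(tumors.mirna_ids).to_numpy(),
                   cfg.detection_floor)[:, None]
    fold = vals / ref
    return pd.DataFrame(
        {"k_over": (fold > cfg.fc_over).sum(axis=1),
         "k_under": (fold < cfg.fc_under).sum(axis=1),
         "n": tumors.n_samples},
        index=pd.Index(tumors.mirna_ids, name="mirna_id"))


def external_validation(
    k_focal: int, n_focal: int, k_rest: int, n_rest: int,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[bool, stats.TestResult, float]:
    """External-cohort validation rule for one miRNA and focal group.

    Validated iff Fisher exact p < 0.05 on the 2x2 table
    (disrupted / not) x (focal group / rest) AND the disruption-
    frequency difference is at least 15 percentage points.
    Returns ``(validated, fisher_result, freq_difference)``.
    """
    if n_focal == 0 or n_rest == 0:
        raise ValueError("empty group in validation test")
    if k_focal > n_focal or k_rest > n_rest:
        raise ValueError("disruption count exceeds group size")
    res = stats.fisher_exact_2x2(
        [[k_focal, n_focal - k_focal], [k_rest, n_rest - k_rest]])
    freq_diff = abs(k_focal / n_focal - k_rest / n_rest)
    validated = (res.p_value < 0.05
                 and freq_diff >= cfg.validation_min_freq_diff)
    return validated, res, freq_diff


def write_de_results(
    calls_by_group: dict[str, pd.DataFrame],
    spec: pd.DataFrame,
    path: str,
) -> None:
    """Flat TSV export: one row per (miRNA, group) with specificity joined."""
    frames = []
    for g in SMOKING_GROUPS:
        df = calls_by_group[g].reset_index()
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    pat = spec.set_index(["mirna_id", "direction"])["pattern"]
    out["pattern"] = [
        pat.get((m, d), "") if d != "none" else ""
        for m, d in zip(out["mirna_id"], out["direction"])]
    out.to_csv(path, sep="\t", index=False)
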