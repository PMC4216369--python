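"""Unsupervised Ward clustering of expression profiles and assessment of
cluster composition against malignancy, smoking status, and clinical
covariates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

from . import stats
from .dataio import ExpressionMatrix, SampleRecord


@dataclass(frozen=True)
class ClusterAssignment:
    labels: Mapping[str, int]      # sample_id -> cluster 1..k
    linkage_matrix: np.ndarray     # scipy merge tree with heights
    k: int

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]


def _preprocess(m: ExpressionMatrix) -> np.ndarray:
    """log2(RPKM+1), then z-score each miRNA across samples.

    Zero-variance rows carry no clustering information and are dropped.
    Returns a samples x features array.
    """
    x = np.log2(m.data.to_numpy() + 1.0)
    sd = x.std(axis=1)
    keep = sd > 0
    x = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return x.T


def ward_cluster(m: ExpressionMatrix, k: int) -> ClusterAssignment:
    """Ward (D2) agglomerative clustering of samples; tree cut into k.

    Samples are clustered on Euclidean distance of row-standardized
    log2(RPKM+1) profiles using the Lance–Williams Ward update, then the
    dendrogram is cut to exactly ``k`` clusters.  Cluster labels are
    renumbered 1..k in order of first appearance along the sample axis.
    """
    if k < 1 or k > m.n_samples:
        raise ValueError(f"k = {k} outside 1..{m.n_samples}")
    x = _preprocess(m)
    z = linkage(x, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = {}
    for sid, c in zip(m.sample_ids, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[sid] = relabel[c]
    return ClusterAssignment(labels=labels, linkage_matrix=z, k=len(relabel))


def cluster_composition_test(
    assign: ClusterAssignment, labels: Mapping[str, str]
) -> stats.TestResult:
    """Association between cluster membership and a categorical label.

    2x2 tables go to the Fisher exact test, anything larger to Pearson
    chi-square.
    """
    sample_ids = list(assign.labels)
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples {missing[:5]}")
    cats = sorted({labels[s] for s in sample_ids})
    if len(cats) < 2:
        raise ValueError("labels must have at least two levels")
    clusters = sorted(set(assign.labels.values()))
    table = np.zeros((len(clusters), len(cats)), dtype=int)
    for s in sample_ids:
        table[clusters.index(assign.labels[s]), cats.index(labels[s])] += 1
    if table.shape == (2, 2):
        return stats.fisher_exact_2x2(table)
    return stats.chi_square_independence(table)


_CATEGORICAL_CODES = {
    "sex": {"M": 0, "F": 1},
    "stage": {"I": 1, "II": 2, "III": 3, "IV": 4},
}


def _covariate_values(meta: Mapping[str, SampleRecord], covariate: str,
                      sample_ids: Sequence[str]) -> np.ndarray:
    raw = [getattr(meta[s], covariate) for s in sample_ids]
    if covariate == "ethnicity":
        cats = sorted({v for v in raw if v not in (None, "unknown")})
        codes = {c: float(i) for i, c in enumerate(cats)}
        return np.array([codes.get(v, np.nan) if v is not None else np.nan
                         for v in raw])
    vals = np.full(len(sample_ids), np.nan)
    for i, v in enumerate(raw):
        if v is None:
            continue
        if covariate in _CATEGORICAL_CODES:
            vals[i] = _CATEGORICAL_CODES[covariate].get(v, np.nan)
        else:
            vals[i] = float(v)
    return vals


def cluster_covariate_scan(
    assign: ClusterAssignment,
    meta: Sequence[SampleRecord],
    covariates: Sequence[str] = ("age", "pack_years", "years_quit", "stage", "sex"),
) -> pd.DataFrame:
    """Per-covariate one-way F of the covariate across cluster labels.

    Categorical covariates are integer-coded (stage ordinally).  A
    covariate missing for every sample is skipped with a warning.
    Complete cases per covariate.
    """
    by_id = {r.sample_id: r for r in meta}
    sample_ids = [s for s in assign.labels if s in by_id]
    groups = np.array([assign.labels[s] for s in sample_ids])
    rows = []
    for cov in covariates:
        vals = _covariate_values(by_id, cov, sample_ids)
        ok = ~np.isnan(vals)
        if ok.sum() == 0 or np.unique(groups[ok]).size < 2:
            warnings.warn(f"covariate {cov!r} skipped (all missing or one cluster)",
                          stacklevel=2)
            continue
        if np.ptp(vals[ok]) == 0:
            rows.append((cov, 0.0, 1.0, int(ok.sum())))
            continue
        res = stats.manova_wilks(vals[ok][:, None], groups[ok])
        rows.append((cov, float(res.per_response_f[0]),
                     float(res.per_response_p[0]), int(ok.sum())))
    return pd.DataFrame(rows, columns=["covariate", "F", "p", "n"])


def two_cluster_ttest(
    assign: ClusterAssignment,
    meta: Sequence[SampleRecord],
    covariate: str,
    cluster_a: int,
    cluster_b: int,
) -> stats.TestResult:
    """Welch t-test of a numeric covariate between two named clusters."""
    by_id = {r.sample_id: r for r in meta}
    def pull(cluster: int) -> np.ndarray:
        ids = [s for s in assign.members(cluster) if s in by_id]
        v = _covariate_values(by_id, covariate, ids)
        return v[~np.isnan(v)]
    a, b = pull(cluster_a), pull(cluster_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each cluster needs >= 2 non-missing values")
    t, p = ttest_ind(a, b, equal_var=False)
    return stats.TestResult(float(t), float(p), "welch-t", (a.size, b.size))


def between_cluster_de(
    m: ExpressionMatrix,
    assign: ClusterAssignment,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Kruskal–Wallis of each miRNA across clusters, B-H corrected."""
    clusters = sorted(set(assign.labels.values()))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    cols = {c: [s for s in m.sample_ids if assign.labels.get(s) == c]
            for c in clusters}
    small = [c for c, ids in cols.items() if len(ids) < 2]
    if small:
        warnings.warn(f"clusters {small} have < 2 samples; KW may be unstable",
                      stacklevel=2)
    data = {c: m.subset_samples(ids).data.to_numpy() for c, ids in cols.items()
            if len(ids) >= 1}
    h = np.empty(m.n_mirna)
    p = np.empty(m.n_mirna)
    for i in range(m.n_mirna):
        res = stats.kruskal_wallis([data[c][i] for c in data])
        h[i], p[i] = res.statistic, res.p_value
    q = stats.benjamini_hochberg(p)
    return pd.DataFrame(
        {"H": h, "p": p, "q": q, "significant": q < q_threshold},
        index=pd.Index(m.mirna_ids, name="mirna_id"))


def overlap_report(set_a: set[str], set_b: set[str]) -> dict[str, float]:
    """Overlap fractions |A∩B|/|A| and |A∩B|/|B| of two significant sets."""
    inter = len(set_a & set_b)
    return {
        "n_a": len(set_a), "n_b": len(set_b), "n_intersection": inter,
        "frac_of_a": inter / len(set_a) if set_a else 0.0,
        "frac_of_b": inter / len(set_b) if set_b else 0.0,
    }
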