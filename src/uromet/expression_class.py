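"""Transcriptomic classification of urothelial tumors.

Three classifiers operate on FPKM matrices (genes x samples):

* consensus molecular subtype by nearest centroid over six classes
  (LumP, LumNS, LumU, Stroma-rich, Ba/Sq, NE-like) using Pearson
  correlation on log2(FPKM+1), with a minimum-correlation threshold
  below which a sample is "unclassified";
* T-cell inflamed vs depleted immune contexture by k=2 partitioning
  around medoids (PAM) on log-transformed, gene-wise median-centered
  expression of an immune gene signature, labeling the cluster with the
  higher mean signature expression as inflamed;
* single-sample gene set enrichment (ssGSEA) with z-standardized scores
  and a rank-based group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import benjamini_hochberg, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "SubtypeCall",
    "ImmuneCall",
    "log_fpkm",
    "classify_subtype",
    "subtype_concordance",
    "pam_cluster",
    "classify_immune",
    "ssgsea",
    "compare_enrichment",
    "MIN_COR_DEFAULT",
]

MIN_COR_DEFAULT = 0.15


@dataclass(frozen=True)
class SubtypeCall:
    sample: str
    label: str  # subtype name or "unclassified"
    best_correlation: float
    all_correlations: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ImmuneCall:
    sample: str
    label: str  # "T-cell inflamed" or "T-cell depleted"
    cluster_index: int


def log_fpkm(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1), the log transform used throughout."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    return np.log2(expr + 1.0)


def classify_subtype(expr: pd.DataFrame, centroids: pd.DataFrame,
                     min_cor: float = MIN_COR_DEFAULT) -> list:
    """Nearest-centroid molecular subtype calls by Pearson correlation.

    ``expr`` is FPKM genes x samples; ``centroids`` is classifier genes x
    subtype centroids on the log2 scale. Correlation is computed over the
    gene intersection; a sample whose best correlation falls below
    ``min_cor`` is "unclassified".
    """
    genes = centroids.index.intersection(expr.index)
    if len(genes) < 2:
        raise ValueError("fewer than 2 classifier genes overlap the expression matrix")
    x = log_fpkm(expr.loc[genes])
    c = centroids.loc[genes]

    xv = x.to_numpy(dtype=float)
    cv = c.to_numpy(dtype=float)
    xz = xv - xv.mean(axis=0)
    cz = cv - cv.mean(axis=0)
    xn = np.sqrt((xz**2).sum(axis=0))
    cn = np.sqrt((cz**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xz.T @ cz) / np.outer(xn, cn)  # samples x subtypes
    r = np.nan_to_num(r, nan=-np.inf)

    calls = []
    for i, sample in enumerate(x.columns):
        corrs = dict(zip(c.columns, r[i]))
        best_idx = int(np.argmax(r[i]))
        best = float(r[i, best_idx])
        label = c.columns[best_idx] if best >= min_cor else "unclassified"
        calls.append(SubtypeCall(sample, label, best, corrs))
    return calls


def subtype_concordance(calls: list, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-patient subtype concordance across all of the patient's samples.

    ``pairs`` needs patient_id and sample_id columns (one row per sample).
    A patient is concordant when every sample shares one label;
    single-sample patients are concordant by convention and flagged.
    """
    by_sample = {c.sample: c.label for c in calls}
    rows = []
    for patient, grp in pairs.groupby("patient_id", sort=True):
        samples = list(grp["sample_id"])
        missing = [s for s in samples if s not in by_sample]
        if missing:
            raise ValueError(f"unclassified samples in manifest: {missing}")
        labels = [by_sample[s] for s in samples]
        rows.append(dict(patient_id=patient, concordant=len(set(labels)) == 1,
                         labels=tuple(labels), single_sample=len(samples) == 1))
    return pd.DataFrame(rows, columns=["patient_id", "concordant", "labels", "single_sample"])


# ---------------------------------------------------------------------------
# partitioning around medoids


def pam_cluster(X, k: int):
    """k-medoids clustering (PAM): BUILD then SWAP, Euclidean distance.

    Deterministic: ties are broken by the lowest index; SWAP accepts the
    best strictly improving swap until a local optimum. Returns
    (assignments, medoid_indices).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 0 < k <= n:
        raise ValueError(f"k must satisfy 0 < k <= n (k={k}, n={n})")
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    if k == n:  # degenerate: every point is its own medoid, cost 0
        return np.arange(n), np.arange(n)

    # BUILD: greedily add the medoid that most reduces total dissimilarity
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.array([np.minimum(cur, d[:, j]).sum() for j in range(n)])
        gains[medoids] = np.inf
        medoids.append(int(np.argmin(gains)))

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    # SWAP to local optimum
    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (current, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            current = best[0]
            improved = True

    medoids = sorted(medoids)
    assign = np.argmin(d[:, medoids], axis=1)
    return assign, np.array(medoids)


def classify_immune(expr: pd.DataFrame, signature_genes: list,
                    reference_expr: pd.DataFrame | None = None) -> list:
    """T-cell inflamed / depleted calls by PAM(k=2) on a gene signature.

    Expression restricted to signature genes, log2(FPKM+1)-transformed
    and median-centered per gene; an optional reference cohort (e.g. a
    large bladder-cancer cohort) can be appended to stabilize the
    two-cluster structure — calls are returned for the query samples
    only. The cluster with the higher mean transformed signature
    expression is labeled "T-cell inflamed".
    """
    genes = pd.Index(signature_genes).intersection(expr.index)
    if len(genes) < 2:
        raise ValueError("fewer than 2 signature genes overlap the expression matrix")
    query_samples = list(expr.columns)
    mat = expr.loc[genes]
    if reference_expr is not None:
        ref = reference_expr.loc[reference_expr.index.intersection(genes)]
        mat = mat.join(ref, how="inner")
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = log_fpkm(mat)
    x = x.sub(x.median(axis=1), axis=0)  # gene-wise median centering
    if float(x.to_numpy().std()) == 0.0:
        raise ValueError("degenerate input: all samples identical after centering")

    assign, _ = pam_cluster(x.T.to_numpy(), k=2)
    mean_sig = [float(x.loc[:, assign == c].mean().mean()) for c in (0, 1)]
    inflamed_cluster = int(np.argmax(mean_sig))
    calls = []
    for j, sample in enumerate(mat.columns):
        if sample not in query_samples:
            continue
        c = int(assign[j])
        label = "T-cell inflamed" if c == inflamed_cluster else "T-cell depleted"
        calls.append(ImmuneCall(sample, label, c))
    return calls


# ---------------------------------------------------------------------------
# single-sample GSEA


def ssgsea(expr: pd.DataFrame, gene_sets: dict, alpha: float = 0.25,
           standardize: bool = True) -> pd.DataFrame:
    """Single-sample gene set enrichment scores (integrated running sum).

    Per sample, genes are ranked by expression (descending; ties broken
    by gene order for determinism). The running sum gains
    ``rank_weight**alpha`` (normalized) at in-set genes and loses
    ``1/(N-|S|)`` at out-of-set genes; the enrichment score is the sum of
    the running-sum values. Scores are z-standardized per set across
    samples when ``standardize`` (mean 0, sd 1, population sd).
    Sets with no overlapping genes are omitted with a warning.
    """
    import warnings

    n_genes = expr.shape[0]
    gene_index = pd.Index(expr.index)
    scores = {}
    order = np.argsort(-expr.to_numpy(dtype=float), axis=0, kind="stable")
    rank_weight = (n_genes - np.arange(n_genes)).astype(float)  # N..1 down the ranking
    w_alpha = rank_weight**alpha
    for set_name, genes in gene_sets.items():
        members = gene_index.isin(set(genes))
        if not members.any():
            warnings.warn(f"gene set {set_name!r} has no overlap; omitted")
            continue
        n_in = int(members.sum())
        if n_in == n_genes:
            warnings.warn(f"gene set {set_name!r} covers every gene; omitted")
            continue
        es = []
        for j in range(expr.shape[1]):
            in_set = members[order[:, j]]
            inc = np.where(in_set, w_alpha, 0.0)
            denom_in = inc.sum()
            step = inc / denom_in - np.where(in_set, 0.0, 1.0 / (n_genes - n_in))
            es.append(float(np.cumsum(step).sum()))
        scores[set_name] = es
    out = pd.DataFrame(scores, index=expr.columns).T  # sets x samples
    if standardize and out.shape[1] > 0:
        mu = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0).replace(0.0, 1.0)
        out = out.sub(mu, axis=0).div(sd, axis=0)
    return out


def compare_enrichment(scores: pd.DataFrame, groups: dict, paired: bool = False,
                       q_threshold: float = 0.25) -> pd.DataFrame:
    """Per-set group comparison of enrichment scores with BH correction.

    Default is the unpaired two-sided Mann-Whitney test; ``paired=True``
    uses the Wilcoxon signed-rank test on per-pair differences (samples
    matched by position within each group). Significant iff q <= 0.25.
    """
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    ga = [s for s in scores.columns if groups.get(s) == names[0]]
    gb = [s for s in scores.columns if groups.get(s) == names[1]]
    if not ga or not gb:
        raise ValueError("both groups must be nonempty")
    rows = []
    for set_name, row in scores.iterrows():
        a, b = row[ga].to_numpy(), row[gb].to_numpy()
        if paired:
            if len(a) != len(b):
                raise ValueError("paired comparison requires equal group sizes")
            res = wilcoxon_signed_rank(a - b)
        else:
            res = mann_whitney_u(a, b)
        rows.append(dict(gene_set=set_name, statistic=res.statistic,
                         p=res.p_value, method=res.method))
    df = pd.DataFrame(rows, columns=["gene_set", "statistic", "p", "method"])
    if len(df):
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["q"] <= q_threshold
    return df
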