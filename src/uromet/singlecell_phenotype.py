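"""Single-cell imaging-cytometry phenotyping from quantified cell tables.

Input is one row per segmented cell carrying marker intensities and
morphology features (area, perimeter, major-axis length, eccentricity,
solidity). The pipeline excludes perfectly convex cells (solidity 1,
segmentation artifacts), log-transforms and z-scores intensities per
image with a +-3 cap, centers and scales globally, removes batch effects
with a parametric empirical-Bayes adjustment (ComBat), builds a
batch-balanced kNN graph on PCA coordinates, clusters with Leiden, maps
clusters onto named metaclusters with a marker rule table, and computes
the per-cell basal/luminal (KRT5/GATA3) plasticity log-ratio and
immune-infiltration statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import mann_whitney_u

__all__ = [
    "PanelConfig",
    "MetaclusterRule",
    "preprocess_cells",
    "correct_batch",
    "embed_and_cluster",
    "cluster_profiles",
    "assign_metaclusters",
    "default_metacluster_rules",
    "plasticity_ratio",
    "infiltration_stats",
]

MORPHOLOGY_FEATURES = ["area", "perimeter", "major_axis_length", "eccentricity", "solidity"]


@dataclass(frozen=True)
class PanelConfig:
    """Marker panel: which channels drive clustering vs readout only."""

    clustering_markers: list
    functional_markers: list
    krt5_channel: str = "KRT5"
    gata3_channel: str = "GATA3"

    def __post_init__(self):
        overlap = set(self.clustering_markers) & set(self.functional_markers)
        if overlap:
            raise ValueError(f"functional markers cannot drive clustering: {sorted(overlap)}")

    @property
    def all_markers(self):
        return list(self.clustering_markers) + list(self.functional_markers)


@dataclass(frozen=True)
class MetaclusterRule:
    label: str
    markers_high: tuple = ()
    markers_low: tuple = ()
    threshold: float = 0.5  # on mean standardized intensity


def preprocess_cells(cells: pd.DataFrame, panel: PanelConfig):
    """Standardize marker intensities; drop solidity-1 cells.

    Steps: exclude cells with solidity exactly 1; log(1+x) transform;
    z-score each marker within each image, capping at [-3, 3]; center
    and scale each marker globally. Images with a single cell get
    z-scores of 0 (with a warning). Returns ``(features, kept_index)``
    where ``features`` holds every panel marker standardized (clustering
    restriction happens downstream).
    """
    missing = [m for m in panel.all_markers if m not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing panel channels: {missing}")
    kept = cells.index[cells["solidity"] != 1.0]
    df = cells.loc[kept]
    x = np.log1p(df[panel.all_markers].astype(float))

    z = pd.DataFrame(index=x.index, columns=x.columns, dtype=float)
    for _, idx in x.groupby(df["image_id"]).groups.items():
        sub = x.loc[idx]
        if len(sub) == 1:
            warnings.warn("image with a single cell: z-scores set to 0")
            z.loc[idx] = 0.0
            continue
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        zi = (sub - mu) / sd.replace(0.0, np.nan)
        z.loc[idx] = zi.fillna(0.0).to_numpy()
    z = z.clip(-3.0, 3.0)

    mu = z.mean(axis=0)
    sd = z.std(axis=0, ddof=0).replace(0.0, 1.0)
    features = (z - mu) / sd
    return features, kept


def correct_batch(features: pd.DataFrame, batch_ids) -> pd.DataFrame:
    """Parametric empirical-Bayes batch correction (ComBat-style).

    Each feature is standardized, per-batch location/scale effects are
    shrunk toward their across-feature priors by the standard iterative
    EB solution, removed, and the global scale restored. A final
    re-centering step preserves each feature's global mean exactly.
    Single-batch input is returned unchanged.
    """
    batch_ids = pd.Series(np.asarray(batch_ids), index=features.index)
    batches = batch_ids.unique()
    if len(batches) < 2:
        return features.copy()
    counts = batch_ids.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs at least 2 cells")

    x = features.to_numpy(dtype=float)
    grand_mean = x.mean(axis=0)
    grand_var = x.var(axis=0, ddof=0)
    grand_var[grand_var == 0] = 1.0
    z = (x - grand_mean) / np.sqrt(grand_var)

    adj = z.copy()
    for b in batches:
        mask = (batch_ids == b).to_numpy()
        nb = int(mask.sum())
        zb = z[mask]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        delta_hat[delta_hat <= 0] = 1e-8

        # moment-based hyperpriors across features
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if len(gamma_hat) > 1 else 1.0
        v = delta_hat.mean()
        s2 = delta_hat.var(ddof=1) if len(delta_hat) > 1 else 1.0
        lam = (v * v + 2 * s2) / s2 if s2 > 0 else 2.0
        theta = (v**3 + v * s2) / s2 if s2 > 0 else v

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        if tau2 > 0:
            for _ in range(100):
                g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (nb * tau2 + delta_star)
                ss = ((zb - g_new) ** 2).sum(axis=0)
                d_new = (theta + 0.5 * ss) / (nb / 2.0 + lam - 1.0)
                d_new = np.maximum(d_new, 1e-8)
                if np.max(np.abs(g_new - gamma_star)) < 1e-8 and np.max(np.abs(d_new - delta_star)) < 1e-8:
                    gamma_star, delta_star = g_new, d_new
                    break
                gamma_star, delta_star = g_new, d_new
        adj[mask] = (zb - gamma_star) / np.sqrt(delta_star)

    out = adj * np.sqrt(grand_var) + grand_mean
    # location re-centering contract: preserve each feature's global mean
    out = out - out.mean(axis=0) + grand_mean
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def _bbknn_graph(coords: np.ndarray, batch_ids: np.ndarray, neighbors_within_batch: int):
    """Edge list: each cell's k nearest neighbors taken from every batch."""
    from sklearn.neighbors import NearestNeighbors

    edges = set()
    for b in np.unique(batch_ids):
        idx = np.flatnonzero(batch_ids == b)
        k = min(neighbors_within_batch + 1, len(idx))
        nn = NearestNeighbors(n_neighbors=k).fit(coords[idx])
        _, nbrs = nn.kneighbors(coords)
        for i, row in enumerate(nbrs):
            taken = 0
            for j_local in row:
                j = idx[j_local]
                if j == i:
                    continue
                edges.add((min(i, j), max(i, j)))
                taken += 1
                if taken >= neighbors_within_batch:
                    break
    return sorted(edges)


def embed_and_cluster(
    features: pd.DataFrame,
    batch_ids,
    n_pcs: int = 30,
    neighbors_within_batch: int = 3,
    resolution: float = 0.5,
    seed: int = 0,
    return_embedding: bool = False,
):
    """PCA + batch-balanced kNN graph + Leiden community detection.

    Returns cluster labels (pd.Series aligned to ``features``); with
    ``return_embedding`` also a 2-D UMAP of the PCA space (visualization
    only; requires umap-learn).
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA

    x = features.to_numpy(dtype=float)
    batch_ids = np.asarray(batch_ids)
    if len(x) <= n_pcs:
        raise ValueError("need more cells than principal components")
    n_pcs_eff = min(n_pcs, x.shape[1])
    if n_pcs_eff < n_pcs:
        warnings.warn(f"n_pcs truncated to {n_pcs_eff} (only {x.shape[1]} features)")
    coords = PCA(n_components=n_pcs_eff, svd_solver="full").fit_transform(x)

    edges = _bbknn_graph(coords, batch_ids, neighbors_within_batch)
    g = igraph.Graph(n=len(x), edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = pd.Series(part.membership, index=features.index, name="cluster")
    if not return_embedding:
        return labels
    import umap

    emb = umap.UMAP(n_components=2, repulsion_strength=25.0, random_state=seed).fit_transform(coords)
    return labels, emb


def cluster_profiles(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean standardized intensity per cluster (rows) and marker (columns).

    Includes a ``n_cells`` column; counts sum to the number of clustered
    cells.
    """
    prof = features.groupby(labels).mean()
    prof["n_cells"] = labels.value_counts().sort_index()
    return prof


def default_metacluster_rules() -> list:
    """Reconstruction of the marker->lineage rule table (first match wins)."""
    R = MetaclusterRule
    return [
        R("Tumor (basal)", ("panKeratin", "KRT5"), ("CD3",)),
        R("Tumor (luminal)", ("panKeratin", "GATA3"), ("CD3",)),
        R("Tumor (other keratins)", ("panKeratin", "Ecadherin"), ("CD3",)),
        R("Treg", ("CD3", "CD4", "FOXP3"), ()),
        R("CD8 T cell", ("CD3", "CD8a"), ()),
        R("CD4 T cell", ("CD3", "CD4"), ()),
        R("Immunosuppressive myeloid", ("CD11b", "CD68", "GranzymeB", "PDL1"), ()),
        R("Macrophage", ("CD68", "CD11b"), ("CD3",)),
        R("Fibroblast", ("aSMA", "Vimentin"), ("CD31", "panKeratin")),
        R("Endothelial", ("CD31",), ("panKeratin",)),
    ]


def assign_metaclusters(profiles: pd.DataFrame, rules: list, panel: PanelConfig) -> pd.Series:
    """First-match-wins metacluster label per cluster profile row.

    A rule matches when every ``markers_high`` mean standardized
    intensity is >= threshold and every ``markers_low`` one is
    < threshold. Unmatched clusters are labeled "unassigned".
    """
    known = set(panel.all_markers)
    for rule in rules:
        bad = (set(rule.markers_high) | set(rule.markers_low)) - known
        if bad:
            raise ValueError(f"rule {rule.label!r} cites unknown markers {sorted(bad)}")
    labels = {}
    for cluster, row in profiles.iterrows():
        labels[cluster] = "unassigned"
        for rule in rules:
            hi_ok = all(row[m] >= rule.threshold for m in rule.markers_high)
            lo_ok = all(row[m] < rule.threshold for m in rule.markers_low)
            if hi_ok and lo_ok:
                labels[cluster] = rule.label
                break
    return pd.Series(labels, name="metacluster")


def plasticity_ratio(cells: pd.DataFrame, panel: PanelConfig, epsilon: float = 0.01):
    """Per-cell basal/luminal log-ratio and per-sample summaries.

    The ratio is log2((KRT5 + eps) / (GATA3 + eps)) on raw intensities;
    0 means equal basal and luminal marker expression. Returns
    ``(per_cell, per_sample)`` where per_sample holds the five-number
    summary (min, q1, median, q3, max) per sample.
    """
    k = cells[panel.krt5_channel].astype(float)
    g = cells[panel.gata3_channel].astype(float)
    ratio = np.log2((k + epsilon) / (g + epsilon))
    per_cell = pd.DataFrame({"sample_id": cells["sample_id"], "log2_krt5_gata3": ratio})
    per_sample = per_cell.groupby("sample_id")["log2_krt5_gata3"].agg(
        min="min",
        q1=lambda v: float(np.quantile(v, 0.25)),
        median="median",
        q3=lambda v: float(np.quantile(v, 0.75)),
        max="max",
        n_cells="count",
    )
    return per_cell, per_sample


def paired_plasticity_delta(per_sample: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Matched primary-metastasis difference of median plasticity ratios.

    ``pairs`` needs patient_id, primary, metastasis columns (sample ids).
    """
    rows = []
    for _, r in pairs.iterrows():
        mp = float(per_sample.loc[r["primary"], "median"])
        mm = float(per_sample.loc[r["metastasis"], "median"])
        rows.append(dict(patient_id=r["patient_id"], median_primary=mp,
                         median_met=mm, delta_median=mm - mp))
    return pd.DataFrame(rows, columns=["patient_id", "median_primary", "median_met", "delta_median"])


def infiltration_stats(cells: pd.DataFrame, metaclusters: pd.Series, groups: dict):
    """Metacluster abundance per image/sample and inflamed-vs-depleted test.

    ``cells`` must carry sample_id and image_id for every clustered cell;
    ``metaclusters`` is the per-cell metacluster label; ``groups`` maps
    sample -> "inflamed" | "depleted". Returns (per_image counts,
    per_sample means, per-metacluster Mann-Whitney comparison).
    """
    df = cells.assign(metacluster=metaclusters.to_numpy())
    per_image = (df.groupby(["sample_id", "image_id", "metacluster"], observed=True)
                 .size().rename("n_cells").reset_index())
    wide = per_image.pivot_table(index=["sample_id", "image_id"], columns="metacluster",
                                 values="n_cells", fill_value=0)
    per_sample = wide.groupby(level="sample_id").mean()

    rows = []
    inflamed = [s for s in per_sample.index if groups.get(s) == "inflamed"]
    depleted = [s for s in per_sample.index if groups.get(s) == "depleted"]
    for mc in per_sample.columns:
        if not inflamed or not depleted:
            raise ValueError("both immune groups must be nonempty")
        res = mann_whitney_u(per_sample.loc[inflamed, mc], per_sample.loc[depleted, mc])
        rows.append(dict(metacluster=mc,
                         mean_inflamed=float(per_sample.loc[inflamed, mc].mean()),
                         mean_depleted=float(per_sample.loc[depleted, mc].mean()),
                         p=res.p_value))
    comparison = pd.DataFrame(rows, columns=["metacluster", "mean_inflamed", "mean_depleted", "p"])
    return per_image, per_sample, comparison
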