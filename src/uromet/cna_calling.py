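"""Capture-region copy-number pipeline: filter, normalize, segment, call.

Read counts per capture region are normalized to fractions of each
sample's total aligned reads; the log2 tumor/normal ratio track is
segmented per chromosome with circular binary segmentation (recursive
circular change-point search with a within-segment permutation test),
segments are called amplified (log2 > 1) or deleted (log2 < -0.5), and
calls are projected onto gene intervals by coordinate overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats_core import fisher_exact_2x2

__all__ = [
    "karyotypic_sort",
    "filter_regions",
    "compute_ratios",
    "segment_cbs",
    "call_segments",
    "annotate_genes",
    "compare_gene_frequency",
    "AMP_THRESHOLD",
    "DEL_THRESHOLD",
]

AMP_THRESHOLD = 1.0  # seg_log2 strictly above -> amplified
DEL_THRESHOLD = -0.5  # seg_log2 strictly below -> deleted


def _chrom_rank(chrom: str):
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    if c.isdigit():
        return (0, int(c), "")
    if c in ("X", "Y"):
        return (1, 23 + ("XY".index(c)), "")
    return (2, 0, c)


def karyotypic_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Order 1..22, X, Y (others appended lexically), then by coordinate."""
    key = df["chrom"].map(_chrom_rank)
    return df.assign(_k=key).sort_values(["_k", "start"], kind="stable").drop(columns="_k")


def _check_sorted(df: pd.DataFrame):
    for chrom, grp in df.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        if np.any(e <= s):
            raise ValueError(f"region with end <= start on chromosome {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"regions unsorted or overlapping on chromosome {chrom}")


def filter_regions(regions: pd.DataFrame, min_reads: int = 100) -> pd.DataFrame:
    """Drop regions with fewer than ``min_reads`` in BOTH tumor and normal."""
    _check_sorted(regions)
    keep = ~((regions["tumor_reads"] < min_reads) & (regions["normal_reads"] < min_reads))
    return regions.loc[keep].reset_index(drop=True)


def compute_ratios(
    retained: pd.DataFrame,
    tumor_total: float | None = None,
    normal_total: float | None = None,
) -> pd.DataFrame:
    """Normalized tumor/normal ratios per region, karyotypically ordered.

    Totals default to the column sums but may be given explicitly as the
    per-sample total aligned reads (the normalization the pipeline uses
    when genome-wide alignment totals are known).
    """
    df = retained.copy()
    zero = df["normal_reads"] == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} region(s) with zero normal reads")
        df = df.loc[~zero]
    t_total = float(tumor_total) if tumor_total is not None else float(df["tumor_reads"].sum())
    n_total = float(normal_total) if normal_total is not None else float(df["normal_reads"].sum())
    if t_total <= 0 or n_total <= 0:
        raise ValueError("per-sample totals must be positive")
    df["norm_tumor"] = df["tumor_reads"] / t_total
    df["norm_normal"] = df["normal_reads"] / n_total
    df["log2_ratio"] = np.log2(df["norm_tumor"] / df["norm_normal"])
    return karyotypic_sort(df).reset_index(drop=True)


# ---------------------------------------------------------------------------
# circular binary segmentation

def _max_between_ss(x: np.ndarray, min_width: int):
    """Best circular split of one segment by between-group sum of squares.

    For fixed data, the two-sample |t| over a split is monotone in the
    between-group sum of squares B, so maximizing B finds the same split.
    Returns (i, j, B) where the arc is x[i:j] in the doubled-index sense
    (cut points i mod n and j mod n), or None if no admissible arc exists.
    """
    n = len(x)
    if n < 2 * min_width:
        return None
    total = x.sum()
    c = np.concatenate([[0.0], np.cumsum(np.concatenate([x, x]))])
    best = (-1.0, 0, 0)
    starts = np.arange(n)
    for L in range(min_width, n - min_width + 1):
        arc = c[starts + L] - c[starts]
        b = (arc * n - L * total) ** 2 / (n * L * (n - L))
        s = int(np.argmax(b))
        if b[s] > best[0]:
            best = (float(b[s]), s, s + L)
    b, i, j = best
    return i, j, b


def _perm_max_between_ss(x: np.ndarray, min_width: int, n_perm: int, rng) -> np.ndarray:
    """Max between-SS over all circular splits, for n_perm permutations."""
    n = len(x)
    total = x.sum()
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    doubled = np.concatenate([perms, perms], axis=1)
    c = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(doubled, axis=1)], axis=1)
    best = np.zeros(n_perm)
    starts = np.arange(n)
    for L in range(min_width, n - min_width + 1):
        arc = c[:, starts + L] - c[:, starts]
        b = (arc * n - L * total) ** 2 / (n * L * (n - L))
        np.maximum(best, b.max(axis=1), out=best)
    return best


def _cbs_chrom(x: np.ndarray, alpha: float, n_perm: int, min_width: int, rng) -> list:
    """Recursive CBS on one chromosome; returns sorted cut points (0 < c < n)."""
    cuts: list = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        found = _max_between_ss(seg, min_width)
        if found is None:
            return
        i, j, b = found
        if b <= 1e-24:  # flat segment: nothing to split
            return
        perm_best = _perm_max_between_ss(seg, min_width, n_perm, rng)
        p = (1 + int((perm_best >= b - 1e-12).sum())) / (1 + n_perm)
        if p >= alpha:
            return
        n = len(seg)
        pts = sorted({i % n, j % n} - {0})  # a cut at 0 is no cut
        if not pts:
            return
        cuts.extend(lo + c for c in pts)
        bounds = [0, *pts, n]
        for a, b_ in zip(bounds[:-1], bounds[1:]):
            recurse(lo + a, lo + b_)

    recurse(0, len(x))
    return sorted(set(cuts))


def segment_cbs(
    ratios: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Circular binary segmentation of per-region log2 ratios.

    ``ratios`` must carry chrom/start/end/log2_ratio in karyotypic order
    (as produced by :func:`compute_ratios`). A candidate split is accepted
    when its within-segment permutation p-value is below ``alpha``; the
    search recurses on accepted sub-segments. Returns one row per segment
    with the member count and the mean member log2 ratio.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values")
    rows = []
    ss = np.random.SeedSequence(seed)
    chrom_order = list(dict.fromkeys(ratios["chrom"]))
    child_seeds = ss.spawn(len(chrom_order))
    for chrom, child in zip(chrom_order, child_seeds):
        grp = ratios.loc[ratios["chrom"] == chrom]
        x = grp["log2_ratio"].to_numpy(dtype=float)
        rng = np.random.default_rng(child)
        cuts = _cbs_chrom(x, alpha, n_perm, min_width, rng)
        bounds = [0, *cuts, len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            sub = grp.iloc[a:b]
            rows.append(dict(
                chrom=chrom,
                start=int(sub["start"].iloc[0]),
                end=int(sub["end"].iloc[-1]),
                first_region=a,
                last_region=b - 1,
                n_regions=b - a,
                seg_log2=float(x[a:b].mean()),
            ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "first_region",
                                       "last_region", "n_regions", "seg_log2"])


def call_segments(segments: pd.DataFrame,
                  amp_threshold: float = AMP_THRESHOLD,
                  del_threshold: float = DEL_THRESHOLD) -> pd.DataFrame:
    """Label each segment amplified / deleted / neutral (strict thresholds)."""
    df = segments.copy()
    log2 = df["seg_log2"].to_numpy()
    call = np.where(log2 > amp_threshold, "amplified",
                    np.where(log2 < del_threshold, "deleted", "neutral"))
    df["call"] = call
    return df


def annotate_genes(segments: pd.DataFrame, gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Gene-level calls from non-neutral segments overlapping each gene.

    ``gene_intervals`` needs chrom/start/end/gene (0-based half-open,
    transcription start/end). A gene spanning segments with conflicting
    non-neutral calls yields one row per call, flagged ``conflict=True``.
    Genes overlapping only neutral segments (or nothing) are omitted.
    """
    known = set(segments["chrom"])
    rows = []
    for _, g in gene_intervals.iterrows():
        if g["chrom"] not in known:
            warnings.warn(f"gene {g['gene']} on unknown chromosome {g['chrom']}; skipped")
            continue
        seg = segments[(segments["chrom"] == g["chrom"])
                       & (segments["start"] < g["end"])
                       & (segments["end"] > g["start"])
                       & (segments["call"] != "neutral")]
        calls = sorted(set(seg["call"]))
        for _, s in seg.iterrows():
            rows.append(dict(gene=g["gene"], call=s["call"], chrom=s["chrom"],
                             seg_start=s["start"], seg_end=s["end"],
                             seg_log2=s["seg_log2"], conflict=len(calls) > 1))
    return pd.DataFrame(rows, columns=["gene", "call", "chrom", "seg_start",
                                       "seg_end", "seg_log2", "conflict"]).drop_duplicates(
        subset=["gene", "call", "chrom", "seg_start"]).reset_index(drop=True)


def compare_gene_frequency(groupA_calls: dict, groupB_calls: dict,
                           gene: str, call_type: str) -> dict:
    """Fisher comparison of one gene's alteration frequency between groups.

    ``group*_calls`` map sample -> set of (gene, call) pairs.
    """
    if not groupA_calls or not groupB_calls:
        raise ValueError("both groups must be nonempty")
    hitA = sum((gene, call_type) in alts for alts in groupA_calls.values())
    hitB = sum((gene, call_type) in alts for alts in groupB_calls.values())
    nA, nB = len(groupA_calls), len(groupB_calls)
    res = fisher_exact_2x2(hitA, nA - hitA, hitB, nB - hitB)
    return dict(countA=hitA, nA=nA, countB=hitB, nB=nB, fisher_p=res.p_value)
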