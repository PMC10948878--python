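"""Multi-caller somatic variant consensus, retention filters, TMB and MSI.

Somatic SNVs are retained when called by at least two of four callers
(MuTect2, Strelka, VarScan, SomaticSniper); indels when called by both
Strelka and VarScan. Retained candidates then pass read-depth, tumor-VAF
and normal-contamination rules, a dbSNP-unless-COSMIC database filter,
and a platform artifact blocklist. Tumor mutational burden is mutations
per megabase of covered sequence; microsatellite instability is the
percentage of unstable microsatellite sites (MSI-high when > 3.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FilterConfig",
    "TmbResult",
    "MsiResult",
    "normalize_allele",
    "merge_callers",
    "apply_quality_filters",
    "apply_database_filter",
    "run_consensus",
    "compute_tmb",
    "compute_msi",
    "MSI_CUTOFF",
]

SNV_CALLERS = ("mutect2", "strelka", "varscan", "somaticsniper")
INDEL_CALLERS = frozenset({"strelka", "varscan"})
# deterministic tie-break when callers report equal tumor depth
_CALLER_ORDER = {"mutect2": 0, "somaticsniper": 1, "strelka": 2, "varscan": 3}

MSI_CUTOFF = 3.5


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic retention rules."""

    min_depth: int = 30  # both tumor and normal
    min_tumor_vaf: float = 0.10
    min_tumor_alt_exclusive: int = 5  # require alt reads strictly greater
    max_normal_vaf: float = 0.01
    max_normal_alt: int = 1  # "just one read" clause, read as <=1
    min_snv_callers: int = 2


@dataclass(frozen=True)
class TmbResult:
    mutation_count: int
    coverage_bases: int
    tmb: float  # mutations per megabase
    tmb_high: bool
    threshold: float


@dataclass(frozen=True)
class MsiResult:
    n_unstable: int
    n_total_sites: int
    score: float  # percentage of unstable sites
    status: str  # "MSI-H" or "MSS"


def normalize_allele(chrom: str, pos: int, ref: str, alt: str):
    """Canonical variant key: trim shared suffix then prefix bases.

    Callers report the same indel with different amounts of redundant
    context; trimming makes keys comparable across callers. The shared
    suffix is removed first, then the shared prefix (advancing ``pos``),
    always leaving at least one base in each allele.
    """
    ref, alt = str(ref), str(alt)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return str(chrom), int(pos), ref, alt


def merge_callers(calls: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Merge per-caller rows into one consensus candidate per variant key.

    Depth/VAF fields come from the supporting caller with the highest
    tumor depth (ties broken by fixed caller order). Candidates without
    sufficient support get ``filter_status="fail_support"``; all others
    start as ``"PASS"`` for the downstream filters to refine.
    """
    config = config or FilterConfig()
    cols = ["chrom", "pos", "ref", "alt", "variant_class", "supporting_callers",
            "tumor_depth", "tumor_alt_reads", "normal_depth", "normal_alt_reads",
            "tumor_vaf", "normal_vaf", "in_dbsnp", "in_cosmic", "gene",
            "consequence", "filter_status"]
    if len(calls) == 0:
        return pd.DataFrame(columns=cols)
    df = calls.copy()
    keys = [normalize_allele(c, p, r, a)
            for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])]
    df["chrom"] = [k[0] for k in keys]
    df["pos"] = [k[1] for k in keys]
    df["ref"] = [k[2] for k in keys]
    df["alt"] = [k[3] for k in keys]

    out = []
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        classes = set(grp["variant_class"])
        if len(classes) > 1:
            raise ValueError(f"inconsistent variant_class for key {key}: {sorted(classes)}")
        vclass = classes.pop()
        callers = sorted(set(grp["caller"]), key=lambda c: _CALLER_ORDER.get(c, 99))
        # representative depths: highest tumor depth, deterministic tie-break
        grp = grp.assign(_ord=[_CALLER_ORDER.get(c, 99) for c in grp["caller"]])
        grp = grp.sort_values(["tumor_depth", "_ord"], ascending=[False, True], kind="stable")
        rep = grp.iloc[0]
        if vclass == "indel":
            supported = INDEL_CALLERS <= set(callers)
        else:
            supported = len(callers) >= config.min_snv_callers
        t_depth, n_depth = int(rep["tumor_depth"]), int(rep["normal_depth"])
        out.append(dict(
            chrom=key[0], pos=key[1], ref=key[2], alt=key[3], variant_class=vclass,
            supporting_callers=tuple(callers),
            tumor_depth=t_depth, tumor_alt_reads=int(rep["tumor_alt_reads"]),
            normal_depth=n_depth, normal_alt_reads=int(rep["normal_alt_reads"]),
            tumor_vaf=rep["tumor_alt_reads"] / t_depth if t_depth else 0.0,
            normal_vaf=rep["normal_alt_reads"] / n_depth if n_depth else 0.0,
            in_dbsnp=bool(rep["in_dbsnp"]), in_cosmic=bool(rep["in_cosmic"]),
            gene=rep["gene"], consequence=rep["consequence"],
            filter_status="PASS" if supported else "fail_support",
        ))
    return pd.DataFrame(out, columns=cols)


def apply_quality_filters(candidates: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Depth, tumor-VAF and normal-contamination rules, in that order.

    Only candidates currently marked PASS are re-evaluated; the first
    failing rule determines the status.
    """
    config = config or FilterConfig()
    df = candidates.copy()
    for i in df.index[df["filter_status"] == "PASS"]:
        row = df.loc[i]
        if row["tumor_depth"] < config.min_depth or row["normal_depth"] < config.min_depth:
            df.at[i, "filter_status"] = "fail_depth"
        elif row["tumor_vaf"] < config.min_tumor_vaf or row["tumor_alt_reads"] <= config.min_tumor_alt_exclusive:
            df.at[i, "filter_status"] = "fail_tumor_vaf"
        elif row["normal_vaf"] > config.max_normal_vaf and row["normal_alt_reads"] > config.max_normal_alt:
            df.at[i, "filter_status"] = "fail_normal_vaf"
    return df


def apply_database_filter(candidates: pd.DataFrame, blocklist: set | None = None) -> pd.DataFrame:
    """dbSNP-unless-COSMIC filter, then the platform artifact blocklist."""
    blocklist = blocklist or set()
    df = candidates.copy()
    for i in df.index[df["filter_status"] == "PASS"]:
        row = df.loc[i]
        if row["in_dbsnp"] and not row["in_cosmic"]:
            df.at[i, "filter_status"] = "fail_dbsnp"
        elif (row["chrom"], row["pos"], row["ref"], row["alt"]) in blocklist:
            df.at[i, "filter_status"] = "fail_blocklist"
    return df


def run_consensus(calls: pd.DataFrame, blocklist: set | None = None,
                  config: FilterConfig | None = None) -> pd.DataFrame:
    """Merge, quality-filter and database-filter one tumor/normal pair."""
    merged = merge_callers(calls, config)
    merged = apply_quality_filters(merged, config)
    return apply_database_filter(merged, blocklist)


def compute_tmb(pass_variants, coverage_bases: int, threshold: float) -> TmbResult:
    """Tumor mutational burden: mutations per megabase of covered bases."""
    if coverage_bases <= 0:
        raise ValueError("coverage_bases must be positive")
    if isinstance(pass_variants, pd.DataFrame):
        n = int((pass_variants["filter_status"] == "PASS").sum()
                if "filter_status" in pass_variants.columns else len(pass_variants))
    else:
        n = int(pass_variants)
    tmb = n / coverage_bases * 1e6
    return TmbResult(n, int(coverage_bases), tmb, tmb > threshold, float(threshold))


def compute_msi(site_calls: pd.DataFrame, cutoff: float = MSI_CUTOFF) -> MsiResult:
    """Microsatellite instability score: % unstable sites; MSI-H iff > cutoff.

    ``site_calls`` needs a ``status`` column with values "stable"/"unstable"
    (or a boolean ``unstable`` column).
    """
    if len(site_calls) == 0:
        raise ValueError("empty microsatellite site table")
    if "unstable" in site_calls.columns:
        unstable = site_calls["unstable"].astype(bool)
    else:
        bad = set(site_calls["status"]) - {"stable", "unstable"}
        if bad:
            raise ValueError(f"unknown site status values {sorted(bad)}")
        unstable = site_calls["status"] == "unstable"
    n_unstable, n_total = int(unstable.sum()), len(site_calls)
    score = 100.0 * n_unstable / n_total
    return MsiResult(n_unstable, n_total, score, "MSI-H" if score > cutoff else "MSS")
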