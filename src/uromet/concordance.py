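"""Shared/private mutation statistics between matched primary and metastatic
tumors, pathogenic-alteration overlap, and cohort alteration frequencies.

Sharing is computed over the union of the two PASS nonsynonymous variant
sets of a matched pair; a patient with several metastases contributes the
mean over its primary-metastasis pairs to cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats_core import fisher_exact_2x2

__all__ = [
    "PatientPair",
    "ConcordanceResult",
    "variant_key_set",
    "shared_private_mutations",
    "cohort_sharing_summary",
    "pathogenic_overlap",
    "gene_alteration_frequencies",
]

PATHOGENIC_LABELS = frozenset({"oncogenic", "likely oncogenic", "likely-oncogenic", "likely_oncogenic"})


@dataclass(frozen=True)
class PatientPair:
    patient_id: str
    primary_sample_id: str
    metastatic_sample_ids: tuple
    chemo_before_sampling: bool = False

    def __post_init__(self):
        if len(self.metastatic_sample_ids) < 1:
            raise ValueError("a pair needs at least one metastatic sample")


@dataclass(frozen=True)
class ConcordanceResult:
    shared_n: int
    primary_private_n: int
    met_private_n: int
    shared_pct: float
    primary_private_pct: float
    met_private_pct: float


def variant_key_set(variants: pd.DataFrame, nonsynonymous_only: bool = True) -> set:
    """PASS variant keys from a consensus table, default nonsynonymous only."""
    df = variants
    if "filter_status" in df.columns:
        df = df[df["filter_status"] == "PASS"]
    if nonsynonymous_only and "consequence" in df.columns:
        df = df[df["consequence"] == "nonsynonymous"]
    return set(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))


def shared_private_mutations(primary_pass: set, met_pass: set) -> ConcordanceResult:
    """Shared and private mutation counts/percentages over the union."""
    union = primary_pass | met_pass
    if not union:
        raise ValueError("empty union of mutation sets")
    shared = len(primary_pass & met_pass)
    p_priv = len(primary_pass - met_pass)
    m_priv = len(met_pass - primary_pass)
    n = len(union)
    return ConcordanceResult(
        shared, p_priv, m_priv,
        100.0 * shared / n, 100.0 * p_priv / n, 100.0 * m_priv / n,
    )


@dataclass(frozen=True)
class SharingSummary:
    mean_shared_pct: float
    min_shared_pct: float
    max_shared_pct: float
    per_patient: dict = field(default_factory=dict)
    mean_by_chemo_status: dict = field(default_factory=dict)


def cohort_sharing_summary(pairs: list) -> SharingSummary:
    """Cohort summary of shared-mutation percentages.

    ``pairs`` is a list of ``(PatientPair, results)`` where ``results`` is a
    ConcordanceResult or list thereof (one per metastasis); each patient
    contributes the unweighted mean over its pairs.
    """
    if not pairs:
        raise ValueError("at least one patient pair is required")
    per_patient, chemo = {}, {}
    for pp, results in pairs:
        if isinstance(results, ConcordanceResult):
            results = [results]
        val = sum(r.shared_pct for r in results) / len(results)
        per_patient[pp.patient_id] = val
        chemo.setdefault(pp.chemo_before_sampling, []).append(val)
    vals = list(per_patient.values())
    by_chemo = {("chemo" if k else "naive"): sum(v) / len(v) for k, v in chemo.items()}
    return SharingSummary(sum(vals) / len(vals), min(vals), max(vals), per_patient, by_chemo)


def pathogenic_overlap(primary_alterations: set, met_alterations: set, oncogenicity: dict) -> dict:
    """Overlap of oncogenic / likely-oncogenic alterations in a matched pair.

    Alterations are (gene, alteration-class) pairs; ``oncogenicity`` maps
    them to labels in the OncoKB style.
    """
    def pathogenic(alts):
        return {a for a in alts
                if str(oncogenicity.get(a, "")).lower() in PATHOGENIC_LABELS}

    p_path = pathogenic(primary_alterations)
    m_path = pathogenic(met_alterations)
    shared = p_path & m_path
    return dict(
        shared_pathogenic=shared,
        primary_private_pathogenic=p_path - m_path,
        met_private_pathogenic=m_path - p_path,
        any_shared=bool(shared),
    )


def gene_alteration_frequencies(per_sample_alterations: dict, groups: dict) -> pd.DataFrame:
    """Per-gene alteration frequency in primary vs metastatic samples.

    ``per_sample_alterations`` maps sample -> set of altered genes;
    ``groups`` maps sample -> "primary" | "metastatic". Returns one row
    per gene with frequencies (%) and the two-sided Fisher p-value.
    """
    missing = set(per_sample_alterations) - set(groups)
    if missing:
        raise ValueError(f"samples without a group: {sorted(missing)}")
    prim = [s for s in per_sample_alterations if groups[s] == "primary"]
    met = [s for s in per_sample_alterations if groups[s] == "metastatic"]
    genes = sorted(set().union(*per_sample_alterations.values())) if per_sample_alterations else []
    rows = []
    for gene in genes:
        a = sum(gene in per_sample_alterations[s] for s in prim)
        c = sum(gene in per_sample_alterations[s] for s in met)
        res = fisher_exact_2x2(a, len(prim) - a, c, len(met) - c)
        rows.append(dict(
            gene=gene,
            count_primary=a, n_primary=len(prim),
            count_met=c, n_met=len(met),
            freq_primary=100.0 * a / len(prim) if prim else 0.0,
            freq_met=100.0 * c / len(met) if met else 0.0,
            fisher_p=res.p_value,
        ))
    return pd.DataFrame(rows, columns=["gene", "count_primary", "n_primary", "count_met",
                                       "n_met", "freq_primary", "freq_met", "fisher_p"])
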