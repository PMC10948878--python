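"""Ground-truth-bearing generators for every input layer of the pipeline.

Each generator emulates one data layer the analysis consumes: multi-caller
somatic variant call sets for a matched primary/metastatic tumor pair,
capture-region read-count tracks with planted copy-number segments, FPKM
expression cohorts with planted subtype and immune-contexture structure,
and single-cell imaging-cytometry marker/morphology tables with planted
cell-population mixtures and batch effects. Every record is covered by
exactly one truth class, and identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimTruth",
    "VariantSimResult",
    "CaptureCountResult",
    "ExpressionSimResult",
    "SingleCellSimResult",
    "gen_matched_variant_calls",
    "gen_capture_counts",
    "gen_expression_cohort",
    "gen_singlecell_cohort",
    "make_centroids",
    "default_panel",
    "default_population_profiles",
]

CHROMS = [str(c) for c in range(1, 23)]
SNV_CALLERS = ("mutect2", "strelka", "varscan", "somaticsniper")
INDEL_CALLERS = ("strelka", "varscan")
_BASES = np.array(list("ACGT"))

ARTIFACT_CLASSES = ("low_depth", "low_vaf", "germline", "dbsnp_only", "blocklist", "single_caller")


@dataclass
class SimTruth:
    """Ground truth for one simulated layer."""

    planted_shared_fraction: float | None = None
    planted_segments: list = field(default_factory=list)
    sample_subtype_labels: dict = field(default_factory=dict)
    sample_immune_labels: dict = field(default_factory=dict)
    cell_population_labels: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class VariantSimResult:
    """Per-caller tables for one primary/metastatic pair, plus truth."""

    calls: dict  # sample_id -> caller -> DataFrame of caller rows
    truth: pd.DataFrame  # one row per variant key: class, membership
    blocklist: set
    sim_truth: SimTruth


@dataclass
class CaptureCountResult:
    regions: pd.DataFrame  # chrom, start, end, tumor_reads, normal_reads
    tumor_total: float  # total aligned reads (genome-wide), tumor
    normal_total: float
    sim_truth: SimTruth


@dataclass
class ExpressionSimResult:
    fpkm: pd.DataFrame  # genes x samples
    centroids: pd.DataFrame  # classifier genes x subtypes (log2 scale)
    signature_genes: list
    sim_truth: SimTruth


@dataclass
class SingleCellSimResult:
    cells: pd.DataFrame
    panel: "object"  # PanelConfig (singlecell_phenotype)
    sim_truth: SimTruth


# ---------------------------------------------------------------------------
# matched variant call sets


def _draw_positions(rng, n, exome_sites):
    """Unique (chrom, pos) pairs from a toy exome grid over 22 chromosomes."""
    if n > exome_sites:
        raise ValueError(f"cannot draw {n} unique sites from a {exome_sites}-site exome")
    idx = rng.choice(exome_sites, size=n, replace=False)
    per_chrom = exome_sites // len(CHROMS) + 1
    chroms = [CHROMS[i // per_chrom] for i in idx]
    pos = [1000 + (i % per_chrom) * 150 + 1 for i in idx]
    return list(zip(chroms, pos))


def _clean_record(rng, mean_depth):
    """Depth/VAF draws that pass every retention rule with margin."""
    t_depth = max(33, int(rng.poisson(mean_depth)))
    vaf = rng.uniform(0.15, 0.6)
    t_alt = min(t_depth, max(6, int(round(vaf * t_depth))))
    n_depth = max(33, int(rng.poisson(mean_depth)))
    n_alt = int(rng.random() < 0.15)  # occasionally exercise the one-read clause
    return t_depth, t_alt, n_depth, n_alt


def gen_matched_variant_calls(
    n_shared: int,
    n_primary_private: int,
    n_met_private: int,
    artifact_config: dict | None = None,
    seed: int = 0,
    indel_fraction: float = 0.15,
    exome_sites: int = 10_000,
    mean_depth: float = 100.0,
) -> VariantSimResult:
    """Simulate per-caller somatic call tables for a matched tumor pair.

    True (clean) variants are planted as shared, primary-private or
    metastasis-private; each appears in >=2 SNV callers (indels in both
    indel callers) with depths and VAFs that pass every retention rule.
    ``artifact_config`` maps decoy class -> rate, where the rate is the
    number of decoys of that class per true variant. Every decoy violates
    exactly one named retention rule. Classes: ``low_depth``, ``low_vaf``,
    ``germline``, ``dbsnp_only``, ``blocklist``, ``single_caller``.
    """
    counts = dict(shared=n_shared, primary_private=n_primary_private, met_private=n_met_private)
    if any(v < 0 for v in counts.values()):
        raise ValueError("variant counts must be nonnegative")
    artifact_config = dict(artifact_config or {})
    rates = {}
    for key, rate in artifact_config.items():
        cls = key[:-5] if key.endswith("_rate") else key
        if cls not in ARTIFACT_CLASSES:
            raise ValueError(f"unknown artifact class {key!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"artifact rate for {key!r} outside [0, 1]")
        rates[cls] = rate

    rng = np.random.default_rng(seed)
    n_true = sum(counts.values())
    n_decoys = {cls: int(round(r * n_true)) for cls, r in rates.items()}
    n_total = n_true + sum(n_decoys.values())

    sites = _draw_positions(rng, n_total, exome_sites)
    records = []  # variant-level records
    i = 0
    for membership, n in counts.items():
        for _ in range(n):
            records.append((sites[i], membership, "clean"))
            i += 1
    for cls, n in n_decoys.items():
        for _ in range(n):
            membership = ["shared", "primary_private", "met_private"][rng.integers(3)]
            records.append((sites[i], membership, cls))
            i += 1

    blocklist: set = set()
    truth_rows = []
    calls: dict = {
        "primary": {c: [] for c in SNV_CALLERS},
        "metastasis": {c: [] for c in SNV_CALLERS},
    }

    for (chrom, pos), membership, cls in records:
        is_indel = rng.random() < indel_fraction
        ref = str(rng.choice(_BASES))
        if is_indel:
            alt = ref + "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
        else:
            alt = str(rng.choice(_BASES[_BASES != ref]))
        vclass = "indel" if is_indel else "SNV"
        gene = f"GENE{rng.integers(1, 400):03d}"

        t_depth, t_alt, n_depth, n_alt = _clean_record(rng, mean_depth)
        in_dbsnp, in_cosmic = False, bool(rng.random() < 0.2)
        if rng.random() < 0.1:  # known hotspot also in dbSNP: survives the db filter
            in_dbsnp, in_cosmic = True, True

        if is_indel:
            callers = list(INDEL_CALLERS)
        else:
            n_support = int(rng.integers(2, 5))
            callers = sorted(rng.choice(SNV_CALLERS, size=n_support, replace=False))

        if cls == "low_depth":
            if rng.random() < 0.5:
                t_depth = int(rng.integers(10, 30))
                t_alt = min(t_alt, t_depth)
            else:
                n_depth = int(rng.integers(10, 30))
                n_alt = min(n_alt, n_depth)
        elif cls == "low_vaf":
            t_alt = max(1, int(0.05 * t_depth))  # VAF ~5% < 10%
        elif cls == "germline":
            n_alt = max(2, int(round(0.05 * n_depth)))  # normal VAF ~5%, >1 read
        elif cls == "dbsnp_only":
            in_dbsnp, in_cosmic = True, False
        elif cls == "blocklist":
            blocklist.add((chrom, pos, ref, alt))
        elif cls == "single_caller":
            if is_indel:
                callers = [str(rng.choice(INDEL_CALLERS))]
            else:
                callers = [str(rng.choice(SNV_CALLERS))]

        samples = {
            "shared": ("primary", "metastasis"),
            "primary_private": ("primary",),
            "met_private": ("metastasis",),
        }[membership]
        for sample in samples:
            for caller in callers:
                calls[sample][caller].append(
                    dict(
                        sample_id=sample,
                        caller=caller,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        variant_class=vclass,
                        tumor_depth=t_depth,
                        tumor_alt_reads=t_alt,
                        normal_depth=n_depth,
                        normal_alt_reads=n_alt,
                        in_dbsnp=in_dbsnp,
                        in_cosmic=in_cosmic,
                        gene=gene,
                        consequence="nonsynonymous",
                    )
                )
        truth_rows.append(
            dict(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                variant_class=vclass,
                membership=membership,
                truth_class=cls,
            )
        )

    columns = [
        "sample_id", "caller", "chrom", "pos", "ref", "alt", "variant_class",
        "tumor_depth", "tumor_alt_reads", "normal_depth", "normal_alt_reads",
        "in_dbsnp", "in_cosmic", "gene", "consequence",
    ]
    for sample in calls:
        for caller in SNV_CALLERS:
            calls[sample][caller] = pd.DataFrame(calls[sample][caller], columns=columns)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "variant_class", "membership", "truth_class"],
    )
    shared_frac = counts["shared"] / n_true if n_true else float("nan")
    sim_truth = SimTruth(planted_shared_fraction=shared_frac, seeds={"variants": seed})
    return VariantSimResult(calls=calls, truth=truth, blocklist=blocklist, sim_truth=sim_truth)


# ---------------------------------------------------------------------------
# capture-region read counts


def gen_capture_counts(
    n_regions_per_chrom: int = 100,
    planted_segments: list | None = None,
    depth_model: dict | None = None,
    seed: int = 0,
    chroms: list | None = None,
    region_width: int = 1_000,
    region_gap: int = 1_000,
) -> CaptureCountResult:
    """Simulate tumor/normal capture-region read counts with planted segments.

    ``planted_segments`` is a list of ``(chrom, start, end, true_log2)`` in
    genomic coordinates (0-based half-open); regions fully inside a planted
    segment take tumor expectation ``mean * 2**true_log2``. The per-sample
    total aligned reads are emitted explicitly and set equal for tumor and
    normal, so the expected normalized ratio inside a segment is exactly
    ``2**true_log2``. ``depth_model`` keys: ``mean`` (default 100) and
    ``noise`` ("poisson", default, or "none" to return expectations).
    """
    chroms = list(chroms) if chroms is not None else CHROMS
    depth_model = dict(depth_model or {})
    mean = float(depth_model.get("mean", 100.0))
    noise = depth_model.get("noise", "poisson")
    planted = sorted(planted_segments or [], key=lambda s: (s[0], s[1]))
    by_chrom: dict = {}
    for chrom, start, end, log2 in planted:
        segs = by_chrom.setdefault(chrom, [])
        if segs and start < segs[-1][1]:
            raise ValueError("planted segments overlap")
        if end <= start:
            raise ValueError("planted segment end must exceed start")
        segs.append((start, end, log2))

    rng = np.random.default_rng(seed)
    rows = []
    for chrom in chroms:
        for i in range(n_regions_per_chrom):
            start = i * (region_width + region_gap)
            end = start + region_width
            log2 = 0.0
            for s, e, l in by_chrom.get(chrom, []):
                if start >= s and end <= e:
                    log2 = l
                    break
            rows.append((chrom, start, end, log2))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "true_log2"])
    normal_exp = np.full(len(df), mean)
    tumor_exp = mean * np.power(2.0, df["true_log2"].to_numpy())
    if noise == "poisson":
        tumor = rng.poisson(tumor_exp).astype(float)
        normal = rng.poisson(normal_exp).astype(float)
    elif noise == "none":
        tumor, normal = tumor_exp, normal_exp
    else:
        raise ValueError(f"unknown depth noise model {noise!r}")

    regions = df[["chrom", "start", "end"]].copy()
    regions["tumor_reads"] = tumor
    regions["normal_reads"] = normal
    total = float(normal_exp.sum())  # equal totals: genome-wide aligned reads
    sim_truth = SimTruth(planted_segments=planted, seeds={"cna": seed})
    return CaptureCountResult(regions=regions, tumor_total=total, normal_total=total, sim_truth=sim_truth)


# ---------------------------------------------------------------------------
# expression cohorts

SUBTYPES = ["LumP", "LumNS", "LumU", "Stroma-rich", "Ba/Sq", "NE-like"]


def make_centroids(n_genes: int = 150, subtypes: list | None = None, seed: int = 2024) -> pd.DataFrame:
    """Random but fixed classifier centroid matrix on the log2(FPKM+1) scale."""
    subtypes = subtypes or SUBTYPES
    rng = np.random.default_rng(seed)
    genes = [f"CLF{i:04d}" for i in range(n_genes)]
    vals = rng.normal(loc=5.0, scale=2.0, size=(n_genes, len(subtypes)))
    return pd.DataFrame(np.clip(vals, 0, None), index=genes, columns=subtypes)


def gen_expression_cohort(
    centroids: pd.DataFrame,
    labels: list,
    noise_sd: float,
    signature_shift: float = 0.0,
    signature_genes: list | None = None,
    immune_labels: list | None = None,
    seed: int = 0,
    sample_ids: list | None = None,
) -> ExpressionSimResult:
    """Simulate an FPKM cohort with planted subtype and immune structure.

    Each sample's log2 expression over the classifier genes equals its
    subtype centroid plus Gaussian noise (sd ``noise_sd``), back-transformed
    to FPKM. Signature genes (default 40 generated symbols) get an extra
    ``signature_shift`` on the log2 scale in samples whose immune label is
    ``"inflamed"`` (``immune_labels`` defaults to alternating).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    for lab in labels:
        if lab not in centroids.columns:
            raise ValueError(f"unknown subtype label {lab!r}")
    n = len(labels)
    rng = np.random.default_rng(seed)
    sample_ids = list(sample_ids) if sample_ids is not None else [f"S{i:03d}" for i in range(n)]
    if immune_labels is None:
        immune_labels = ["inflamed" if i % 2 == 0 else "depleted" for i in range(n)]
    if signature_genes is None:
        signature_genes = [f"SIG{i:03d}" for i in range(40)]

    log_expr = np.column_stack([centroids[lab].to_numpy() for lab in labels])
    if noise_sd > 0:
        log_expr = log_expr + rng.normal(0, noise_sd, size=log_expr.shape)

    sig_base = rng.normal(3.0, 1.0, size=len(signature_genes))
    sig = np.tile(sig_base[:, None], (1, n))
    if noise_sd > 0:
        sig = sig + rng.normal(0, noise_sd, size=sig.shape)
    inflamed = np.array([lab == "inflamed" for lab in immune_labels])
    sig[:, inflamed] += signature_shift

    full_log = np.vstack([log_expr, sig])
    genes = list(centroids.index) + list(signature_genes)
    fpkm = pd.DataFrame(
        np.clip(np.power(2.0, full_log) - 1.0, 0.0, None), index=genes, columns=sample_ids
    )
    sim_truth = SimTruth(
        sample_subtype_labels=dict(zip(sample_ids, labels)),
        sample_immune_labels=dict(zip(sample_ids, immune_labels)),
        seeds={"expression": seed},
    )
    return ExpressionSimResult(
        fpkm=fpkm, centroids=centroids, signature_genes=list(signature_genes), sim_truth=sim_truth
    )


# ---------------------------------------------------------------------------
# single-cell imaging-cytometry tables


def default_panel():
    """Default marker panel mirroring a tumor/immune/stromal antibody set."""
    from .singlecell_phenotype import PanelConfig

    clustering = [
        "panKeratin", "KRT5", "GATA3", "Ecadherin", "CD3", "CD4", "CD8a",
        "CD68", "CD11b", "CD11c", "CD16", "aSMA", "Vimentin", "CD31", "FOXP3",
    ]
    functional = ["Ki67", "PD1", "PDL1", "GranzymeB"]
    return PanelConfig(
        clustering_markers=clustering,
        functional_markers=functional,
        krt5_channel="KRT5",
        gata3_channel="GATA3",
    )


_HI, _LO = (2.5, 0.35), (0.1, 0.4)  # log-normal (location, scale) for +/- markers


def default_population_profiles(panel=None) -> dict:
    """Log-normal marker models and morphology models for seven populations."""
    panel = panel or default_panel()
    markers = panel.clustering_markers + panel.functional_markers

    def prof(high, functional_high=(), morph=None):
        m = {mk: (_HI if mk in set(high) | set(functional_high) else _LO) for mk in markers}
        morph = morph or {}
        return {
            "markers": m,
            "morphology": {
                "area": morph.get("area", (4.6, 0.3)),
                "perimeter": morph.get("perimeter", (3.6, 0.25)),
                "major_axis_length": morph.get("major_axis_length", (2.8, 0.25)),
                "eccentricity_beta": morph.get("eccentricity_beta", (2.0, 2.0)),
                "solidity_beta": morph.get("solidity_beta", (12.0, 2.0)),
            },
        }

    return {
        "tumor_luminal": prof(["panKeratin", "GATA3", "Ecadherin"], ["Ki67"]),
        "tumor_basal": prof(["panKeratin", "KRT5", "Ecadherin"], ["Ki67"]),
        "cd4_tcell": prof(["CD3", "CD4"], ["PD1"]),
        "cd8_tcell": prof(["CD3", "CD8a"], ["GranzymeB", "PD1"]),
        "treg": prof(["CD3", "CD4", "FOXP3"]),
        "macrophage": prof(["CD68", "CD11b", "CD16"], ["PDL1"]),
        "fibroblast": prof(["aSMA", "Vimentin"]),
        "endothelial": prof(["CD31", "Vimentin"]),
    }


def gen_singlecell_cohort(
    population_profiles: dict | None = None,
    n_cells_per_image: int = 500,
    images_per_sample: int = 2,
    batch_effects: dict | None = None,
    seed: int = 0,
    sample_ids: list | None = None,
    population_weights: dict | None = None,
    solidity_one_prob: float = 0.02,
    panel=None,
) -> SingleCellSimResult:
    """Simulate a single-cell marker-intensity + morphology table.

    Marker intensities are log-normal draws per population profile; batch
    effects are per-batch multiplicative factors applied to raw marker
    intensities (``batch_effects``: batch_id -> {marker: factor} or a
    scalar factor for all markers). A fraction ``solidity_one_prob`` of
    cells get solidity exactly 1.0, mimicking convex segmentation
    artifacts that downstream filtering must remove.
    """
    panel = panel or default_panel()
    profiles = population_profiles or default_population_profiles(panel)
    markers = panel.clustering_markers + panel.functional_markers
    for name, prof in profiles.items():
        missing = set(markers) - set(prof["markers"])
        if missing:
            raise ValueError(f"profile {name!r} missing panel markers {sorted(missing)}")
    sample_ids = list(sample_ids) if sample_ids is not None else ["P1_prim", "P1_met", "P2_prim", "P2_met"]
    pops = sorted(profiles)
    weights = np.array([population_weights.get(p, 1.0) if population_weights else 1.0 for p in pops])
    weights = weights / weights.sum()
    batch_effects = batch_effects or {}

    rng = np.random.default_rng(seed)
    batches = {s: f"batch{(i % 2) + 1}" for i, s in enumerate(sample_ids)}
    rows = []
    labels = {}
    cell_id = 0
    for sample in sample_ids:
        batch = batches[sample]
        be = batch_effects.get(batch, {})
        for img in range(images_per_sample):
            image_id = f"{sample}_img{img}"
            pop_draw = rng.choice(len(pops), size=n_cells_per_image, p=weights)
            for p_idx in pop_draw:
                pop = pops[p_idx]
                prof = profiles[pop]
                rec = {"cell_id": f"c{cell_id:07d}", "sample_id": sample, "image_id": image_id, "batch_id": batch}
                for mk in markers:
                    loc, scale = prof["markers"][mk]
                    factor = be if np.isscalar(be) else be.get(mk, 1.0)
                    rec[mk] = float(rng.lognormal(loc, scale)) * float(factor)
                morph = prof["morphology"]
                rec["area"] = float(rng.lognormal(*morph["area"]))
                rec["perimeter"] = float(rng.lognormal(*morph["perimeter"]))
                rec["major_axis_length"] = float(rng.lognormal(*morph["major_axis_length"]))
                rec["eccentricity"] = float(rng.beta(*morph["eccentricity_beta"]))
                if rng.random() < solidity_one_prob:
                    rec["solidity"] = 1.0
                else:
                    rec["solidity"] = float(np.clip(rng.beta(*morph["solidity_beta"]), 1e-6, 0.999999))
                rows.append(rec)
                labels[rec["cell_id"]] = pop
                cell_id += 1
    cols = ["cell_id", "sample_id", "image_id", "batch_id", *markers,
            "area", "perimeter", "major_axis_length", "eccentricity", "solidity"]
    cells = pd.DataFrame(rows, columns=cols)
    sim_truth = SimTruth(cell_population_labels=labels, seeds={"cells": seed})
    return SingleCellSimResult(cells=cells, panel=panel, sim_truth=sim_truth)
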