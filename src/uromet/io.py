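"""Readers and writers for the pipeline's file formats.

Per-caller variant call sets travel as VCF v4.2 (one file per caller,
caller name in the INFO ``CALLER`` key or the filename) or an equivalent
TSV dialect; regions, expression matrices, centroids, manifests and cell
tables are plain TSV/CSV; gene sets are GMT; panel and metacluster rule
configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .singlecell_phenotype import MetaclusterRule, PanelConfig

__all__ = [
    "write_caller_vcf", "read_caller_vcf",
    "write_variants_tsv", "read_variants_tsv",
    "write_regions_tsv", "read_regions_tsv",
    "write_matrix_tsv", "read_matrix_tsv",
    "read_gene_list", "read_gmt",
    "write_cells_csv", "read_cells_csv",
    "read_panel_yaml", "write_panel_yaml",
    "read_rules_yaml", "write_rules_yaml",
    "read_blocklist_tsv", "write_blocklist_tsv",
    "read_pairs_manifest", "read_oncogenicity_tsv",
    "write_truth_json",
]

_VCF_COLUMNS = ["sample_id", "caller", "chrom", "pos", "ref", "alt", "variant_class",
                "tumor_depth", "tumor_alt_reads", "normal_depth", "normal_alt_reads",
                "in_dbsnp", "in_cosmic", "gene", "consequence"]


def write_caller_vcf(path, calls: pd.DataFrame, caller: str | None = None) -> None:
    """Minimal VCF v4.2 emitter for one caller's somatic calls."""
    df = calls if caller is None else calls[calls["caller"] == caller]
    caller = caller or (df["caller"].iloc[0] if len(df) else "unknown")
    chroms = list(dict.fromkeys(df["chrom"])) or ["1"]
    lines = ["##fileformat=VCFv4.2", f"##source=uromet-synthetic;caller={caller}"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=CALLER,Number=1,Type=String,Description="Somatic caller">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumor sample id">',
        '##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumor depth">',
        '##INFO=<ID=TAD,Number=1,Type=Integer,Description="Tumor alt reads">',
        '##INFO=<ID=NDP,Number=1,Type=Integer,Description="Normal depth">',
        '##INFO=<ID=NAD,Number=1,Type=Integer,Description="Normal alt reads">',
        '##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Present in dbSNP">',
        '##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Present in COSMIC">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=VCLASS,Number=1,Type=String,Description="SNV or indel">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, r in df.iterrows():
        info = (f"CALLER={r['caller']};SAMPLE={r['sample_id']};TDP={int(r['tumor_depth'])};"
                f"TAD={int(r['tumor_alt_reads'])};NDP={int(r['normal_depth'])};"
                f"NAD={int(r['normal_alt_reads'])}")
        if r["in_dbsnp"]:
            info += ";DBSNP"
        if r["in_cosmic"]:
            info += ";COSMIC"
        info += f";GENE={r['gene']};CSQ={r['consequence']};VCLASS={r['variant_class']}"
        lines.append(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_caller_vcf(path, caller: str | None = None) -> pd.DataFrame:
    """Read one caller's VCF into the caller-variant table layout."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for v in vcf:
        info = dict(v.INFO)
        rows.append(dict(
            sample_id=info.get("SAMPLE", ""),
            caller=caller or info.get("CALLER") or Path(path).stem.split(".")[0],
            chrom=v.CHROM, pos=int(v.POS), ref=v.REF, alt=v.ALT[0],
            variant_class=info.get("VCLASS", "SNV"),
            tumor_depth=int(info.get("TDP", 0)), tumor_alt_reads=int(info.get("TAD", 0)),
            normal_depth=int(info.get("NDP", 0)), normal_alt_reads=int(info.get("NAD", 0)),
            in_dbsnp=bool(info.get("DBSNP", False)), in_cosmic=bool(info.get("COSMIC", False)),
            gene=info.get("GENE", ""), consequence=info.get("CSQ", "other"),
        ))
    vcf.close()
    return pd.DataFrame(rows, columns=_VCF_COLUMNS)


def write_variants_tsv(path, df: pd.DataFrame) -> None:
    out = df.copy()
    if "supporting_callers" in out.columns:
        out["supporting_callers"] = [",".join(c) for c in out["supporting_callers"]]
    out.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "supporting_callers" in df.columns:
        df["supporting_callers"] = [tuple(str(c).split(",")) for c in df["supporting_callers"]]
    return df


def write_regions_tsv(path, regions: pd.DataFrame,
                      tumor_total: float | None = None,
                      normal_total: float | None = None) -> None:
    """Regions TSV; optional per-sample alignment totals as header comments."""
    with open(path, "w") as fh:
        if tumor_total is not None:
            fh.write(f"#tumor_total={tumor_total}\n")
        if normal_total is not None:
            fh.write(f"#normal_total={normal_total}\n")
        regions[["chrom", "start", "end", "tumor_reads", "normal_reads"]].to_csv(
            fh, sep="\t", index=False)


def read_regions_tsv(path):
    """Returns (regions, tumor_total, normal_total); totals None if absent."""
    t_total = n_total = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#tumor_total="):
            t_total = float(line.split("=", 1)[1])
        elif line.startswith("#normal_total="):
            n_total = float(line.split("=", 1)[1])
        else:
            body.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t", dtype={"chrom": str})
    return df, t_total, n_total


def write_matrix_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_list(path) -> list:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.split("\t")[0])
    return genes


def read_gmt(path) -> dict:
    """GMT gene-set collection: name, description, then member genes."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_cells_csv(path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_panel_yaml(path, panel: PanelConfig) -> None:
    data = dict(clustering_markers=list(panel.clustering_markers),
                functional_markers=list(panel.functional_markers),
                krt5_channel=panel.krt5_channel, gata3_channel=panel.gata3_channel)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_panel_yaml(path) -> PanelConfig:
    data = yaml.safe_load(Path(path).read_text())
    return PanelConfig(
        clustering_markers=list(data["clustering_markers"]),
        functional_markers=list(data["functional_markers"]),
        krt5_channel=data.get("krt5_channel", "KRT5"),
        gata3_channel=data.get("gata3_channel", "GATA3"),
    )


def write_rules_yaml(path, rules: list) -> None:
    data = [dict(label=r.label, markers_high=list(r.markers_high),
                 markers_low=list(r.markers_low), threshold=r.threshold) for r in rules]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_rules_yaml(path) -> list:
    data = yaml.safe_load(Path(path).read_text())
    return [MetaclusterRule(d["label"], tuple(d.get("markers_high", ())),
                            tuple(d.get("markers_low", ())), float(d.get("threshold", 0.5)))
            for d in data]


def write_blocklist_tsv(path, blocklist: set) -> None:
    rows = sorted(blocklist)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_blocklist_tsv(path) -> set:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return set(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))


def read_pairs_manifest(path) -> pd.DataFrame:
    """TSV with patient_id, primary, metastasis, chemo_status columns."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_oncogenicity_tsv(path) -> dict:
    """Static lookup: gene, alteration, oncogenicity -> {(gene, alt): label}."""
    df = pd.read_csv(path, sep="\t")
    return {(r["gene"], r["alteration"]): r["oncogenicity"] for _, r in df.iterrows()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] if isinstance(obj, set) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_truth_json(path, sim_truth) -> None:
    """Serialize a SimTruth (ground-truth sidecar) to JSON."""
    data = dict(
        planted_shared_fraction=sim_truth.planted_shared_fraction,
        planted_segments=[list(s) for s in sim_truth.planted_segments],
        sample_subtype_labels=sim_truth.sample_subtype_labels,
        sample_immune_labels=sim_truth.sample_immune_labels,
        cell_population_labels=sim_truth.cell_population_labels,
        seeds=sim_truth.seeds,
    )
    Path(path).write_text(json.dumps(_jsonable(data), indent=2))
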