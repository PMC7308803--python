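"""Readers and writers for external formats.

Conventions: coordinates are 1-based inclusive internally (VCF convention);
BED input (0-based half-open) is converted at the boundary; chromosome
labels are normalized by stripping a leading ``chr``.  Readers reject
malformed values with line context rather than coercing them; every writer
produces files its paired reader parses losslessly (dosages, ids,
positions).

Formats: GWAS summary statistics TSV (SNP/CHR/BP/A1/A2/BETA/SE/P), VCF
(GT hard calls plus DS dosages; read via cyvcf2), PLINK text dialects
(.raw additive with a sibling .map, and .ped/.map), sample tables and QC
reports as TSV, BED4 gene intervals, GMT gene sets, and a flat key=value
configuration format.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from agestrat_prs.datatypes import GenotypePanel, SUMSTATS_COLUMNS, validate_sumstats

_SUMSTATS_HEADER = {"SNP": "id", "CHR": "chrom", "BP": "pos", "A1": "effect_allele",
                    "A2": "other_allele", "BETA": "beta", "SE": "se", "P": "p"}


def _norm_chrom(values) -> pd.Series:
    s = pd.Series(values).astype(str)
    return s.str.replace(r"^chr", "", regex=True)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV (SNP CHR BP A1 A2 BETA SE P).

    Extra columns are ignored.  Rows with non-numeric BETA/SE/P are
    rejected with their line numbers; P must lie in (0, 1]; SNP ids must
    be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SUMSTATS_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns=_SUMSTATS_HEADER)[list(_SUMSTATS_HEADER.values())]
    lines = df.index + 2  # 1-based, after the header line
    bad_rows = []
    for col in ("pos", "beta", "se", "p"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        bad_rows.extend(lines[bad].tolist())
        df[col] = vals
    out_of_domain = (df["p"] <= 0) | (df["p"] > 1) | (df["se"] <= 0)
    bad_rows.extend(lines[out_of_domain.fillna(False)].tolist())
    if bad_rows:
        raise ValueError(
            f"{path}: malformed or out-of-domain numeric values on lines "
            f"{sorted(set(bad_rows))[:10]}"
        )
    dups = df.loc[df["id"].duplicated(), "id"].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicated SNP ids {dups[:5]}")
    df["chrom"] = _norm_chrom(df["chrom"])
    df["pos"] = df["pos"].astype(int)
    return validate_sumstats(df.reset_index(drop=True))


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    validate_sumstats(sumstats)
    out = sumstats[SUMSTATS_COLUMNS].rename(
        columns={v: k for k, v in _SUMSTATS_HEADER.items()}
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype panels
# ---------------------------------------------------------------------------

def write_panel_vcf(panel: GenotypePanel, path) -> None:
    """Write a VCF with GT hard calls and a DS dosage FORMAT field."""
    path = Path(path)
    calls = panel.hard_calls()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.sample_ids)) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in panel.variants.iterrows():
            fields = [str(row["chrom"]), str(row["pos"]), str(row["id"]),
                      str(row["other_allele"]), str(row["effect_allele"]), ".", ".",
                      f"INFO={row['info']:g}", "GT:DS"]
            col_calls = calls[:, j]
            col_ds = panel.dosages[:, j]
            miss = np.isnan(col_calls)
            sample_fields = [
                "./.:." if miss[i] else f"{gt_map[col_calls[i]]}:{col_ds[i]:g}"
                for i in range(panel.n_samples)
            ]
            fh.write("\t".join(fields + sample_fields) + "\n")


def read_panel_vcf(path) -> GenotypePanel:
    """Read a (plain or bgzipped) VCF into a panel via cyvcf2.

    ALT-allele dosages come from the DS field when present (clipped to
    [0, 2] with a warning if outside), else from GT hard calls.
    Multi-allelic records are skipped with a reported count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    ids, chroms, poss, eff, oth, infos = [], [], [], [], [], []
    dosage_cols, missing_cols = [], []
    n_multi = 0
    n_clipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM).removeprefix("chr"))
        poss.append(var.POS)
        eff.append(var.ALT[0])
        oth.append(var.REF)
        infos.append(float(var.INFO.get("INFO", 1.0)))
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        gt = np.array(var.gt_types)  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        miss = gt == 2
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            if np.any((d < 0) | (d > 2)):
                n_clipped += int(np.sum((d < 0) | (d > 2)))
                d = np.clip(d, 0, 2)
            miss = np.isnan(d)
            d = np.where(miss, 0.0, d)
        else:
            d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=0.0)
        dosage_cols.append(d)
        missing_cols.append(miss)
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multi-allelic records", stacklevel=2)
    if n_clipped:
        warnings.warn(f"{path}: clipped {n_clipped} DS values to [0, 2]", stacklevel=2)
    if not ids:
        raise ValueError(f"{path}: no usable biallelic records")
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "effect_allele": eff, "other_allele": oth, "info": infos})
    dosages = np.column_stack(dosage_cols)
    missing = np.column_stack(missing_cols)
    return GenotypePanel(sample_ids=samples, variants=variants, dosages=dosages,
                         missing=missing if missing.any() else None)


def write_panel_raw(panel: GenotypePanel, prefix) -> None:
    """Write PLINK additive text (.raw) plus a sibling .map for positions."""
    prefix = Path(prefix)
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{r['id']}_{r['effect_allele']}" for _, r in panel.variants.iterrows()
    ]
    with open(prefix.with_suffix(".raw"), "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(panel.sample_ids):
            row = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j in range(panel.n_variants):
                if panel.missing is not None and panel.missing[i, j]:
                    row.append("NA")
                else:
                    row.append(f"{panel.dosages[i, j]:g}")
            fh.write(" ".join(row) + "\n")
    _write_map(panel, prefix.with_suffix(".map"))


def _write_map(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        for _, r in panel.variants.iterrows():
            fh.write(f"{r['chrom']}\t{r['id']}\t0\t{r['pos']}\n")


def _read_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep=r"\s+", header=None,
                    names=["chrom", "id", "cm", "pos"], dtype={"chrom": str})
    m["chrom"] = _norm_chrom(m["chrom"])
    return m


def read_panel_raw(prefix) -> GenotypePanel:
    """Read PLINK .raw; positions/alleles come from the sibling .map when
    present, else synthetic consecutive positions on chromosome 0."""
    prefix = Path(prefix)
    raw_path = prefix if prefix.suffix == ".raw" else prefix.with_suffix(".raw")
    df = pd.read_csv(raw_path, sep=r"\s+")
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_cols = [c for c in fixed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{raw_path}: missing PLINK .raw columns {missing_cols}")
    snp_cols = [c for c in df.columns if c not in fixed]
    ids, eff = [], []
    for c in snp_cols:
        vid, _, allele = c.rpartition("_")
        if not vid:
            raise ValueError(f"{raw_path}: malformed SNP column {c!r} (want ID_ALLELE)")
        ids.append(vid)
        eff.append(allele)
    dosages = df[snp_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    missing = np.isnan(dosages)
    dosages = np.where(missing, 0.0, dosages)
    map_path = raw_path.with_suffix(".map")
    if map_path.exists():
        m = _read_map(map_path).set_index("id")
        chroms = m.loc[ids, "chrom"].tolist()
        poss = m.loc[ids, "pos"].tolist()
    else:
        chroms, poss = ["0"] * len(ids), list(range(1, len(ids) + 1))
    other = ["N" if e != "N" else "M" for e in eff]  # .raw does not carry the other allele
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "effect_allele": eff, "other_allele": other, "info": 1.0})
    return GenotypePanel(sample_ids=df["IID"].astype(str).to_numpy(), variants=variants,
                         dosages=dosages, missing=missing if missing.any() else None)


def write_panel_ped(panel: GenotypePanel, prefix) -> None:
    """Write PLINK .ped/.map (hard calls; fractional dosages are rounded)."""
    prefix = Path(prefix)
    calls = panel.hard_calls()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            row = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j in range(panel.n_variants):
                e = panel.variants["effect_allele"].iloc[j]
                o = panel.variants["other_allele"].iloc[j]
                g = calls[i, j]
                if np.isnan(g):
                    row += ["0", "0"]
                else:
                    row += {0.0: [o, o], 1.0: [o, e], 2.0: [e, e]}[g]
            fh.write(" ".join(row) + "\n")
    _write_map(panel, prefix.with_suffix(".map"))


def read_panel_ped(prefix) -> GenotypePanel:
    """Read PLINK .ped/.map.  The effect (counted) allele per variant is
    taken as the less frequent allele observed, for want of an annotation."""
    prefix = Path(prefix)
    m = _read_map(prefix.with_suffix(".map"))
    with open(prefix.with_suffix(".ped")) as fh:
        rows = [line.split() for line in fh if line.strip()]
    n_var = len(m)
    sample_ids, geno = [], []
    for k, row in enumerate(rows, start=1):
        if len(row) != 6 + 2 * n_var:
            raise ValueError(
                f"{prefix.with_suffix('.ped')}: line {k} has {len(row)} fields, "
                f"expected {6 + 2 * n_var}"
            )
        sample_ids.append(row[1])
        geno.append(row[6:])
    geno = np.array(geno).reshape(len(rows), n_var, 2)
    dosages = np.zeros((len(rows), n_var))
    missing = np.zeros_like(dosages, dtype=bool)
    eff, oth = [], []
    for j in range(n_var):
        alleles = geno[:, j, :]
        obs = alleles[alleles != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 0:
            uniq, counts = np.array(["N", "M"]), np.array([0, 0])
        if len(uniq) == 1:
            uniq = np.append(uniq, "N" if uniq[0] != "N" else "M")
            counts = np.append(counts, 0)
        order = np.argsort(counts)  # minor allele first
        e, o = uniq[order[0]], uniq[order[-1]]
        eff.append(e)
        oth.append(o)
        missing[:, j] = (alleles == "0").any(axis=1)
        dosages[:, j] = (alleles == e).sum(axis=1)
    variants = m[["id", "chrom", "pos"]].copy()
    variants["effect_allele"] = eff
    variants["other_allele"] = oth
    variants["info"] = 1.0
    return GenotypePanel(sample_ids=np.array(sample_ids), variants=variants,
                         dosages=dosages, missing=missing if missing.any() else None)


def read_panel(path, dialect: str = "vcf") -> GenotypePanel:
    """Dispatch on dialect: ``vcf``, ``raw`` (PLINK additive) or ``ped``."""
    if dialect == "vcf":
        return read_panel_vcf(path)
    if dialect == "raw":
        return read_panel_raw(path)
    if dialect == "ped":
        return read_panel_ped(path)
    raise ValueError(f"unknown panel dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Sample tables, BED, GMT, flat config
# ---------------------------------------------------------------------------

def write_sample_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample table lacks a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_bed(path) -> pd.DataFrame:
    """Read BED4 gene intervals; 0-based half-open converted to 1-based
    inclusive ``chrom, start, end, gene``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str, "gene": str})
    if df[["start", "end"]].isna().any().any() or df["gene"].isna().any():
        raise ValueError(f"{path}: BED4 requires chrom, start, end, gene on every line")
    df["chrom"] = _norm_chrom(df["chrom"])
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: interval with start > end after conversion")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name, description, then gene ids, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {k} has fewer than 3 tab-separated fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_flat_config(path) -> dict[str, str]:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {k} is not of the form key = value")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
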