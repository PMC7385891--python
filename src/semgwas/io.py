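"""Reading and writing genotype/phenotype data, the MAF and call-rate filters,
and the phenotype transforms (category merges, log, z-score)."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ORDINAL, DatasetBundle, VariableMeta


class MalformedRecordError(ValueError):
    pass


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VCF reader (htslib via cyvcf2): diploid GT coded by alternate-allele count.

    Multi-allelic records are skipped (count reported in snp_info.attrs).
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:                       # htslib parse failure
        raise MalformedRecordError(f"{path}: {exc}") from exc
    samples = list(reader.samples)
    if not samples:
        raise MalformedRecordError(f"{path}: no sample columns")
    rows = []
    info_rows = []
    skipped = 0
    for lineno, rec in enumerate(reader, 1):
        if rec.ALT is None or len(rec.ALT) != 1:
            skipped += 1
            continue
        codes = []
        for call in rec.genotypes:
            alleles = call[:-1]                    # last entry is the phase flag
            if any(a < 0 for a in alleles):
                codes.append(np.nan)
            else:
                codes.append(float(sum(alleles)))
        if len(codes) != len(samples):
            raise MalformedRecordError(f"record {lineno}: wrong call count")
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        rows.append((snp_id, codes))
        info_rows.append((snp_id, rec.CHROM, int(rec.POS), rec.REF, rec.ALT[0]))
    reader.close()
    genotypes = pd.DataFrame({sid: codes for sid, codes in rows}, index=samples)
    snp_info = pd.DataFrame(info_rows, columns=["snp", "chrom", "pos", "ref", "alt"]
                            ).set_index("snp")
    snp_info.attrs["skipped_multiallelic"] = skipped
    return genotypes, snp_info


def read_genotype_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plain sample x SNP TSV: header = SNP ids, first column = sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    genotypes = df.astype(float)
    snp_info = pd.DataFrame({"chrom": 1, "pos": np.arange(1, df.shape[1] + 1),
                             "ref": "N", "alt": "N"}, index=df.columns)
    return genotypes, snp_info


def read_genotypes(path, format: str = "vcf") -> tuple[pd.DataFrame, pd.DataFrame]:
    if format == "vcf":
        return read_vcf(path)
    if format == "table":
        return read_genotype_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_vcf(path, genotypes: pd.DataFrame, snp_info: pd.DataFrame) -> None:
    """Write codes {0,1,2,NaN} as a minimal VCF v4.2 (GT only, positions 1-based)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(snp_info["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in genotypes.index) + "\n")
        for snp in genotypes.columns:
            info = snp_info.loc[snp]
            calls = [gt_map.get(int(c), "./.") if np.isfinite(c) else "./."
                     for c in genotypes[snp]]
            fh.write(f"{info['chrom']}\t{info['pos']}\t{snp}\t{info['ref']}\t"
                     f"{info['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def filter_variants(genotypes: pd.DataFrame, maf_min: float = 0.03,
                    call_rate_min: float = 0.90
                    ) -> tuple[pd.DataFrame, dict]:
    """Retain SNPs with MAF strictly above ``maf_min`` and call rate strictly
    above ``call_rate_min``.

    MAF is min(p, 1-p) with p = mean(code)/2 over non-missing calls.
    """
    codes = genotypes.to_numpy(dtype=float)
    n = codes.shape[0]
    called = np.isfinite(codes).sum(axis=0)
    call_rate = called / n
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    pass_maf = maf > maf_min
    pass_cr = call_rate > call_rate_min
    keep = pass_maf & pass_cr
    report = {
        "n_input": int(codes.shape[1]),
        "n_retained": int(keep.sum()),
        "dropped_maf": int((~pass_maf).sum()),
        "dropped_call_rate": int((~pass_cr).sum()),
        "maf_min": maf_min, "call_rate_min": call_rate_min,
    }
    return genotypes.loc[:, keep], report


def prepare_phenotypes(raw_table: pd.DataFrame,
                       meta: dict[str, VariableMeta]) -> pd.DataFrame:
    """Apply category merges, log transforms and z-scoring per trait metadata.

    Ordinal traits keep integer codes (thresholds are estimated downstream);
    quantitative traits end up with mean 0 and sd 1.
    """
    missing = [c for c in raw_table.columns if str(c) not in meta]
    if missing:
        raise KeyError(f"metadata missing for traits: {missing}")
    out = raw_table.copy()
    for col in out.columns:
        m = meta[str(col)]
        series = out[col]
        if m.merge_map:
            series = series.map(lambda v: m.merge_map.get(v, v))
        if m.kind == ORDINAL:
            out[col] = series
            continue
        values = series.to_numpy(dtype=float)
        if "log" in m.transform:
            bad = np.nonzero(np.isfinite(values) & (values <= 0))[0]
            if bad.size:
                sample = raw_table.index[bad[0]]
                raise ValueError(
                    f"non-positive value for log transform: trait {col!r}, "
                    f"sample {sample!r}")
            values = np.log(values)
        if m.transform in ("zscore", "log+zscore", "none", "log"):
            # all quantitative traits are z-scored
            mu = np.nanmean(values)
            sd = np.nanstd(values, ddof=1)
            if sd == 0:
                raise ValueError(f"constant quantitative trait {col!r}")
            values = (values - mu) / sd
        out[col] = values
    return out


def write_phenotypes(path, phenotypes: pd.DataFrame,
                     meta: dict[str, VariableMeta]) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="sample")
    side = Path(str(path) + ".meta.tsv")
    rows = [{"trait": name, "kind": m.kind, "transform": m.transform,
             "merge_map": json.dumps(m.merge_map)} for name, m in meta.items()]
    pd.DataFrame(rows).to_csv(side, sep="\t", index=False)


def read_phenotypes(path) -> tuple[pd.DataFrame, dict[str, VariableMeta]]:
    phen = pd.read_csv(path, sep="\t", index_col="sample")
    side = Path(str(path) + ".meta.tsv")
    meta: dict[str, VariableMeta] = {}
    def _coerce_key(k):
        try:
            f = float(k)
            return int(f) if f == int(f) else f
        except (TypeError, ValueError):
            return k

    if side.exists():
        tab = pd.read_csv(side, sep="\t")
        for _, row in tab.iterrows():
            raw_map = (json.loads(row["merge_map"])
                       if isinstance(row.get("merge_map"), str) else {})
            meta[str(row["trait"])] = VariableMeta(
                name=str(row["trait"]), kind=row["kind"],
                transform=row.get("transform", "none"),
                merge_map={_coerce_key(k): v for k, v in raw_map.items()})
    else:
        meta = {str(c): VariableMeta(name=str(c)) for c in phen.columns}
    return phen, meta


def load_bundle(vcf_path, phenotype_path) -> DatasetBundle:
    genotypes, snp_info = read_vcf(vcf_path)
    phen, meta = read_phenotypes(phenotype_path)
    common = [s for s in genotypes.index if s in phen.index]
    return DatasetBundle(genotypes=genotypes.loc[common],
                         snp_info=snp_info,
                         phenotypes=phen.loc[common],
                         trait_meta=meta)


def write_manifest(path, **entries) -> None:
    import semgwas

    doc = {"package_version": semgwas.__version__,
           "python": platform.python_version(),
           "numpy": np.__version__, "pandas": pd.__version__}
    doc.update(entries)
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
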