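"""Readers and writers for the pipeline's file formats.

Genotypes come in as VCF v4.x (read through cyvcf2); population maps,
frequency tables, sentinel catalogues and functional annotations are TSV;
gene coordinates are BED. All coordinates are held 1-based inclusive
internally (VCF convention); BED's 0-based half-open intervals are converted
at the reader boundary.
"""

from __future__ import annotations

import csv
from collections import defaultdict

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    FREQ_COLUMNS,
    MISSING,
    GenotypeMatrix,
    PopFreqTable,
    SentinelCatalog,
    VariantRecord,
    resolve_func_class,
)


def read_pop_map(path) -> dict[str, str]:
    """Read a two-column (sample, population) TSV; a header line is optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in {"sample", "sample_id"}:
                continue
            if len(row) < 2:
                raise ValueError(f"population map line {i + 1} has fewer than 2 columns")
            out[row[0]] = row[1]
    if not out:
        raise ValueError(f"empty population map: {path}")
    return out


def read_vcf(path, pop_map=None, default_pop: str = "pop1") -> GenotypeMatrix:
    """Load a VCF into alt-allele dosages.

    Multiallelic sites are split into one biallelic record per alternate
    allele; each sample's dosage for an alt is the number of its called
    alleles equal to that alt, so the per-sample sum of alt dosages at a
    split site equals its total non-reference allele count. Genotypes with
    any missing allele become :data:`~varstrat.types.MISSING`.

    pop_map maps sample id -> population; when given, a VCF sample absent
    from the map is a hard error.
    """
    if isinstance(pop_map, (str, bytes)) or hasattr(pop_map, "__fspath__"):
        pop_map = read_pop_map(pop_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if pop_map is not None:
        absent = [s for s in samples if s not in pop_map]
        if absent:
            raise ValueError(f"samples missing from population map: {absent}")
        pops = [pop_map[s] for s in samples]
    else:
        pops = [default_pop] * len(samples)

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        for alt_i, alt in enumerate(v.ALT, start=1):
            dos = np.empty(len(samples), dtype=np.int8)
            for si, g in enumerate(gts):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    dos[si] = MISSING
                else:
                    dos[si] = sum(1 for a in alleles if a == alt_i)
            variants.append(VariantRecord(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt))
            columns.append(dos)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(sample_ids=samples, variants=variants, calls=calls,
                          pop_labels=pops)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write biallelic GT-only records as a minimal VCF v4.2 text file."""
    contigs: dict[str, None] = {}
    for v in gm.variants:
        contigs.setdefault(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, var in enumerate(gm.variants):
            gts = "\t".join(gt_str[int(c)] for c in gm.calls[:, j])
            fh.write(f"{var.chrom}\t{var.pos}\t{var.variant_id}\t{var.ref}\t{var.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def write_pop_map(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpop\n")
        for s, p in zip(gm.sample_ids, gm.pop_labels):
            fh.write(f"{s}\t{p}\n")


def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED; 0-based half-open -> 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            if end0 <= start0:
                raise ValueError(f"empty BED interval: {line}")
            rows.append((chrom, start0 + 1, end0, name))
    if not rows:
        raise ValueError(f"no intervals in BED file {path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene intervals back out as BED."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.name}\n")


def read_freq_table(path) -> PopFreqTable:
    df = pd.read_csv(path, sep="\t")
    if "af" not in df.columns:
        df["af"] = df["alt_count"] / df["n_chrom"]
    return PopFreqTable(df[FREQ_COLUMNS])


def write_freq_table(freqs: PopFreqTable, path) -> None:
    freqs.table.to_csv(path, sep="\t", index=False)


def read_sentinels(path) -> list[SentinelCatalog]:
    """Read a sentinel TSV with a leading ``phenotype`` column."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for pheno, sub in df.groupby("phenotype", sort=False):
        out.append(SentinelCatalog(phenotype=str(pheno),
                                   entries=sub.drop(columns="phenotype").reset_index(drop=True)))
    if not out:
        raise ValueError(f"no sentinels in {path}")
    return out


def write_sentinels(catalogs, path) -> None:
    frames = []
    for cat in catalogs:
        sub = cat.entries.copy()
        sub.insert(0, "phenotype", cat.phenotype)
        frames.append(sub)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict[str, str]:
    """Read variant_id -> functional class, collapsing multi-labels by precedence."""
    labels: dict[str, list[str]] = defaultdict(list)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in {"variant_id", "variant"}:
                continue
            vid, raw = row[0], row[1]
            labels[vid].extend(lab for lab in raw.split(",") if lab)
    return {vid: resolve_func_class(labs) for vid, labs in labels.items()}


def write_annotations(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tfunc_class\tis_novel\n")
        for v in variants:
            fh.write(f"{v.variant_id}\t{v.func_class}\t{int(v.is_novel)}\n")
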