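"""Readers and writers for the pipeline's plain-text formats.

Conventions: CpG positions are 1-based; BED-style interval tracks are
0-based half-open (stored as such in memory, so BED files round-trip
unchanged). Methylation matrices are written CpG-rows x sample-columns
(the common array-export layout) but held in memory samples x CpGs;
the reader auto-orients using the index labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, SampleMetadata
from .context import AnnotationTrack
from .hits import CpGSet
from .mqtl import GenotypeMatrix


def write_methylation(mm, path) -> None:
    """Write betas as TSV, CpG rows x sample columns, plus a coordinate
    side-car ``<path>.coords.tsv`` when coordinates are available."""
    betas = getattr(mm, "betas", mm)
    betas.T.to_csv(path, sep="\t", index_label="cpg_id")
    info = getattr(mm, "cpg_info", None)
    if info is not None:
        info.to_csv(str(path) + ".coords.tsv", sep="\t", index_label="cpg_id")


def read_methylation(path, coords_path=None) -> MethylationMatrix | pd.DataFrame:
    """Read a methylation TSV, auto-orienting to samples x CpGs.

    Orientation is decided from the labels: if the row index looks like
    CpG ids (``cg``-prefixed) and the columns do not, the table is
    transposed. Returns a ``MethylationMatrix`` when a coordinate
    side-car exists (or is passed), otherwise a bare DataFrame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows_cpg = _looks_like_cpgs(df.index)
    cols_cpg = _looks_like_cpgs(df.columns)
    if rows_cpg and not cols_cpg:
        df = df.T
    df.index.name = "sample_id"
    df.columns.name = "cpg_id"
    if coords_path is None:
        candidate = Path(str(path) + ".coords.tsv")
        coords_path = candidate if candidate.exists() else None
    if coords_path is not None:
        info = pd.read_csv(coords_path, sep="\t", index_col=0)
        return MethylationMatrix(betas=df, cpg_info=info.loc[df.columns])
    return df


def _looks_like_cpgs(index) -> bool:
    labels = [str(x) for x in list(index)[:20]]
    return bool(labels) and all(s.startswith("cg") for s in labels)


def write_metadata(metadata, path) -> None:
    frame = getattr(metadata, "frame", metadata)
    frame.to_csv(path, index_label="sample_id", date_format="%Y-%m-%d")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, index_col=0, parse_dates=["conception_date"])
    if "collection_date" in df.columns:
        df["collection_date"] = pd.to_datetime(df["collection_date"])
    df["conception_date"] = df["conception_date"].dt.date
    return SampleMetadata(df.drop(columns=[c for c in ("theta",) if c in df]))


def write_bed(track: AnnotationTrack, path) -> None:
    """Write an interval track as 3-column BED (0-based half-open)."""
    if track.intervals is None:
        raise ValueError("only interval tracks can be written as BED")
    track.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path, name=None) -> AnnotationTrack:
    iv = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return AnnotationTrack(name=name or Path(path).stem, intervals=iv)


def write_dosage(genotypes: GenotypeMatrix, path) -> None:
    """Dosage TSV: SNP rows (chrom, pos, then one column per sample)."""
    out = genotypes.info[["chrom", "pos"]].join(genotypes.dosages.T)
    out.to_csv(path, sep="\t", index_label="snp_id")


def read_dosage(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    info = df[["chrom", "pos"]]
    dosages = df.drop(columns=["chrom", "pos"]).T.astype(int)
    dosages.index.name = "sample_id"
    return GenotypeMatrix(dosages=dosages, info=info)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT genotypes derived from dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(genotypes.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        info = genotypes.info.sort_values(["chrom", "pos"])
        for snp_id, row in info.iterrows():
            calls = "\t".join(gt_map[int(v)] for v in genotypes.dosages[snp_id])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF via cyvcf2 (GT, or DS when present)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        if "DS" in dict(var.FORMAT or {}):
            rows.append(np.rint(np.asarray(var.format("DS")).ravel()).astype(int))
        else:
            gts = np.asarray(var.genotypes)[:, :2]
            rows.append(gts.sum(axis=1).astype(int))
    dosages = pd.DataFrame(np.column_stack(rows) if rows else np.empty((len(samples), 0)),
                           index=pd.Index(samples, name="sample_id"),
                           columns=ids)
    info = pd.DataFrame({"chrom": chroms, "pos": pos}, index=ids)
    return GenotypeMatrix(dosages=dosages, info=info)


def write_cpg_set(cpg_set: CpGSet, path) -> None:
    """One-column TSV of CpG ids plus a JSON provenance side-car."""
    pd.Series(cpg_set.cpg_ids, name="cpg_id").to_csv(path, sep="\t", index=False)
    side = {"label": cpg_set.label, "provenance": cpg_set.provenance}
    Path(str(path) + ".provenance.json").write_text(json.dumps(side, indent=2, default=str))


def read_cpg_set(path) -> CpGSet:
    ids = pd.read_csv(path, sep="\t")["cpg_id"].tolist()
    side = Path(str(path) + ".provenance.json")
    label, prov = "custom", {}
    if side.exists():
        data = json.loads(side.read_text())
        label, prov = data.get("label", "custom"), data.get("provenance", {})
    return CpGSet(label=label, cpg_ids=ids, provenance=prov)


def write_ewas(table: pd.DataFrame, path) -> None:
    """EWAS table as TSV with a fixed, documented column order."""
    cols = ["intercept", "beta1", "gamma1", "sin_p", "cos_p", "lrt_stat",
            "p_value", "q_value", "amplitude_pct", "peak_day", "nadir_day",
            "n_used", "n_outliers"]
    table[cols].to_csv(path, sep="\t", index_label="cpg_id", float_format="%.10g")


def read_ewas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="cpg_id")


def write_cohort(cohort, outdir) -> None:
    """Write all cohort artefacts (methylation, metadata, genotypes,
    tracks, truth) into a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_methylation(cohort.methylation, outdir / "methylation.tsv")
    write_metadata(cohort.metadata, outdir / "metadata.csv")
    write_dosage(cohort.genotypes, outdir / "dosages.tsv")
    write_vcf(cohort.genotypes, outdir / "genotypes.vcf")
    for track in cohort.tracks:
        write_bed(track, outdir / f"track_{track.name}.bed")
    write_truth(cohort.truth, outdir / "truth.tsv")
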