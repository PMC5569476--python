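"""Readers and writers for the toolkit's file formats.

Coordinates are 1-based inclusive internally (VCF/GFF convention).  BED input
(0-based half-open) is converted at this boundary.  Genotypes travel as VCF:
GT 0/0, 0/1, 1/1 for AA/AB/BB, ./.  for uncalled, with a FORMAT/NG integer
flag distinguishing no-signal NG samples from failed/off-cluster ``--``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam

from .calling import IntensityMatrix
from .genotypes import GenotypeMatrix

# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_candidates(path) -> pd.DataFrame:
    """Candidate manifest TSV (id, chrom, pos, ref, alt, maf, het_rate,
    accuracy, design_score, multi_mapped [, region_class, feature])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    if "multi_mapped" in df.columns:
        df["multi_mapped"] = df["multi_mapped"].astype(bool)
    return df


def write_candidates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genome_layout(path) -> pd.DataFrame:
    """Genome layout TSV: chrom, length_bp, subgenome."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "subgenome": str})
    if (df["length_bp"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome names in genome layout")
    return df


def write_genome_layout(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample, group [, replicate_of, parent1, parent2]."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    if "parent1" in df.columns:
        self_ped = df.index == df["parent1"]
        if self_ped.any() or (df.index == df.get("parent2", pd.Series(index=df.index))).any():
            raise ValueError("self-pedigree in metadata")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: sample column + one column per trait."""
    return pd.read_csv(path, sep="\t").set_index("sample")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# BED (repeat masks) — 0-based half-open on disk, 1-based inclusive in memory
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    out = pd.DataFrame({"chrom": df["chrom"],
                        "start": df["start"].astype(int) + 1,
                        "end": df["end"].astype(int)})
    if (out["end"] < out["start"]).any():
        bad = out[out["end"] < out["start"]].iloc[0]
        raise ValueError(f"malformed BED interval on {bad['chrom']}")
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"chrom": intervals["chrom"],
                        "start": intervals["start"].astype(int) - 1,
                        "end": intervals["end"].astype(int)})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_variant_positions(path) -> pd.DataFrame:
    """Neighbor-variant TSV: chrom, pos (1-based)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_variant_positions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 gene features
# ---------------------------------------------------------------------------

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


def read_gff3(path) -> pd.DataFrame:
    """Gene/exon/UTR features (chrom, start, end, ftype, gene_id), 1-based."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for f in db.all_features():
        if f.featuretype == "gene":
            rows.append({"chrom": f.seqid, "start": f.start, "end": f.end,
                         "ftype": "gene", "gene_id": f.id})
        elif f.featuretype == "exon" or f.featuretype in _UTR_TYPES:
            parents = list(db.parents(f, featuretype="gene"))
            gene_id = parents[0].id if parents else f.attributes.get("Parent", [""])[0]
            if not parents:
                warnings.warn(f"feature {f.id or f.featuretype} at "
                              f"{f.seqid}:{f.start}-{f.end} has no gene parent")
            ftype = "exon" if f.featuretype == "exon" else "UTR"
            rows.append({"chrom": f.seqid, "start": f.start, "end": f.end,
                         "ftype": ftype, "gene_id": gene_id})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ftype", "gene_id"])


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write a gene/exon/UTR feature table as GFF3 (exon/UTR Parent = gene)."""
    type_map = {"gene": "gene", "exon": "exon", "UTR": "five_prime_UTR"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counters: dict[str, int] = {}
        for _, f in features.sort_values(["chrom", "start"]).iterrows():
            ftype = type_map[f["ftype"]]
            if f["ftype"] == "gene":
                attrs = f"ID={f['gene_id']}"
            else:
                counters[f["gene_id"]] = counters.get(f["gene_id"], 0) + 1
                attrs = (f"ID={f['gene_id']}.{f['ftype']}{counters[f['gene_id']]};"
                         f"Parent={f['gene_id']}")
            fh.write("\t".join([str(f["chrom"]), "snparray", ftype,
                                str(int(f["start"])), str(int(f["end"])),
                                ".", "+", ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# intensity matrices
# ---------------------------------------------------------------------------

def read_intensities(path) -> IntensityMatrix:
    """Long-format intensity TSV: marker_id, sample_id, theta, norm_r."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "sample_id": str})
    theta = df.pivot(index="marker_id", columns="sample_id", values="theta")
    norm_r = df.pivot(index="marker_id", columns="sample_id", values="norm_r")
    return IntensityMatrix(theta=theta, norm_r=norm_r)


def write_intensities(intensities: IntensityMatrix, path) -> None:
    long = intensities.theta.stack().rename("theta").to_frame()
    long["norm_r"] = intensities.norm_r.stack()
    long.index.names = ["marker_id", "sample_id"]
    long.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

_GT_FIELD = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./.", -2: "./."}


def write_vcf(gm: GenotypeMatrix, manifest: pd.DataFrame, path) -> None:
    """Write calls as VCF.

    ``manifest`` is marker-indexed (or has an ``id`` column) with chrom, pos,
    ref, alt.  NG is encoded as FORMAT/NG=1 with GT ./. ; failed/off-cluster
    calls are ./. with NG=0.
    """
    mf = manifest.set_index("id") if "id" in manifest.columns else manifest
    mf = mf.loc[gm.markers]
    samples = list(map(str, gm.samples))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snparray\n")
        for chrom in pd.unique(mf["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=NG,Number=1,Type=Integer,'
                 'Description="1 = no-signal (NG) sample at a working locus">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        codes = gm.codes.values
        order = np.lexsort((mf["pos"].to_numpy(), mf["chrom"].to_numpy()))
        for i in order:
            marker = gm.markers[i]
            row = mf.iloc[i]
            fields = [str(row["chrom"]), str(int(row["pos"])), str(marker),
                      str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT:NG"]
            for c in codes[i]:
                fields.append(f"{_GT_FIELD[int(c)]}:{1 if c == -1 else 0}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a genotype VCF back into a GenotypeMatrix plus a marker manifest."""
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    codes = []
    manifest_rows = []
    markers = []
    for rec in vcf:
        markers.append(rec.id)
        manifest_rows.append({"id": rec.id, "chrom": rec.chrom, "pos": rec.pos,
                              "ref": rec.ref,
                              "alt": rec.alts[0] if rec.alts else "."})
        row = np.full(len(samples), -2, dtype=np.int8)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or None in gt:
                row[j] = -1 if call.get("NG") == 1 else -2
            else:
                row[j] = int(sum(gt))
        codes.append(row)
    gm = GenotypeMatrix(pd.DataFrame(np.array(codes, dtype=np.int8),
                                     index=markers, columns=samples))
    manifest = pd.DataFrame(manifest_rows).set_index("id")
    return gm, manifest


# ---------------------------------------------------------------------------
# small result writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_distance_matrix(dm, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample")


def read_distance_matrix(path):
    from .popgen import DistanceMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(ids=list(df.index.astype(str)), values=df.values)


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick + "\n")
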