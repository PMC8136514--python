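"""Readers and writers for the pipeline's on-disk formats.

All basepair coordinates on disk are 0-based half-open (the BED/bedGraph
convention).  Formats: 4-column bedGraph-style depth TSV, BED, FASTA
(via Biopython), minimal PAF with an ``id:f:`` identity tag, a two-file
backcross representation (marker map TSV + genotype matrix TSV with a
phenotype column), and counts TSV with subclass/PBS annotation columns plus
a sample-to-group TSV.  Malformed lines are reported with their line
numbers; all round-trips are lossless on valid files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gv1scan.assembly import AlignmentSegment
from gv1scan.cnv import CnvCall, DepthProfile, DistanceMatrix
from gv1scan.expression import ExpressionMatrix
from gv1scan.linkage import BackcrossDataset

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def _lines(path: PathLike):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line and not line.startswith(("#", "track")):
                yield i, line


# -- bedGraph-style depth TSV ------------------------------------------------


def write_depth_profile(profile: DepthProfile, path: PathLike) -> None:
    with open(path, "w") as fh:
        for s, e, c in zip(profile.starts, profile.ends, profile.counts):
            fh.write(f"{profile.chrom}\t{s}\t{e}\t{c:g}\n")


def read_depth_profile(path: PathLike, strain: str) -> DepthProfile:
    chroms, starts, ends, counts = [], [], [], []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{i}: expected 4 columns, got {len(parts)}")
        try:
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            counts.append(float(parts[3]))
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
    if not starts:
        raise FormatError(f"{path}: empty depth file")
    if len(set(chroms)) != 1:
        raise FormatError(f"{path}: multiple chromosomes in one profile")
    return DepthProfile(
        strain=strain,
        chrom=chroms[0],
        starts=np.array(starts),
        ends=np.array(ends),
        counts=np.array(counts),
    )


# -- BED ---------------------------------------------------------------------


def write_bed(records: Sequence[tuple], path: PathLike) -> None:
    """Write (chrom, start, end[, extra...]) tuples as BED."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path: PathLike) -> list[tuple]:
    out = []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: BED needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
        if end <= start:
            raise FormatError(f"{path}:{i}: empty or inverted interval")
        out.append((parts[0], start, end, *parts[3:]))
    return out


def write_cnv_calls(calls: Sequence[CnvCall], path: PathLike) -> None:
    """CNV calls as a TSV with state and span columns (BED-compatible)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstate\tmean_ratio\tspan_kb\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.state}"
                f"\t{c.mean_ratio:.4f}\t{c.span_kb:.1f}\n"
            )


# -- FASTA -------------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- minimal PAF -------------------------------------------------------------


def write_paf(
    segs: Sequence[AlignmentSegment],
    path: PathLike,
    query_lengths: Mapping[str, int] | None = None,
    target_lengths: Mapping[str, int] | None = None,
) -> None:
    """Minimal PAF: 11 mandatory columns, mapq 255, plus an id:f: tag."""
    with open(path, "w") as fh:
        for s in segs:
            qlen = (query_lengths or {}).get(s.qname, s.qend)
            tlen = (target_lengths or {}).get(s.tname, s.tend)
            span = max(s.query_span, s.target_span)
            matches = round(span * s.identity / 100.0)
            strand = "+" if s.orientation == "forward" else "-"
            fh.write(
                f"{s.qname}\t{qlen}\t{s.qstart}\t{s.qend}\t{strand}"
                f"\t{s.tname}\t{tlen}\t{s.tstart}\t{s.tend}"
                f"\t{matches}\t{span}\t255\tid:f:{s.identity:.4f}\n"
            )


def read_paf(path: PathLike) -> list[AlignmentSegment]:
    segs = []
    for i, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 12:
            raise FormatError(f"{path}:{i}: PAF needs >= 12 columns")
        try:
            identity = None
            for tag in parts[12:]:
                if tag.startswith("id:f:"):
                    identity = float(tag[5:])
            if identity is None:
                # fall back to matches / block length
                identity = 100.0 * int(parts[9]) / int(parts[10])
            segs.append(
                AlignmentSegment(
                    qname=parts[0],
                    qstart=int(parts[2]),
                    qend=int(parts[3]),
                    tname=parts[5],
                    tstart=int(parts[7]),
                    tend=int(parts[8]),
                    identity=identity,
                    orientation="forward" if parts[4] == "+" else "reverse",
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
    return segs


# -- backcross ---------------------------------------------------------------


def write_backcross(data: BackcrossDataset, map_path: PathLike, geno_path: PathLike) -> None:
    data.markers.to_csv(map_path, sep="\t", index=False)
    df = pd.DataFrame(data.genotypes, columns=list(data.markers["name"]))
    df.insert(0, "animal", [f"a{i}" for i in range(len(df))])
    df["phenotype"] = data.phenotype
    df.to_csv(geno_path, sep="\t", index=False)


def read_backcross(map_path: PathLike, geno_path: PathLike) -> BackcrossDataset:
    markers = pd.read_csv(map_path, sep="\t")
    geno_df = pd.read_csv(geno_path, sep="\t")
    missing = [c for c in ("animal", "phenotype") if c not in geno_df.columns]
    if missing:
        raise FormatError(f"{geno_path}: missing columns {missing}")
    marker_cols = [c for c in geno_df.columns if c not in ("animal", "phenotype")]
    if marker_cols != list(markers["name"]):
        raise FormatError(
            f"{geno_path}: genotype columns do not match the marker map"
        )
    return BackcrossDataset(
        markers=markers,
        genotypes=geno_df[marker_cols].to_numpy(dtype="U1"),
        phenotype=geno_df["phenotype"].to_numpy(),
    )


# -- expression counts -------------------------------------------------------


def write_expression(m: ExpressionMatrix, counts_path: PathLike, groups_path: PathLike) -> None:
    df = m.loci.join(m.counts)
    df.index.name = "locus"
    df.to_csv(counts_path, sep="\t")
    g = m.groups.rename("group").to_frame()
    if m.library_sizes is not None:
        g["library_size"] = m.library_sizes
    g.index.name = "sample"
    g.to_csv(groups_path, sep="\t")


def read_expression(counts_path: PathLike, groups_path: PathLike) -> ExpressionMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="locus")
    for col in ("subclass", "pbs"):
        if col not in df.columns:
            raise FormatError(f"{counts_path}: missing column {col!r}")
    gdf = pd.read_csv(groups_path, sep="\t", index_col="sample")
    libs = gdf["library_size"] if "library_size" in gdf.columns else None
    sample_cols = [c for c in df.columns if c not in ("subclass", "pbs")]
    return ExpressionMatrix(
        counts=df[sample_cols].astype(int),
        loci=df[["subclass", "pbs"]],
        groups=gdf["group"],
        library_sizes=libs,
    )


# -- distance matrix ---------------------------------------------------------


def write_distance_matrix(d: DistanceMatrix, path: PathLike) -> None:
    pd.DataFrame(d.values, index=d.strains, columns=d.strains).to_csv(path, sep="\t")


def read_distance_matrix(path: PathLike) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(strains=list(df.columns), values=df.to_numpy())
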