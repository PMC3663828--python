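"""Readers and writers for the standard text formats used by the pipeline.

FASTA via Biopython, GFF3 via gffutils (in-memory database), tabular formats
(BED6, fragment tables, bedGraph, TSV) via pandas.  All writers emit
deterministic ordering; coordinates are converted between the internal
0-based half-open convention and each format's native convention here and
only here.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import GeneModel
from .genome import GenomeAssembly
from .profiles import FilterMask

__all__ = [
    "read_fasta", "write_fasta",
    "read_bed_reads", "write_bed_reads",
    "read_pairs",
    "write_bedgraph", "read_bedgraph",
    "write_mask_bed", "read_intervals_bed",
    "write_gff3", "read_gff3",
    "read_tag_counts", "write_tag_counts",
    "write_pi_model", "read_pi_model",
    "write_energy_profile", "read_energy_profile",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> GenomeAssembly:
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeAssembly(seqs)


def write_fasta(genome: GenomeAssembly, path: str, width: int = 70) -> None:
    records = [SeqRecord(Seq(genome.sequences[c]), id=c, description="")
               for c in genome]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Reads (BED6: score column carries the mapping weight)


def read_bed_reads(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "weight",
                            "strand"],
                     dtype={"chrom": str}, float_precision="round_trip")
    return df[["chrom", "start", "end", "strand", "weight"]]


def write_bed_reads(reads: pd.DataFrame, path: str) -> None:
    df = reads.copy()
    if "name" not in df:
        df["name"] = [f"read{i}" for i in range(len(df))]
    df[["chrom", "start", "end", "name", "weight", "strand"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g")


def read_pairs(path: str) -> pd.DataFrame:
    """Paired-end fragments as a chrom/start/end[/weight] TSV (BED3-like)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in df.columns:
        df = df.rename(columns={3: "weight"})
    else:
        df["weight"] = 1.0
    return df[["chrom", "start", "end", "weight"]]


# ---------------------------------------------------------------------------
# bedGraph profiles


def write_bedgraph(profile: Dict[str, np.ndarray], path: str,
                   precision: int = 17) -> None:
    """Run-length-merged bedGraph; NaN stretches are omitted."""
    with open(path, "w") as fh:
        for chrom in profile:
            v = np.asarray(profile[chrom], dtype=float)
            if len(v) == 0:
                continue
            # boundaries where the value changes (NaN == NaN for merging)
            same = (v[1:] == v[:-1]) | (np.isnan(v[1:]) & np.isnan(v[:-1]))
            starts = np.concatenate([[0], np.flatnonzero(~same) + 1])
            ends = np.concatenate([starts[1:], [len(v)]])
            for s, e in zip(starts, ends):
                if np.isnan(v[s]):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.{precision}g}\n")


def read_bedgraph(path: str, lengths: Dict[str, int],
                  fill: float = np.nan) -> Dict[str, np.ndarray]:
    out = {c: np.full(n, fill) for c, n in lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str}, float_precision="round_trip")
    for row in df.itertuples(index=False):
        out[row.chrom][row.start:row.end] = row.value
    return out


# ---------------------------------------------------------------------------
# Masks / intervals (BED3)


def write_mask_bed(mask: FilterMask, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in mask.to_intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_intervals_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return df


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: Iterable[GeneModel], path: str,
               source: str = "nucleoform") -> None:
    """Write gene/mRNA/exon features (GFF3 is 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g.gene_id
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            tid = f"{gid}.t1"
            fh.write(f"{g.chrom}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={gid}\n")
            for k, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={tid}.e{k + 1};Parent={tid}\n")


def read_gff3(path: str, transcript_choice: str = "longest") -> List[GeneModel]:
    """Load gene models from GFF3, one transcript per gene.

    ``transcript_choice``: "longest" picks the transcript with the largest
    summed exon length; "first" picks the first annotated one.
    """
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        best: Optional[Tuple[int, List[Tuple[int, int]]]] = None
        for k, mrna in enumerate(db.children(gene, featuretype="mRNA",
                                             order_by="start")):
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(mrna, featuretype="exon"))
            span = sum(e - s for s, e in exons)
            if not exons:
                continue
            if transcript_choice == "first":
                if best is None:
                    best = (span, exons)
            elif best is None or span > best[0]:
                best = (span, exons)
        if best is None:
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, best[1]))
    return genes


# ---------------------------------------------------------------------------
# Expression tag counts


def read_tag_counts(path: str) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "count"],
                     dtype={"gene_id": str}, float_precision="round_trip")
    return dict(zip(df["gene_id"], df["count"].astype(float)))


def write_tag_counts(counts: Dict[str, float], path: str) -> None:
    pd.DataFrame({"gene_id": list(counts), "count": list(counts.values())}) \
        .to_csv(path, sep="\t", header=False, index=False,
                float_format="%.17g")


# ---------------------------------------------------------------------------
# Model parameters (word/energy TSV; round-trips bit-stably via %.17g)


def write_pi_model(model, path: str) -> None:
    from .seqmodels import BASES, DINUCLEOTIDES
    rows = [("offset", model.offset_)]
    rows += list(zip(BASES, model.mono_energies_))
    rows += list(zip(DINUCLEOTIDES, model.dinuc_energies_))
    pd.DataFrame(rows, columns=["word", "energy"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_pi_model(path: str, footprint: int = 147, N: int = 2):
    from .seqmodels import BASES, DINUCLEOTIDES, PositionIndependentModel
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    vals = dict(zip(df["word"], df["energy"].astype(float)))
    m = PositionIndependentModel(N=N, footprint=footprint)
    m.offset_ = float(vals["offset"])
    m.mono_energies_ = np.array([vals[b] for b in BASES])
    m.dinuc_energies_ = np.array([vals[w] for w in DINUCLEOTIDES])
    return m


# ---------------------------------------------------------------------------
# Energy profiles (bedGraph-style TSV over start positions)


def write_energy_profile(energy, path: str) -> None:
    data = {c: np.where(energy.defined[c], energy.E[c], np.nan)
            for c in energy.E}
    with open(path, "w") as fh:
        fh.write(f"#mu={energy.mu:.17g}\tfootprint={energy.footprint}\n")
    _append_bedgraph(data, path)


def _append_bedgraph(profile: Dict[str, np.ndarray], path: str) -> None:
    with open(path, "a") as fh:
        for chrom in profile:
            v = profile[chrom]
            for i in np.flatnonzero(np.isfinite(v)):
                fh.write(f"{chrom}\t{i}\t{i + 1}\t{v[i]:.17g}\n")


def read_energy_profile(path: str, lengths: Dict[str, int]):
    from .energetics import EnergyProfile
    with open(path) as fh:
        header = fh.readline().strip()
    parts = dict(kv.split("=") for kv in header.lstrip("#").split("\t"))
    mu = float(parts["mu"])
    footprint = int(parts["footprint"])
    n = {c: max(L - footprint + 1, 0) for c, L in lengths.items()}
    out = {c: np.full(k, np.nan) for c, k in n.items()}
    df = pd.read_csv(path, sep="\t", header=None, skiprows=1,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str}, float_precision="round_trip")
    for row in df.itertuples(index=False):
        out[row.chrom][row.start] = row.value
    return EnergyProfile(out, mu, footprint)
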