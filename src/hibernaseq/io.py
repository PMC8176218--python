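"""Readers and writers for the plain-text formats used by the pipeline.

FASTA, BED6/BED12, two-file (plus/minus) bedGraph, TSV tables and YAML
pattern libraries.  Everything round-trips; coordinates stay 0-based,
half-open on disk (BED convention).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from .core import CoverageTrack, GeneModel, InputError, PatternLibrary, TranscribedSegment


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True, build_index=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_bed12(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.start) for s, e in exons)
            thick = g.cds if g.cds is not None else (g.start, g.start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom,
                        g.start,
                        g.end,
                        g.gene_id,
                        0,
                        g.strand,
                        thick[0],
                        thick[1],
                        "0,0,0",
                        len(exons),
                        sizes + ",",
                        starts + ",",
                    )
                )
                + "\n"
            )


def read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            thick = (int(f[6]), int(f[7]))
            cds = thick if thick[1] > thick[0] else None
            genes.append(
                GeneModel(
                    gene_id=f[3],
                    chrom=f[0],
                    start=start,
                    end=end,
                    strand=f[5],
                    exons=exons,
                    cds=cds,
                )
            )
    return genes


def write_segments_bed6(segments: list[TranscribedSegment], path: str | os.PathLike) -> None:
    """BED6 output: name = state, score = mean coverage x10 rounded."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.chrom, s.strand, s.start)):
            score = int(round(s.mean_coverage * 10))
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{score}\t{s.strand}\n")


def read_segments_bed6(path: str | os.PathLike) -> list[TranscribedSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, state, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                TranscribedSegment(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    state=state,
                    mean_coverage=int(score) / 10 if int(score) else 0.05,
                )
            )
    return out


def write_bedgraph(track: CoverageTrack, prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write one bedGraph per strand: <prefix>.plus.bedgraph / <prefix>.minus.bedgraph."""
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = Path(f"{prefix}.{tag}.bedgraph")
        with open(path, "w") as fh:
            for chrom in track.chrom_lengths:
                arr = track.get(chrom, strand)
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
        paths.append(path)
    return tuple(paths)


def read_bedgraph(
    plus_path: str | os.PathLike,
    minus_path: str | os.PathLike,
    chrom_lengths: dict[str, int],
) -> CoverageTrack:
    track = CoverageTrack(chrom_lengths)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.rstrip("\n").split("\t")[:4]
                if chrom not in chrom_lengths:
                    raise InputError(f"bedGraph chromosome {chrom!r} not in genome")
                track.get(chrom, strand)[int(s) : int(e)] += float(v)
    return track


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_pattern_library(library: PatternLibrary, path: str | os.PathLike) -> None:
    doc = {
        "states": list(library.states),
        "templates": {name: [float(x) for x in vec] for name, vec in library.templates.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_pattern_library(path: str | os.PathLike) -> PatternLibrary:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PatternLibrary(
        tuple(doc["states"]),
        {name: np.asarray(vec, float) for name, vec in doc["templates"].items()},
    )
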