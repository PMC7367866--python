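"""Readers, writers and provenance headers.

FASTA goes through Bio.SeqIO; paired FASTQ streams through Biopython's fast
FastqGeneralIterator so large simulated libraries never sit in memory.
Tabular artifacts (TSV, BED) begin with '#'-comment provenance lines
recording the tool version, subcommand, seed and a config hash, and BED
coordinates are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from . import __version__
from .design import (AnnotationInterval, DesignConfig, LadderDesign,
                     LadderElement, LadderSet, SourceWindow)
from .simulate import ReadBatch

__all__ = [
    "read_fasta", "write_fasta", "read_fastq_paired", "write_fastq_paired",
    "provenance_lines", "write_tsv", "read_tsv", "write_ladder_annotation",
    "read_ladder_set", "batch_to_fastq", "fastq_to_batch",
]


def provenance_lines(subcommand: str, seed: int | None = None,
                     config: dict | None = None) -> list[str]:
    cfg_hash = hashlib.sha1(
        json.dumps(config or {}, sort_keys=True, default=str).encode()).hexdigest()[:12]
    lines = [f"# cnladder v{__version__}", f"# subcommand={subcommand}",
             f"# config_sha1={cfg_hash}"]
    if seed is not None:
        lines.insert(2, f"# seed={seed}")
    return lines


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA records as (id, upper-case sequence); duplicate ids are an error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"lowercase bases in {rec.id} upper-cased", stacklevel=2)
            seq = seq.upper()
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_fastq_paired(path1: str | Path, path2: str | Path
                      ) -> Iterator[tuple[str, str, str, str, str]]:
    """Stream (name, seq1, qual1, seq2, qual2); errors name the record index."""
    it1 = FastqGeneralIterator(str(path1))
    it2 = FastqGeneralIterator(str(path2))
    i = 0
    while True:
        try:
            r1 = next(it1, None)
            r2 = next(it2, None)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ at record {i}: {exc}") from exc
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError(f"mate files differ in length at record {i}")
        name = r1[0].split()[0]
        if name.endswith("/1"):
            name = name[:-2]
        yield name, r1[1], r1[2], r2[1], r2[2]
        i += 1


def write_fastq_paired(path1: str | Path, path2: str | Path,
                       pairs: Iterable[tuple[str, str, str, str, str]]) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, q1, s2, q2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")


def batch_to_fastq(batch: ReadBatch, prefix: str | Path) -> tuple[Path, Path]:
    p1 = Path(f"{prefix}_R1.fastq")
    p2 = Path(f"{prefix}_R2.fastq")
    write_fastq_paired(p1, p2, batch.pairs())
    return p1, p2


def fastq_to_batch(path1: str | Path, path2: str | Path) -> ReadBatch:
    names, r1, r2 = [], [], []
    for name, s1, _q1, s2, _q2 in read_fastq_paired(path1, path2):
        names.append(name)
        r1.append(s1)
        r2.append(s2)
    return ReadBatch(names, r1, r2)


def write_tsv(path: str | Path, df: pd.DataFrame, subcommand: str,
              seed: int | None = None, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(subcommand, seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_ladder_annotation(path: str | Path, ladder_set: LadderSet,
                            subcommand: str = "design",
                            seed: int | None = None) -> None:
    """BED-style annotation: 0-based half-open intervals tiling each molecule."""
    rows = []
    for ladder in ladder_set:
        for iv in ladder.annotation:
            rows.append({
                "ladder_id": ladder.ladder_id, "start": iv.start, "end": iv.end,
                "feature": iv.feature,
                "element_id": iv.element_id or ".",
                "copy_index": iv.copy_index if iv.copy_index is not None else ".",
                "cn": iv.cn if iv.cn is not None else ".",
            })
    write_tsv(path, pd.DataFrame(rows), subcommand, seed)


def read_ladder_set(fasta_path: str | Path, annotation_path: str | Path,
                    config: DesignConfig | None = None) -> LadderSet:
    """Rebuild a LadderSet from its FASTA and annotation artifacts.

    Element sequences are sliced back out of the full molecules using the
    annotated intervals, so a written design round-trips exactly.
    """
    seqs = dict(read_fasta(fasta_path))
    ann = read_tsv(annotation_path)
    ladders = []
    for lid, sub in ann.groupby("ladder_id", sort=False):
        if lid not in seqs:
            raise ValueError(f"annotation refers to unknown ladder {lid}")
        full = seqs[lid]
        intervals = []
        elements: dict[str, LadderElement] = {}
        spacers = []
        flank5 = flank3 = ""
        for _, row in sub.sort_values("start").iterrows():
            start, end = int(row["start"]), int(row["end"])
            feature = row["feature"]
            eid = None if row["element_id"] in (".", None) else str(row["element_id"])
            copy_index = None if row["copy_index"] in (".", None) else int(row["copy_index"])
            cn = None if row["cn"] in (".", None) else int(row["cn"])
            intervals.append(AnnotationInterval(start, end, feature, eid, copy_index, cn))
            piece = full[start:end]
            if feature == "element" and eid not in elements:
                elements[eid] = LadderElement(eid, piece, SourceWindow("unknown", -1, -1), cn)
            elif feature == "spacer":
                spacers.append(piece)
            elif feature == "flank_5p":
                flank5 = piece
            elif feature == "flank_3p":
                flank3 = piece
        ladders.append(LadderDesign(
            ladder_id=str(lid), elements=list(elements.values()),
            spacer_sequences=spacers, flank_5p=flank5, flank_3p=flank3,
            full_sequence=full, annotation=intervals))
    cfg = config
    if cfg is None:
        elem_len = len(ladders[0].elements[0].sequence)
        cfg = DesignConfig(
            element_len=elem_len,
            cn_vector=tuple(sorted(e.assigned_cn for e in ladders[0].elements)),
            spacer_len=len(ladders[0].spacer_sequences[0]) if ladders[0].spacer_sequences else 0,
            flank_len=len(ladders[0].flank_5p),
            n_ladders=len(ladders))
    return LadderSet(ladders=ladders, config=cfg)
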