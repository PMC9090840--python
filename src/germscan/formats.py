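"""Readers and writers for the text formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the boundary.  Readers are lossless — biotype filtering and
deduplication happen downstream.  Depth is held dense (one integer per base)
because every consumer is a linear pass over the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SeqDict",
    "DepthTrack",
    "GeneModel",
    "BedRecord",
    "GONAD_GROUPS",
    "EMBRYO_GROUPS",
    "read_seqdict",
    "write_seqdict",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "write_sample_sheet",
]

GONAD_GROUPS = ("UD", "EF", "MF", "LF", "PM", "EM", "MM", "LM")
EMBRYO_GROUPS = ("pre_pgr", "post_pgr")

BIOTYPES = ("protein_coding", "rRNA", "tRNA", "lncRNA", "pseudogene", "other")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class SeqDict:
    """Ordered mapping of sequence name -> length in bases."""

    def __init__(self, lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise FormatError("duplicate sequence names in SeqDict")
        for name, length in items:
            if int(length) < 1:
                raise FormatError(f"sequence {name!r} has non-positive length {length}")
        self._lengths: dict[str, int] = {n: int(v) for n, v in items}

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, SeqDict) and self._lengths == other._lengths

    def items(self):
        return self._lengths.items()

    def names(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"SeqDict({len(self)} sequences, {self.total_length} bp)"


@dataclass
class DepthTrack:
    """Dense per-base integer depth for one sample over a SeqDict.

    Sequences absent from the source file are present as all-zero arrays so
    that downstream scans can iterate the SeqDict without special cases.
    """

    sample: str
    seqdict: SeqDict
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.seqdict.items():
            if name not in self.depths:
                self.depths[name] = np.zeros(length, dtype=np.int64)
        for name, arr in self.depths.items():
            if name not in self.seqdict:
                raise FormatError(f"depth for unknown sequence {name!r}")
            arr = np.asarray(arr, dtype=np.int64)
            if arr.shape != (self.seqdict[name],):
                raise FormatError(
                    f"depth array for {name!r} has length {arr.shape[0]}, "
                    f"expected {self.seqdict[name]}"
                )
            if arr.min(initial=0) < 0:
                raise FormatError(f"negative depth on sequence {name!r}")
            self.depths[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.depths[name]


@dataclass(frozen=True)
class GeneModel:
    """One gene feature. Coordinates 0-based half-open on its sequence."""

    gene_id: str
    name: str
    seq: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid span [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BedRecord:
    seq: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"BED record {self.seq}:{self.start}-{self.end} has start >= end")


# ---------------------------------------------------------------------------
# sequence-length table


def read_seqdict(path: str | Path) -> SeqDict:
    """Read a two-column TSV of sequence name and length."""
    items: list[tuple[str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                items.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return SeqDict(items)


def write_seqdict(seqdict: SeqDict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, length in seqdict.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, seqdict: SeqDict, sample: str | None = None) -> DepthTrack:
    """Read a 4-column bedGraph into a dense DepthTrack.

    Records must be non-overlapping within each sequence; uncovered positions
    are depth 0.  Raises FormatError naming the offending line on overlap,
    unknown sequence, or negative value.
    """
    depths = {name: np.zeros(length, dtype=np.int64) for name, length in seqdict.items()}
    covered = {name: np.zeros(length, dtype=bool) for name, length in seqdict.items()}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            seq, s, e, v = parts[0], parts[1], parts[2], parts[3]
            if seq not in seqdict:
                raise FormatError(f"{path}:{lineno}: unknown sequence {seq!r}")
            try:
                start, end = int(s), int(e)
                value = float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {value}")
            if not (0 <= start < end <= seqdict[seq]):
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) outside {seq!r} "
                    f"(length {seqdict[seq]})"
                )
            if covered[seq][start:end].any():
                raise FormatError(f"{path}:{lineno}: overlapping bedGraph records on {seq!r}")
            covered[seq][start:end] = True
            depths[seq][start:end] = int(round(value))
    label = sample if sample is not None else Path(path).stem
    return DepthTrack(sample=label, seqdict=seqdict, depths=depths)


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Write a DepthTrack as run-length encoded bedGraph (zero runs omitted).

    read_bedgraph(write_bedgraph(t)) reproduces t exactly because absent
    positions read back as depth 0.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in track.seqdict:
            arr = track.depths[name]
            if arr.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            values = arr[starts]
            nz = values != 0
            if not nz.any():
                continue
            pd.DataFrame(
                {"seq": name, "start": starts[nz], "end": ends[nz], "value": values[nz]}
            ).to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GFF3 gene features


def _gff3_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        out[key] = value
    return out


def read_gff3_genes(path: str | Path, seqdict: SeqDict) -> list[GeneModel]:
    """Read gene-level features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open
    ((1,100) -> [0,100)).  Name defaults to ID when absent; biotype (from a
    ``biotype`` or ``gene_biotype`` attribute) defaults to protein_coding.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = parts
            if ftype != "gene":
                continue
            if seq not in seqdict:
                raise FormatError(f"{path}:{lineno}: unknown sequence {seq!r}")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = _gff3_attributes(attrs_s)
            if "ID" not in attrs:
                raise FormatError(f"{path}:{lineno}: gene feature missing ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            start, end = start1 - 1, end1
            if end > seqdict[seq]:
                raise FormatError(f"{path}:{lineno}: gene extends past end of {seq!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    name=attrs.get("Name", gene_id),
                    seq=seq,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else ".",
                    biotype=attrs.get("biotype", attrs.get("gene_biotype", "protein_coding")),
                )
            )
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.name};biotype={g.biotype}"
            fh.write(
                f"{g.seq}\tgermscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    """Write BED5 (or BED6 when any record carries a strand)."""
    records = list(records)
    with_strand = any(r.strand is not None for r in records)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fields = [r.seq, str(r.start), str(r.end), r.name, repr(float(r.score))]
            if with_strand:
                fields.append(r.strand or ".")
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else None
            out.append(BedRecord(parts[0], start, end, name, score, strand))
    return out


# ---------------------------------------------------------------------------
# count matrix + sample sheet


def read_counts(
    path_counts: str | Path,
    path_sheet: str | Path,
    mode: str = "gonad",
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a gene x sample count TSV plus a sample sheet.

    Returns (counts, sheet) where counts is a DataFrame (genes as index,
    samples as columns) and sheet a Series mapping sample id -> group label.
    The group vocabulary is closed per mode ('gonad' or 'embryo').
    """
    vocab = GONAD_GROUPS if mode == "gonad" else EMBRYO_GROUPS
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"{path_counts}: duplicate gene ids {dupes[:5]}")
    if counts.columns.has_duplicates:
        raise FormatError(f"{path_counts}: duplicate sample ids")
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().any()
        raise FormatError(
            f"{path_counts}: non-numeric cells in columns {list(bad[bad].index)[:5]}"
        )
    if (numeric < 0).any().any():
        raise FormatError(f"{path_counts}: negative counts")
    counts = numeric

    sheet_df = pd.read_csv(path_sheet, sep="\t")
    if not {"sample_id", "group"}.issubset(sheet_df.columns):
        raise FormatError(f"{path_sheet}: expected columns sample_id and group")
    if sheet_df["sample_id"].duplicated().any():
        raise FormatError(f"{path_sheet}: duplicate sample ids")
    sheet = pd.Series(
        sheet_df["group"].to_numpy(), index=sheet_df["sample_id"].to_numpy(), name="group"
    )
    unknown = set(sheet) - set(vocab)
    if unknown:
        raise FormatError(
            f"{path_sheet}: unknown group labels {sorted(unknown)}; allowed: {list(vocab)}"
        )
    missing = set(counts.columns) - set(sheet.index)
    if missing:
        raise FormatError(f"samples {sorted(missing)} in count matrix missing from sheet")
    extra = set(sheet.index) - set(counts.columns)
    if extra:
        raise FormatError(f"samples {sorted(extra)} in sheet missing from count matrix")
    sheet = sheet.loc[counts.columns]
    return counts, sheet


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def write_sample_sheet(sheet: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": sheet.index, "group": sheet.to_numpy()})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
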