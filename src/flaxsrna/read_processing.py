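"""FASTQ/FASTA read processing: trimming, filtering, and tag collapsing.

Small-RNA libraries are sequenced through a 3' adapter, so every useful read
contains the adapter downstream of the insert.  Processing removes the
adapter, drops low-quality reads, collapses identical inserts into unique
*tags* with per-library counts, and applies the abundance filter (tags seen
fewer than ``min_count`` times in a library are treated as absent from it).
The :class:`TagTable` produced here is the unit of all downstream analysis.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seq import check_dna, normalize

DEFAULT_MIN_COUNT = 6
DEFAULT_MIN_LEN = 16
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_MEAN_QUALITY = 20.0

CONDITIONS = ("N", "P", "NPK")


@dataclass
class ReadRecord:
    """A single sequencing read (qualities optional, Phred scale)."""

    id: str
    sequence: str
    qualities: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass
class SrnaLibrary:
    """Bookkeeping for one sequenced library."""

    name: str
    condition: str
    total_raw: int = 0
    total_clean: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.total_clean > self.total_raw:
            raise ValueError("total_clean cannot exceed total_raw")


@dataclass
class TagTable:
    """Collapsed unique sRNA tags with per-library counts.

    ``counts`` is a DataFrame indexed by tag (uppercase DNA, no N) with one
    integer column per library.
    """

    counts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(dtype=int))

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)

    def lengths(self) -> pd.Series:
        return self.counts.index.to_series().str.len().rename("length")

    def count(self, tag: str, library: str) -> int:
        if tag in self.counts.index and library in self.counts.columns:
            return int(self.counts.at[tag, library])
        return 0

    @classmethod
    def from_mapping(cls, data: Mapping[str, Mapping[str, int]]) -> "TagTable":
        """Build from ``{tag: {library: count}}``; validates tags."""
        tags = {check_dna(t, allow_n=False): c for t, c in data.items()}
        df = pd.DataFrame.from_dict(tags, orient="index").fillna(0).astype(int)
        df.index.name = "tag"
        return cls(df.sort_index())

    def merge(self, other: "TagTable") -> "TagTable":
        """Outer-join two tables; shared libraries are summed."""
        merged = self.counts.add(
            other.counts.reindex(columns=self.counts.columns.union(other.counts.columns)),
            fill_value=0,
        )
        merged = merged.reindex(columns=self.counts.columns.union(other.counts.columns))
        return TagTable(merged.fillna(0).astype(int).sort_index())

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "length", df.index.str.len())
        df.to_csv(path, sep="\t", index_label="tag")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TagTable":
        df = pd.read_csv(path, sep="\t", index_col="tag")
        df = df.drop(columns=["length"])
        return cls(df.astype(int))


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTQ (Phred+33) as :class:`ReadRecord`."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(
                id=title.split()[0],
                sequence=normalize(seq),
                qualities=[ord(c) - 33 for c in qual],
            )


def read_fasta(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield ReadRecord(id=rec.id, sequence=normalize(str(rec.seq)))


def trim_adapter(
    read: ReadRecord | str,
    adapter: str,
    min_overlap: int = 8,
) -> str | None:
    """Remove the 3' adapter from a read; ``None`` means rejected.

    The insert upstream of the left-most full adapter occurrence is returned.
    If the adapter does not occur in full, a suffix of the read matching a
    prefix of the adapter of length >= ``min_overlap`` (exact match) is
    trimmed instead.  Reads without any adapter evidence are rejected, as are
    reads whose insert would be empty: with a 3'-adapter protocol a genuine
    small-RNA insert is shorter than the read, so the adapter must be seen.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if not seq:
        raise ValueError("cannot trim an empty read")
    adapter = normalize(adapter)
    if not (1 <= min_overlap <= len(adapter)):
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = normalize(seq)
    pos = seq.find(adapter)
    if pos == -1:
        # longest suffix of the read equal to a prefix of the adapter
        for ov in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:ov]):
                pos = len(seq) - ov
                break
        else:
            return None
    return seq[:pos] if pos > 0 else None


def quality_ok(read: ReadRecord, min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY) -> bool:
    """Conventional quality gate: no N and mean Phred >= threshold."""
    if "N" in read.sequence:
        return False
    if read.qualities is not None:
        if sum(read.qualities) / len(read.qualities) < min_mean_quality:
            return False
    return True


def collapse_reads(
    sequences: Iterable[str],
    library: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> TagTable:
    """Collapse trimmed inserts into a single-library :class:`TagTable`.

    Sequences containing N or outside the length bounds are dropped.
    """
    counter: collections.Counter[str] = collections.Counter()
    for s in sequences:
        s = normalize(s)
        if "N" in s or not (min_len <= len(s) <= max_len):
            continue
        counter[s] += 1
    df = pd.DataFrame({library: pd.Series(counter, dtype=int)})
    df.index.name = "tag"
    return TagTable(df.sort_index())


def process_library(
    reads: Iterable[ReadRecord],
    library: str,
    adapter: str,
    min_overlap: int = 8,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[TagTable, SrnaLibrary]:
    """Full per-library chain: quality filter, adapter trim, collapse."""
    inserts = []
    total_raw = 0
    for read in reads:
        total_raw += 1
        if not quality_ok(read, min_mean_quality):
            continue
        insert = trim_adapter(read, adapter, min_overlap)
        if insert is not None:
            inserts.append(insert)
    table = collapse_reads(inserts, library, min_len, max_len)
    condition = library if library in CONDITIONS else "N"
    stats = SrnaLibrary(
        name=library,
        condition=condition,
        total_raw=total_raw,
        total_clean=len(inserts),
    )
    return table, stats


def filter_abundance(
    table: TagTable,
    min_count: int = DEFAULT_MIN_COUNT,
    per_library: bool = True,
) -> TagTable:
    """Apply the abundance filter (default: keep counts of six or more).

    With ``per_library`` each library is filtered independently: counts below
    the threshold are zeroed, and tags absent everywhere are dropped.  This
    matches per-library "unique sequences with abundance >= threshold"
    accounting.  Otherwise a tag is kept (with all its counts) if its maximum
    count across libraries reaches the threshold.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    df = table.counts
    if per_library:
        filtered = df.where(df >= min_count, 0)
        filtered = filtered[(filtered > 0).any(axis=1)]
    else:
        filtered = df[(df >= min_count).any(axis=1)]
    return TagTable(filtered.astype(int))


def length_histogram(table: TagTable, weighting: str = "reads") -> dict[int, float]:
    """Length distribution as fractions summing to 1.

    ``weighting='reads'`` weights each tag by its total read count across
    libraries; ``'unique'`` counts each tag once.
    """
    if len(table) == 0:
        raise ValueError("length_histogram of an empty table")
    if weighting not in ("reads", "unique"):
        raise ValueError("weighting must be 'reads' or 'unique'")
    lengths = table.lengths()
    if weighting == "reads":
        weights = table.counts.sum(axis=1)
    else:
        weights = pd.Series(1, index=table.counts.index)
    grouped = weights.groupby(lengths).sum()
    total = grouped.sum()
    return {int(k): float(v) / total for k, v in grouped.items()}


def write_histogram_tsv(hist: Mapping[int, float], path: str | Path) -> None:
    pd.Series(dict(sorted(hist.items())), name="fraction").rename_axis("length").to_csv(
        path, sep="\t"
    )
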