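"""Exact-match mapping of short tags to a genome via a k-mer seed index.

Tags are abundance-collapsed exact sequences, so mapping is exact-match on
both strands with all occurrences reported (multi-hit), which is what
presence/absence genome-matching of small-RNA tags requires at desk scale.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .read_processing import TagTable
from .seq import check_dna, normalize, revcomp

DEFAULT_SEED_K = 12
DEFAULT_MAX_HITS = 20


@dataclass(frozen=True, order=True)
class GenomeHit:
    """One exact occurrence of a tag: 0-based half-open forward coordinates.

    A ``-`` strand hit means the reverse complement of the tag occurs at
    ``[start, end)`` of the forward contig sequence.
    """

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")


@dataclass
class MapResult:
    hits: list[GenomeHit]
    overflow: bool = False


@dataclass
class GenomeIndex:
    """Seed-and-verify exact substring index over a set of contigs."""

    contigs: dict[str, str]
    k: int = DEFAULT_SEED_K
    _seeds: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs or all(len(s) == 0 for s in self.contigs.values()):
            raise ValueError("cannot index an empty genome")
        self.contigs = {name: check_dna(s) for name, s in self.contigs.items()}
        seeds: dict[str, list[tuple[str, int]]] = collections.defaultdict(list)
        for name in sorted(self.contigs):
            seq = self.contigs[name]
            for i in range(len(seq) - self.k + 1):
                seeds[seq[i : i + self.k]].append((name, i))
        self._seeds = dict(seeds)

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = DEFAULT_SEED_K) -> "GenomeIndex":
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs, k=k)

    def occurrences(self, query: str) -> list[tuple[str, int]]:
        """All forward-strand occurrence positions of ``query`` (exact)."""
        query = normalize(query)
        out = []
        for contig, pos in self._seeds.get(query[: self.k], ()):
            if self.contigs[contig][pos : pos + len(query)] == query:
                out.append((contig, pos))
        return out

    def slice(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]


def map_tag(index: GenomeIndex, tag: str, max_hits: int = DEFAULT_MAX_HITS) -> MapResult:
    """All exact occurrences of ``tag`` on both strands, sorted and capped."""
    tag = check_dna(tag, allow_n=False)
    if len(tag) < index.k:
        raise ValueError(f"tag shorter than seed length k={index.k}")
    hits = [
        GenomeHit(contig, pos, pos + len(tag), "+")
        for contig, pos in index.occurrences(tag)
    ]
    rc = revcomp(tag)
    hits += [
        GenomeHit(contig, pos, pos + len(tag), "-")
        for contig, pos in index.occurrences(rc)
    ]
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    overflow = len(hits) > max_hits
    return MapResult(hits[:max_hits], overflow)


def hit_sequence(index: GenomeIndex, hit: GenomeHit) -> str:
    """Genomic sequence of a hit in tag orientation."""
    s = index.slice(hit.contig, hit.start, hit.end)
    return revcomp(s) if hit.strand == "-" else s


def mapping_summary(
    table: TagTable, index: GenomeIndex, max_hits: int = DEFAULT_MAX_HITS
) -> dict[str, float]:
    """Per-library fraction of (present) tags with at least one genome hit."""
    mapped: dict[str, bool] = {}
    for tag in table.tags:
        mapped[tag] = len(map_tag(index, tag, max_hits).hits) > 0
    out = {}
    for lib in table.libraries:
        present = table.counts.index[table.counts[lib] > 0]
        if len(present) == 0:
            out[lib] = 0.0
        else:
            out[lib] = sum(mapped[t] for t in present) / len(present)
    return out


def map_table(
    table: TagTable, index: GenomeIndex, max_hits: int = DEFAULT_MAX_HITS
) -> dict[str, MapResult]:
    return {tag: map_tag(index, tag, max_hits) for tag in table.tags}


def write_gff3(hits: Mapping[str, MapResult] | Iterable[tuple[str, MapResult]], path: str | Path) -> None:
    """Write hits as GFF3 ``match`` features (1-based inclusive coordinates)."""
    items = hits.items() if isinstance(hits, Mapping) else hits
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for tag, result in items:
            for h in result.hits:
                out.write(
                    f"{h.contig}\tflaxsrna\tmatch\t{h.start + 1}\t{h.end}\t.\t"
                    f"{h.strand}\t.\tName={tag}\n"
                )
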