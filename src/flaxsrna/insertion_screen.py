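"""Screening sRNA tags against an insertion sequence and its flanks.

The question: are any small RNAs transcribed from a genomic insertion (such
as the 5.7-kb LIS-1 element of small flax genotrophs)?  Tags at or above the
abundance threshold are matched exactly (both strands) against the insertion
and its 5'/3' flanking sequences.  A match only indicates derivation from
the insertion if the tag is absent from every library of plants lacking the
insertion — a tag present at similar abundance in insertion-free libraries
must come from elsewhere in the genome.  Surviving candidates are finally
folded in context: without a stem-loop precursor there is no miRNA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import hairpin
from .read_processing import DEFAULT_MIN_COUNT, TagTable
from .seq import revcomp

REGIONS = ("insertion", "flank5", "flank3")


@dataclass
class InsertionMatch:
    tag: str
    region: str
    start: int  # 0-based within region sequence
    end: int
    strand: str
    counts: dict[str, int]
    unique_to_insertion_libraries: bool | None = None
    hairpin_passed: bool | None = None


def screen_insertion(
    table: TagTable,
    regions: Mapping[str, str],
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[InsertionMatch]:
    """Exact-substring matches (both strands) of abundant tags in each region.

    ``regions`` maps region labels (``insertion``, ``flank5``, ``flank3``)
    to their sequences.  Tags must reach ``min_count`` in at least one
    library to be considered.
    """
    for label, seq in regions.items():
        if label not in REGIONS:
            raise ValueError(f"unknown region label {label!r}")
        if not seq:
            raise ValueError(f"region {label!r} is empty")
    matches = []
    for tag in table.tags:
        counts = {lib: int(table.counts.at[tag, lib]) for lib in table.libraries}
        if max(counts.values()) < min_count:
            continue
        for label in REGIONS:
            seq = regions.get(label)
            if not seq:
                continue
            for query, strand in ((tag, "+"), (revcomp(tag), "-")):
                pos = seq.find(query)
                if pos != -1:
                    matches.append(
                        InsertionMatch(
                            tag=tag,
                            region=label,
                            start=pos,
                            end=pos + len(tag),
                            strand=strand,
                            counts=counts,
                        )
                    )
                    break  # one match record per (tag, region)
    return matches


def exclude_shared(
    matches: list[InsertionMatch],
    present_libs: list[str],
    absent_libs: list[str],
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[InsertionMatch]:
    """Cross-library exclusion: keep matches unique to insertion-carrying libraries.

    A candidate survives when it reaches the abundance threshold in at least
    one insertion-present library and stays below it in every
    insertion-absent library; a tag found at similar abundance in libraries
    without the insertion cannot derive from it.
    """
    if not present_libs or not absent_libs:
        raise ValueError("both library partitions must be non-empty")
    if set(present_libs) & set(absent_libs):
        raise ValueError("library partitions overlap")
    out = []
    for m in matches:
        in_present = any(m.counts.get(lib, 0) >= min_count for lib in present_libs)
        in_absent = any(m.counts.get(lib, 0) >= min_count for lib in absent_libs)
        m.unique_to_insertion_libraries = in_present and not in_absent
        if m.unique_to_insertion_libraries:
            out.append(m)
    return out


def verdict_hairpin(
    candidates: list[InsertionMatch],
    regions: Mapping[str, str],
    flank: int = hairpin.DEFAULT_FLANK,
    proximal: int = hairpin.PROXIMAL_FLANK,
    min_paired_fraction: float = hairpin.DEFAULT_MIN_PAIRED_FRACTION,
    max_unpaired_run: int = hairpin.DEFAULT_MAX_UNPAIRED_RUN,
    min_window_pairs: int = hairpin.DEFAULT_MIN_WINDOW_PAIRS,
) -> bool:
    """Fold windows around each candidate; True iff any forms a precursor.

    Mirrors novel-miRNA window excision on the region sequence itself.  The
    overall verdict answers "was any insertion-derived miRNA found?".
    """
    any_passed = False
    for m in candidates:
        seq = regions[m.region]
        passed = False
        for lo_flank, hi_flank in ((proximal, flank), (flank, proximal)):
            start = max(0, m.start - lo_flank)
            end = min(len(seq), m.end + hi_flank)
            win = seq[start:end]
            ms, me = m.start - start, m.end - start
            if m.strand == "-":
                win = revcomp(win)
                ms, me = len(win) - me, len(win) - ms
            cand = hairpin.evaluate_precursor(
                win,
                (ms, me),
                min_paired_fraction,
                max_unpaired_run,
                min_window_pairs,
            )
            if cand.passed:
                passed = True
                break
        m.hairpin_passed = passed
        any_passed = any_passed or passed
    return any_passed


def matches_to_tsv(matches: list[InsertionMatch], path: str | Path) -> None:
    rows = []
    for m in matches:
        row = {
            "tag": m.tag,
            "region": m.region,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
            "unique_to_insertion_libraries": m.unique_to_insertion_libraries,
            "hairpin_passed": m.hairpin_passed,
        }
        row.update(m.counts)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_verdict_json(
    candidates: list[InsertionMatch], overall: bool, path: str | Path
) -> None:
    payload = {
        "insertion_derived_mirna_found": overall,
        "n_unique_candidates": len(candidates),
        "candidates": [
            {"tag": m.tag, "region": m.region, "hairpin_passed": m.hairpin_passed}
            for m in candidates
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
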