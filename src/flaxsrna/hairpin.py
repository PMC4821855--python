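"""Novel miRNA discovery: window excision, folding, stem-loop criteria.

Candidate precursor windows are excised around genome hits of unannotated
tags and folded by nested base-pair maximization (Watson-Crick plus G:U,
minimum hairpin loop of three unpaired bases).  Among the many structures
attaining the maximal pair count the traceback prefers stacked (helical)
pairs and then the 5'-most pairing, so outputs are bit-stable and planted
stems are recovered rather than an arbitrary co-optimal scatter.

The precursor criteria judge the mature tag against the *dominant partner
block* of the folded window: the compact region (star arm) receiving the
most mature pairing partners.  A candidate passes when that block is
one-sided and loop-free with respect to the mature, the mature is mostly
paired into it, no long unpaired run interrupts it, and the window forms a
substantial number of pairs overall.

Coordinates are 0-based half-open throughout; GFF3 output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_map import GenomeHit, GenomeIndex, MapResult
from .seq import check_dna, revcomp

MIN_LOOP = 3
DEFAULT_FLANK = 150
PROXIMAL_FLANK = 15

# precursor pass thresholds (explicit, configurable stand-ins for the
# "typical stem-loop structure" judgement)
DEFAULT_MIN_PAIRED_FRACTION = 0.60
DEFAULT_MAX_UNPAIRED_RUN = 4
DEFAULT_MIN_WINDOW_PAIRS = 15
STAR_BLOCK_SLACK = 4  # extra width allowed for the star arm (bulges)

_PAIRABLE = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PAIR_MATRIX = np.zeros((4, 4), dtype=bool)
for _a, _b in _PAIRABLE:
    _PAIR_MATRIX[_BASE_CODE[_a], _BASE_CODE[_b]] = True

_NEG = -(10**12)
_PAIR_WEIGHT = 1024  # pair count dominates; stacking is the tie-break


@dataclass
class FoldResult:
    sequence: str
    structure: str
    pairs: list[tuple[int, int]]

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    def partner(self) -> list[int]:
        """Partner index per position, -1 for unpaired."""
        p = [-1] * len(self.sequence)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p


def fold_bpmax(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Maximum nested base pairing (AU, GC, GU) with loops >= ``min_loop``.

    The pair count is the exact maximum over all nested structures.  Ties
    are resolved deterministically, preferring stacked pairs (contiguous
    helices) and then the 5'-most pairing with the smallest partner index.
    """
    seq = check_dna(sequence, allow_n=False)
    n = len(seq)
    code = np.fromiter((_BASE_CODE[c] for c in seq), dtype=np.int8, count=n)
    can_pair = _PAIR_MATRIX[code[:, None], code[None, :]]
    # C[i, j]: best score of seq[i..j] with (i, j) paired; M[i, j]: best
    # score of the free interval.  Rows padded so M[j+1, j] == 0.
    C = np.full((n + 2, n + 1), _NEG, dtype=np.int64)
    M = np.zeros((n + 2, n + 1), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can_pair[i, j]:
                inner = M[i + 1, j - 1]
                if C[i + 1, j - 1] > _NEG // 2:
                    inner = max(inner, C[i + 1, j - 1] + 1)  # +1 stack bonus
                C[i, j] = _PAIR_WEIGHT + inner
            ks = np.arange(i + min_loop + 1, j + 1)
            M[i, j] = max(M[i + 1, j], (C[i, ks] + M[ks + 1, j]).max(initial=_NEG))

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("M", 0, n - 1)] if n > min_loop + 1 else []
    while stack:
        kind, i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if kind == "M":
            paired_here = False
            for k in range(i + min_loop + 1, j + 1):
                if C[i, k] > _NEG // 2 and C[i, k] + M[k + 1, j] == M[i, j]:
                    pairs.append((i, k))
                    stack.append(("M", k + 1, j))
                    stack.append(("C", i, k))
                    paired_here = True
                    break
            if not paired_here:
                stack.append(("M", i + 1, j))
        else:  # (i, j) is paired; decompose the interior
            stacked = C[i + 1, j - 1] + 1 if C[i + 1, j - 1] > _NEG // 2 else _NEG
            if stacked == C[i, j] - _PAIR_WEIGHT and stacked >= M[i + 1, j - 1]:
                pairs.append((i + 1, j - 1))
                stack.append(("C", i + 1, j - 1))
            else:
                stack.append(("M", i + 1, j - 1))
    pairs.sort()
    structure = ["."] * n
    for a, b in pairs:
        structure[a], structure[b] = "(", ")"
    return FoldResult(sequence=seq, structure="".join(structure), pairs=pairs)


@dataclass
class Window:
    """An excised candidate window with the mature tag located inside it."""

    hit: GenomeHit
    sequence: str
    mature_start: int
    mature_end: int
    genome_start: int
    genome_end: int


def excise_windows(
    index: GenomeIndex,
    hit: GenomeHit,
    flank: int = DEFAULT_FLANK,
    proximal: int = PROXIMAL_FLANK,
) -> list[Window]:
    """Two candidate windows around a hit: distal flank 3' or 5' of the tag.

    Windows are clamped to contig bounds; minus-strand windows are
    reverse-complemented so the mature sequence appears verbatim.
    """
    contig_len = len(index.contigs[hit.contig])
    windows = []
    for lo_flank, hi_flank in ((proximal, flank), (flank, proximal)):
        start = max(0, hit.start - lo_flank)
        end = min(contig_len, hit.end + hi_flank)
        seq = index.slice(hit.contig, start, end)
        m0, m1 = hit.start - start, hit.end - start
        if hit.strand == "-":
            seq = revcomp(seq)
            m0, m1 = len(seq) - m1, len(seq) - m0
        windows.append(
            Window(
                hit=hit,
                sequence=seq,
                mature_start=m0,
                mature_end=m1,
                genome_start=start,
                genome_end=end,
            )
        )
    # deduplicate fully-clamped identical windows
    uniq: list[Window] = []
    for w in windows:
        if not any(w.sequence == u.sequence and w.mature_start == u.mature_start for u in uniq):
            uniq.append(w)
    return uniq


@dataclass
class HairpinCandidate:
    window: Window | None
    sequence: str
    structure: str
    mature_start: int
    mature_end: int
    arm: str | None
    mature_paired_fraction: float
    max_consecutive_unpaired: int
    pair_count: int
    loop_spans: list[tuple[int, int]] = field(default_factory=list)
    passed: bool = False


def _hairpin_loops(fold: FoldResult) -> list[tuple[int, int]]:
    """Hairpin-loop spans: unpaired stretches directly closed by a pair."""
    partner = fold.partner()
    return [
        (i + 1, j)
        for i, j in fold.pairs
        if all(partner[k] == -1 for k in range(i + 1, j))
    ]


def _dominant_block(
    ext_pairs: list[tuple[int, int]], mature_len: int, slack: int
) -> set[int]:
    """Mature positions whose partner falls in the best compact star block.

    The block is a window of width ``mature_len + slack`` over partner
    positions holding the largest number of mature partners.
    """
    best: set[int] = set()
    width = mature_len + slack
    for lo in sorted(p for _, p in ext_pairs):
        members = {k for k, p in ext_pairs if lo <= p < lo + width}
        if len(members) > len(best):
            best = members
    return best


def evaluate_precursor(
    window_seq: str,
    mature_span: tuple[int, int],
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION,
    max_unpaired_run: int = DEFAULT_MAX_UNPAIRED_RUN,
    min_window_pairs: int = DEFAULT_MIN_WINDOW_PAIRS,
    min_loop: int = MIN_LOOP,
    window: Window | None = None,
) -> HairpinCandidate:
    """Fold a window and apply the stem-loop precursor criteria.

    Pass requires: (a) the mature lies on one arm — its dominant partner
    block sits entirely on one side and the mature overlaps no hairpin
    loop; (b) the fraction of mature bases paired into that block is >=
    ``min_paired_fraction``; (c) the longest mature stretch not paired into
    the block is <= ``max_unpaired_run``; (d) the window forms >=
    ``min_window_pairs`` base pairs in total.
    """
    ms, me = mature_span
    if not (0 <= ms < me <= len(window_seq)):
        raise ValueError("mature span outside window")
    fold = fold_bpmax(window_seq, min_loop)
    partner = fold.partner()
    loops = _hairpin_loops(fold)

    ext_pairs = [
        (k, partner[k])
        for k in range(ms, me)
        if partner[k] != -1 and not (ms <= partner[k] < me)
    ]
    block = _dominant_block(ext_pairs, me - ms, STAR_BLOCK_SLACK)
    block_partners = [p for k, p in ext_pairs if k in block]
    one_sided = bool(block_partners) and (
        all(p >= me for p in block_partners) or all(p < ms for p in block_partners)
    )
    loop_overlap = any(lo < me and ms < hi for lo, hi in loops)
    one_arm = one_sided and not loop_overlap
    arm = None
    if one_arm:
        arm = "5p" if block_partners[0] >= me else "3p"

    paired_fraction = len(block) / (me - ms)
    run = best_run = 0
    for k in range(ms, me):
        run = run + 1 if k not in block else 0
        best_run = max(best_run, run)

    passed = (
        one_arm
        and paired_fraction >= min_paired_fraction
        and best_run <= max_unpaired_run
        and fold.pair_count >= min_window_pairs
    )
    return HairpinCandidate(
        window=window,
        sequence=fold.sequence,
        structure=fold.structure,
        mature_start=ms,
        mature_end=me,
        arm=arm,
        mature_paired_fraction=paired_fraction,
        max_consecutive_unpaired=best_run,
        pair_count=fold.pair_count,
        loop_spans=loops,
        passed=passed,
    )


def discover_novel(
    tags: list[str],
    hits_by_tag: dict[str, MapResult],
    index: GenomeIndex,
    flank: int = DEFAULT_FLANK,
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION,
    max_unpaired_run: int = DEFAULT_MAX_UNPAIRED_RUN,
    min_window_pairs: int = DEFAULT_MIN_WINDOW_PAIRS,
) -> dict[str, HairpinCandidate]:
    """Evaluate all windows of all hits per tag; report tags with a pass.

    The best passing candidate is chosen by highest mature paired fraction,
    ties broken by smallest genomic window start.
    """
    out: dict[str, HairpinCandidate] = {}
    for tag in tags:
        best: HairpinCandidate | None = None
        for hit in hits_by_tag[tag].hits:
            for w in excise_windows(index, hit, flank):
                cand = evaluate_precursor(
                    w.sequence,
                    (w.mature_start, w.mature_end),
                    min_paired_fraction,
                    max_unpaired_run,
                    min_window_pairs,
                    window=w,
                )
                if not cand.passed:
                    continue
                if (
                    best is None
                    or cand.mature_paired_fraction > best.mature_paired_fraction
                    or (
                        cand.mature_paired_fraction == best.mature_paired_fraction
                        and cand.window.genome_start < best.window.genome_start
                    )
                ):
                    best = cand
        if best is not None:
            out[tag] = best
    return out


def candidates_to_tsv(candidates: dict[str, HairpinCandidate], path: str | Path) -> None:
    rows = []
    for tag, c in candidates.items():
        rows.append(
            {
                "tag": tag,
                "contig": c.window.hit.contig if c.window else "",
                "window_start": c.window.genome_start if c.window else -1,
                "window_end": c.window.genome_end if c.window else -1,
                "strand": c.window.hit.strand if c.window else ".",
                "arm": c.arm or ".",
                "mature_paired_fraction": round(c.mature_paired_fraction, 4),
                "max_consecutive_unpaired": c.max_consecutive_unpaired,
                "pair_count": c.pair_count,
                "structure": c.structure,
                "precursor": c.sequence,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_precursor_gff3(candidates: dict[str, HairpinCandidate], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for tag, c in candidates.items():
            if c.window is None:
                continue
            out.write(
                f"{c.window.hit.contig}\tflaxsrna\tpre_miRNA\t"
                f"{c.window.genome_start + 1}\t{c.window.genome_end}\t.\t"
                f"{c.window.hit.strand}\t.\tName={tag}\n"
            )
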