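"""Tag annotation: conserved miRNA homology, non-coding classes, summaries.

Tags are classified against two databases: a mature-miRNA set (miRBase/PMRD
style, ungapped homology with up to two mismatches) and a labelled
non-coding-RNA set (Rfam style, exact substring containment).  Because
known non-miRNA sRNAs are filtered out before miRNA calling, exact
non-coding containment takes precedence over a conserved match with
mismatches; a perfect conserved match wins over everything.

Also provides a minimal miRNA-target complementarity scorer (seed-weighted
mismatch/wobble/indel penalties) used for target-prediction plumbing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .read_processing import DEFAULT_MIN_COUNT, TagTable
from .seq import check_dna, normalize, revcomp

CATEGORIES = (
    "conserved_miRNA",
    "rRNA5S",
    "tRNA",
    "snoRNA",
    "other_known_sRNA",
    "unannotated",
)
NONCODING_CLASSES = ("rRNA5S", "tRNA", "snoRNA", "other_known_sRNA")

DEFAULT_MAX_MISMATCH = 2
MIN_HOMOLOGY_OVERLAP = 18
MAX_HOMOLOGY_LENGTH_DIFF = 2

# miRNA families conventionally reported merged
_FAMILY_SYNONYMS = {
    "miR165": "miR165/166",
    "miR166": "miR165/166",
    "miR156": "miR156/157",
    "miR157": "miR156/157",
    "miR170": "miR170/171",
    "miR171": "miR170/171",
}


@dataclass
class AnnotationRecord:
    tag: str
    category: str
    family: str | None = None
    db_id: str | None = None
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "conserved_miRNA") != bool(self.family):
            raise ValueError("family set iff category is conserved_miRNA")


def family_from_id(db_id: str) -> str:
    """Extract the miRNA family from a database identifier.

    ``lus-miR166a`` -> ``miR165/166`` (synonymous families merged).
    """
    m = re.search(r"miR-?(N?[0-9]+)", db_id, flags=re.IGNORECASE)
    if not m:
        raise ValueError(f"cannot parse miRNA family from {db_id!r}")
    fam = f"miR{m.group(1)}"
    return _FAMILY_SYNONYMS.get(fam, fam)


def load_mature_db(path: str | Path) -> list[tuple[str, str]]:
    """Mature miRNA FASTA as ordered (id, DNA sequence) pairs."""
    db = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize(str(rec.seq))
        if not seq:
            raise ValueError(f"malformed mature database record {rec.id!r}: empty")
        db.append((rec.id, seq))
    return db


def load_ncrna_db(path: str | Path) -> list[tuple[str, str, str]]:
    """Non-coding RNA FASTA with ``class=<label>`` in the description.

    Returns ordered (id, class, DNA sequence) triples.
    """
    db = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"class=(\S+)", rec.description)
        if not m or m.group(1) not in NONCODING_CLASSES:
            raise ValueError(
                f"ncRNA record {rec.id!r} lacks a valid class= token "
                f"(expected one of {NONCODING_CLASSES})"
            )
        db.append((rec.id, m.group(1), normalize(str(rec.seq))))
    return db


def _min_hamming(tag: str, mature: str) -> int | None:
    """Minimum mismatches over all ungapped offsets with overlap >= 18 nt.

    Returns ``None`` when no offset yields a sufficient overlap or the
    length difference exceeds the homology guard.
    """
    if abs(len(tag) - len(mature)) > MAX_HOMOLOGY_LENGTH_DIFF:
        return None
    best: int | None = None
    # offset = start of mature relative to start of tag
    for off in range(-len(mature) + 1, len(tag)):
        lo = max(0, off)
        hi = min(len(tag), off + len(mature))
        if hi - lo < MIN_HOMOLOGY_OVERLAP:
            continue
        mm = sum(tag[i] != mature[i - off] for i in range(lo, hi))
        if best is None or mm < best:
            best = mm
    return best


def match_conserved(
    tag: str,
    mature_db: list[tuple[str, str]],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> AnnotationRecord | None:
    """Best ungapped homology match of a tag against the mature database.

    Ties on mismatch count are broken by database order.
    """
    tag = check_dna(tag, allow_n=False)
    best: tuple[int, str] | None = None
    for db_id, mature in mature_db:
        mm = _min_hamming(tag, mature)
        if mm is not None and mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, db_id)
    if best is None:
        return None
    mm, db_id = best
    return AnnotationRecord(
        tag=tag,
        category="conserved_miRNA",
        family=family_from_id(db_id),
        db_id=db_id,
        mismatches=mm,
    )


def classify_noncoding(tag: str, ncrna_db: list[tuple[str, str, str]]) -> str | None:
    """Class of the first database record containing the tag (either strand)."""
    tag = check_dna(tag, allow_n=False)
    rc = revcomp(tag)
    for _, cls, seq in ncrna_db:
        if tag in seq or rc in seq:
            return cls
    return None


def annotate_tag(
    tag: str,
    mature_db: list[tuple[str, str]],
    ncrna_db: list[tuple[str, str, str]],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> AnnotationRecord:
    """Single-tag classification with the documented precedence.

    Perfect conserved match > non-coding containment > conserved match with
    mismatches > unannotated.
    """
    conserved = match_conserved(tag, mature_db, max_mismatch)
    if conserved is not None and conserved.mismatches == 0:
        return conserved
    nc = classify_noncoding(tag, ncrna_db)
    if nc is not None:
        return AnnotationRecord(tag=tag, category=nc)
    if conserved is not None:
        return conserved
    return AnnotationRecord(tag=tag, category="unannotated")


def annotate_table(
    table: TagTable,
    mature_db: list[tuple[str, str]],
    ncrna_db: list[tuple[str, str, str]],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> pd.DataFrame:
    """Annotate every tag; returns a DataFrame indexed by tag."""
    rows = []
    for tag in table.tags:
        rec = annotate_tag(tag, mature_db, ncrna_db, max_mismatch)
        rows.append(
            {
                "tag": rec.tag,
                "category": rec.category,
                "family": rec.family,
                "db_id": rec.db_id,
                "mismatches": rec.mismatches,
            }
        )
    return pd.DataFrame(rows).set_index("tag")


def percentage(count: int, total: int) -> float:
    """Half-up percentage with 2 decimals, as printed in annotation tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_annotation(
    table: TagTable,
    annotations: pd.DataFrame,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Annotation summary: per-library category counts and percentages.

    The denominator for each library is the number of unique tags whose count
    in that library reaches the abundance threshold; percentages are half-up
    rounded to two decimals of that denominator.
    """
    rows: dict[str, dict[str, float | int]] = {}
    for lib in table.libraries:
        present = table.counts.index[table.counts[lib] >= min_count]
        total = len(present)
        if total == 0:
            raise ValueError(f"library {lib!r} has no tags at abundance >= {min_count}")
        cats = annotations.loc[annotations.index.intersection(present), "category"]
        rows[f"{lib}_count"] = {"total": total}
        rows[f"{lib}_pct"] = {"total": 100.0}
        for cat in CATEGORIES:
            n = int((cats == cat).sum())
            rows[f"{lib}_count"][cat] = n
            rows[f"{lib}_pct"][cat] = percentage(n, total)
    summary = pd.DataFrame(rows)
    summary.index.name = "category"
    return summary


# --- minimal miRNA-target complementarity scoring ------------------------

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
INDEL_PENALTY = 2.0
CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled penalties
DEFAULT_TARGET_CUTOFF = 3.0


@dataclass
class TargetScore:
    penalty: float
    mismatches: list[int]
    wobbles: list[int]
    indels: list[int]

    @property
    def perfect(self) -> bool:
        return self.penalty == 0.0


def _core_weight(mirna_pos_1based: int) -> float:
    return 2.0 if CORE_START <= mirna_pos_1based <= CORE_END else 1.0


def score_target(mirna: str, site: str) -> TargetScore:
    """Complementarity penalty between a miRNA and a candidate target site.

    The site (mRNA, 5'->3') is reverse-complemented and globally aligned to
    the miRNA; identity is a perfect pair, G:U wobbles cost 0.5, mismatches
    1.0, indels 2.0, all doubled within miRNA positions 2-13 (the core).
    Lower is better; 0 means perfect complementarity.
    """
    if not mirna or not site:
        raise ValueError("empty miRNA or site sequence")
    m = check_dna(mirna, allow_n=False)
    t = revcomp(check_dna(site, allow_n=False))
    n, k = len(m), len(t)
    # wobble in duplex space maps to (G,A) or (T,C) in (miRNA, revcomp-site)
    wobble = {("G", "A"), ("T", "C")}
    INF = float("inf")
    dp = [[INF] * (k + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for i in range(1, n + 1):
        dp[i][0] = dp[i - 1][0] + INDEL_PENALTY * _core_weight(i)
    for j in range(1, k + 1):
        dp[0][j] = dp[0][j - 1] + INDEL_PENALTY * _core_weight(1)
    for i in range(1, n + 1):
        w = _core_weight(i)
        for j in range(1, k + 1):
            if m[i - 1] == t[j - 1]:
                sub = 0.0
            elif (m[i - 1], t[j - 1]) in wobble:
                sub = WOBBLE_PENALTY * w
            else:
                sub = MISMATCH_PENALTY * w
            dp[i][j] = min(
                dp[i - 1][j - 1] + sub,
                dp[i - 1][j] + INDEL_PENALTY * w,
                dp[i][j - 1] + INDEL_PENALTY * w,
            )
    # traceback for event positions (1-based miRNA coordinates)
    mismatches: list[int] = []
    wobbles: list[int] = []
    indels: list[int] = []
    i, j = n, k
    while i > 0 or j > 0:
        w = _core_weight(max(i, 1))
        if i > 0 and j > 0:
            if m[i - 1] == t[j - 1]:
                sub = 0.0
            elif (m[i - 1], t[j - 1]) in wobble:
                sub = WOBBLE_PENALTY * w
            else:
                sub = MISMATCH_PENALTY * w
            if dp[i][j] == dp[i - 1][j - 1] + sub:
                if sub and (m[i - 1], t[j - 1]) in wobble:
                    wobbles.append(i)
                elif sub:
                    mismatches.append(i)
                i, j = i - 1, j - 1
                continue
        if i > 0 and dp[i][j] == dp[i - 1][j] + INDEL_PENALTY * w:
            indels.append(i)
            i -= 1
            continue
        indels.append(max(i, 1))
        j -= 1
    return TargetScore(
        penalty=dp[n][k],
        mismatches=sorted(mismatches),
        wobbles=sorted(wobbles),
        indels=sorted(indels),
    )
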