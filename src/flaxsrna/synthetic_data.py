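"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate a three-library plant small-RNA experiment (normal
N, phosphate-deficient P, nutrient-excess NPK) at desk scale: collapsed tag
libraries with planted conserved miRNAs, planted stem-loop precursors for
novel miRNAs, a planted insertion locus with library-restricted tags, a
21/24-nt length structure, and qPCR Ct matrices with per-transcript
amplification efficiencies, per-condition expression effects and Gaussian
noise.  Every planted element is recorded in a :class:`SyntheticTruth` that
round-trips through JSON, so recovery tests compare pipeline output against
generator bookkeeping.

Planted elements are *verified during generation*: novel precursor loci are
redrawn until they pass the precursor criteria in their final sequence
context, decoy (non-hairpin) loci until they fail in both windows, and
unmappable tags until they genuinely do not occur in the genome.  A planted
label therefore always matches the structural truth of the emitted
sequence, for any seed.

All randomness flows from one master seed through named child seeds, so
fixtures are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate, hairpin
from .seq import revcomp

READ_LENGTH = 40
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
DEFAULT_GENOME_LENGTH = 40_000
DEFAULT_GC = 0.5
# library depths scaled ~1/160 from the 7.2/11.6/7.6 M raw reads of the
# emulated experiment, preserving their ratios
DEFAULT_DEPTHS = {"N": 45_000, "P": 72_000, "NPK": 48_000}
DEFAULT_QPCR_N = {"N": 14, "P": 12, "NPK": 7}
DEFAULT_REPLICATE_SD = 0.15
DEFAULT_SAMPLE_SHIFT_SD = 0.5


def child_seed(master_seed: int, label: str) -> int:
    """Deterministic child seed derived from the master seed and a label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, label))


def random_seq(rng: np.random.Generator, length: int, gc: float = DEFAULT_GC) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_hairpin_precursor(
    mature: str,
    loop_length: int,
    star_mutations: int,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, int]]:
    """Mature + loop + (mutated) star; returns (precursor, mature span).

    The star is the reverse complement of the mature with
    ``star_mutations`` random substitutions; with at most three mutations
    on a 19-24 nt mature the construct satisfies the precursor criteria.
    Substitutions avoid the terminal star positions so that the folded
    construct pairs exactly ``len(mature) - star_mutations`` mature bases
    (a terminal break could re-pair into the loop).
    """
    if not 19 <= len(mature) <= 24:
        raise ValueError("mature must be 19-24 nt")
    if loop_length < hairpin.MIN_LOOP:
        raise ValueError(f"loop must be >= {hairpin.MIN_LOOP} nt")
    star = list(revcomp(mature))
    interior = np.arange(1, len(star) - 1)
    pairable = {"A": "T", "C": "G", "G": "CT", "T": "AG"}  # incl. G:U wobble
    # well-separated positions: freed bases cannot re-pair without crossing
    # an intact stem pair, so exactly star_mutations mature bases unpair
    while True:
        positions = rng.choice(interior, size=star_mutations, replace=False)
        if star_mutations < 2 or np.diff(np.sort(positions)).min() >= 3:
            break
    for pos in positions:
        partner = mature[len(mature) - 1 - pos]
        alternatives = [
            b for b in "ACGT" if b != star[pos] and b not in pairable[partner]
        ]
        star[pos] = alternatives[rng.integers(len(alternatives))]
    loop = random_seq(rng, loop_length)
    return mature + loop + "".join(star), (0, len(mature))


def make_genome(
    rng: np.random.Generator,
    length: int,
    planted: Sequence[tuple[str, str]],
    gc: float = DEFAULT_GC,
    margin: int = 40,
    contig: str = "chr1",
) -> tuple[dict[str, str], dict[str, tuple[int, int, str]]]:
    """I.i.d. background genome with planted elements at recorded coordinates.

    Each element is inserted on a random strand (reverse-complemented for
    ``-``) at a non-overlapping position at least ``margin`` from other
    elements and the contig ends.  Returns ({contig: sequence},
    {name: (start, end, strand)}).
    """
    total = sum(len(s) for _, s in planted) + margin * (len(planted) + 1)
    if total > length:
        raise ValueError("planted elements exceed genome length")
    background = list(random_seq(rng, length, gc))
    coords: dict[str, tuple[int, int, str]] = {}
    occupied: list[tuple[int, int]] = []
    for name, seq in planted:
        for _ in range(10_000):
            start = int(rng.integers(margin, length - len(seq) - margin))
            span = (start - margin, start + len(seq) + margin)
            if all(span[1] <= lo or span[0] >= hi for lo, hi in occupied):
                break
        else:
            raise RuntimeError("could not place planted elements")
        strand = "+" if rng.random() < 0.5 else "-"
        insert = seq if strand == "+" else revcomp(seq)
        background[start : start + len(seq)] = list(insert)
        occupied.append(span)
        coords[name] = (start, start + len(seq), strand)
    return {contig: "".join(background)}, coords


def sample_library(
    profile: Mapping[str, float],
    depth: int,
    adapter: str,
    rng: np.random.Generator,
    genome: str | None = None,
    library: str = "lib",
    read_length: int = READ_LENGTH,
) -> list[tuple[str, str]]:
    """Multinomial read sampling from an RPM profile; remainder is background.

    ``profile`` maps insert sequences to expected RPM (sum <= 1e6); the
    remaining probability mass produces background reads from random
    genome positions (random strand, lengths 20-24 nt).  Returns (id,
    read sequence) pairs, where each read is insert + adapter truncated to
    ``read_length``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    units = sorted(profile)
    probs = np.array([profile[u] / 1e6 for u in units])
    if probs.sum() > 1 + 1e-9:
        raise ValueError("profile RPM sums above 1e6")
    background_p = max(0.0, 1.0 - probs.sum())
    if background_p > 0 and genome is None:
        raise ValueError("background mass requires a genome")
    counts = rng.multinomial(depth, np.append(probs, background_p))
    reads: list[tuple[str, str]] = []
    serial = 0
    for unit, n in zip(units, counts[: len(units)]):
        for _ in range(n):
            serial += 1
            reads.append((f"{library}_{serial}", (unit + adapter)[:read_length]))
    for _ in range(counts[-1]):
        serial += 1
        length = int(rng.integers(20, 25))
        pos = int(rng.integers(0, len(genome) - length))
        insert = genome[pos : pos + length]
        if rng.random() < 0.5:
            insert = revcomp(insert)
        reads.append((f"{library}_{serial}", (insert + adapter)[:read_length]))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, seq in reads:
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n{seq}\n")


# --- qPCR ----------------------------------------------------------------


@dataclass
class TranscriptDesign:
    """Generative parameters for one qPCR amplicon."""

    name: str
    efficiency: float
    baseline_ct: float
    condition_effects: dict[str, float] = field(default_factory=dict)  # log2 units
    sample_sd: float = 0.1  # per-sample biological noise, Ct cycles

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1.2:
            raise ValueError("efficiency must be in (0, 1.2]")


def default_qpcr_design() -> list[TranscriptDesign]:
    """The default amplicon panel: stable references, unstable candidate
    references, and two differentially expressed miRNA targets with their
    anti-correlated predicted target mRNAs."""
    return [
        TranscriptDesign("ETIF3E", 1.00, 21.0, {}, 0.08),
        TranscriptDesign("ETIF3H", 1.00, 22.0, {}, 0.08),
        TranscriptDesign("GAPDH", 0.99, 20.0, {}, 0.40),
        TranscriptDesign("EF1A", 0.98, 19.0, {}, 0.30),
        TranscriptDesign("lus-miR-N3", 0.97, 27.0, {}, 0.50),
        TranscriptDesign("lus-miR-N12", 0.97, 28.0, {}, 0.55),
        TranscriptDesign("lus-miR-N306", 0.96, 29.0, {}, 0.60),
        TranscriptDesign("miR399", 0.97, 24.0, {"P": 1.4}, 0.10),
        TranscriptDesign("lus-miR-N1", 0.96, 26.0, {"P": -1.7, "NPK": -0.3}, 0.10),
        TranscriptDesign("E2", 0.98, 25.0, {"P": -1.2}, 0.10),
        TranscriptDesign("E1", 0.98, 25.5, {"P": 1.2}, 0.10),
    ]


def make_qpcr_dataset(
    design: Sequence[TranscriptDesign],
    n_per_condition: Mapping[str, int],
    replicate_sd: float,
    rng: np.random.Generator,
    n_replicates: int = 3,
    sample_shift_sd: float = DEFAULT_SAMPLE_SHIFT_SD,
) -> pd.DataFrame:
    """Simulated long-format Ct table.

    Generative model per sample s of condition c and transcript t:

        Ct = baseline_t - effect_t(c) / log2(1 + E_t) + shift_s
             + biological noise + replicate noise

    where ``shift_s`` is a per-sample global Ct offset (pipetting / input
    amount) that reference-based normalization must cancel, and the
    condition effect is expressed in log2 quantity units so the planted
    ddCteff of a target against zero-effect references equals the effect.
    """
    for n in n_per_condition.values():
        if n < 2:
            raise ValueError("need at least 2 samples per condition")
    rows = []
    for cond in sorted(n_per_condition):
        for i in range(n_per_condition[cond]):
            sample = f"{cond}{i + 1:02d}"
            shift = rng.normal(0.0, sample_shift_sd)
            for t in design:
                effect = t.condition_effects.get(cond, 0.0)
                mean_ct = (
                    t.baseline_ct
                    - effect / np.log2(1 + t.efficiency)
                    + shift
                    + rng.normal(0.0, t.sample_sd)
                )
                reps = mean_ct + rng.normal(0.0, replicate_sd, size=n_replicates)
                row = {
                    "sample": sample,
                    "condition": cond,
                    "transcript": t.name,
                    "efficiency": t.efficiency,
                }
                for k, v in enumerate(reps, 1):
                    row[f"ct_rep{k}"] = round(float(v), 4)
                rows.append(row)
    return pd.DataFrame(rows)


# --- full fixture --------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Everything planted into a fixture, JSON-round-trippable."""

    seed: int
    conserved: dict[str, dict]  # tag -> {family, db_id}
    noncoding: dict[str, str]  # tag -> class
    novel: dict[str, dict]  # name -> {tag, precursor, start, end, strand}
    decoys: list[str]
    unmappable: list[str]
    insertion_unique: list[str]
    insertion_shared: list[str]
    flank3_shared: list[str]
    present_libs: list[str]
    absent_libs: list[str]
    profile: dict[str, dict[str, float]]  # library -> tag -> RPM
    depths: dict[str, int]
    adapter: str
    qpcr: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


_CONSERVED_IDS = [
    "lus-miR166a",
    "lus-miR165b",
    "lus-miR399",
    "lus-miR168",
    "lus-miR169",
    "lus-miR395",
    "lus-miR398",
    "lus-miR408",
]
_EXTRA_DB_IDS = ["ath-miR156a", "osa-miR172b", "ptc-miR319a", "vvi-miR396c"]


def _draw_distinct_tag(
    rng: np.random.Generator, existing: set[str], length: int = 21
) -> str:
    while True:
        tag = random_seq(rng, length)
        if tag not in existing:
            return tag


def _verified_novel_block(
    rng: np.random.Generator,
    mature_db: list[tuple[str, str]],
    existing: set[str],
    flank: int = hairpin.DEFAULT_FLANK,
    proximal: int = hairpin.PROXIMAL_FLANK,
) -> tuple[str, str, str]:
    """(tag, precursor, block) where the block passes the criteria in situ.

    The block is proximal-flank + precursor + distal padding, exactly the
    window the pipeline will excise around the planted tag, so passing here
    guarantees passing after genome placement on either strand.
    """
    for _ in range(200):
        tag = _draw_distinct_tag(rng, existing)
        if annotate.match_conserved(tag, mature_db) is not None:
            continue
        muts = int(rng.integers(0, 4))
        precursor, _ = make_hairpin_precursor(tag, 8, muts, rng)
        pad = flank - (len(precursor) - len(tag))
        block = random_seq(rng, proximal) + precursor + random_seq(rng, pad)
        cand = hairpin.evaluate_precursor(block, (proximal, proximal + len(tag)))
        if cand.passed:
            return tag, precursor, block
    raise RuntimeError("could not construct a passing novel precursor block")


def _verified_decoy_block(
    rng: np.random.Generator,
    mature_db: list[tuple[str, str]],
    existing: set[str],
    flank: int = hairpin.DEFAULT_FLANK,
    proximal: int = hairpin.PROXIMAL_FLANK,
) -> tuple[str, str]:
    """(tag, block) where both excision windows fail the criteria."""
    for _ in range(200):
        tag = _draw_distinct_tag(rng, existing)
        if annotate.match_conserved(tag, mature_db) is not None:
            continue
        block = random_seq(rng, flank) + tag + random_seq(rng, flank)
        ms = flank
        w1 = block[ms - proximal : ms + len(tag) + flank]
        w2 = block[ms - flank : ms + len(tag) + proximal]
        c1 = hairpin.evaluate_precursor(w1, (proximal, proximal + len(tag)))
        c2 = hairpin.evaluate_precursor(w2, (flank, flank + len(tag)))
        if not c1.passed and not c2.passed:
            return tag, block
    raise RuntimeError("could not construct a structure-negative decoy block")


def _verified_negative_region_tag(
    rng: np.random.Generator,
    region: str,
    existing: set[str],
) -> str:
    """A 21-nt substring of ``region`` whose context windows fail the criteria."""
    for _ in range(500):
        pos = int(rng.integers(0, len(region) - 21))
        tag = region[pos : pos + 21]
        if tag in existing or "N" in tag:
            continue
        negative = True
        for lo, hi in ((hairpin.PROXIMAL_FLANK, hairpin.DEFAULT_FLANK),
                       (hairpin.DEFAULT_FLANK, hairpin.PROXIMAL_FLANK)):
            start = max(0, pos - lo)
            end = min(len(region), pos + 21 + hi)
            cand = hairpin.evaluate_precursor(
                region[start:end], (pos - start, pos - start + 21)
            )
            if cand.passed:
                negative = False
                break
        if negative:
            return tag
    raise RuntimeError("could not find a structure-negative insertion tag")


def make_fixture(
    outdir: str | Path,
    seed: int,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    gc: float = DEFAULT_GC,
    depths: Mapping[str, int] | None = None,
    adapter: str = DEFAULT_ADAPTER,
    n_novel: int = 5,
    n_decoys: int = 6,
    qpcr_n: Mapping[str, int] | None = None,
    replicate_sd: float = DEFAULT_REPLICATE_SD,
) -> SyntheticTruth:
    """Emit a complete fixture directory and return its ground truth.

    Files: genome.fa, mature.fa, ncrna.fa, lis1.fa, flank5.fa, flank3.fa,
    {N,P,NPK}.fastq, ct.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    depths = dict(depths or DEFAULT_DEPTHS)
    qpcr_n = dict(qpcr_n or DEFAULT_QPCR_N)
    existing: set[str] = set()

    # conserved mature database: planted tags plus foreign entries
    rng_cons = child_rng(seed, "conserved")
    conserved: dict[str, dict] = {}
    mature_records = []
    for db_id in _CONSERVED_IDS:
        tag = _draw_distinct_tag(rng_cons, existing)
        existing.add(tag)
        conserved[tag] = {"family": annotate.family_from_id(db_id), "db_id": db_id}
        mature_records.append((db_id, tag))
    for db_id in _EXTRA_DB_IDS:
        extra = _draw_distinct_tag(rng_cons, existing)
        existing.add(extra)
        mature_records.append((db_id, extra))
    mature_db = list(mature_records)

    # non-coding database and planted non-miRNA sRNA tags
    rng_nc = child_rng(seed, "ncrna")
    nc_records = [
        ("rrn5S_1", "rRNA5S", random_seq(rng_nc, 119)),
        ("tRNA-Ala_1", "tRNA", random_seq(rng_nc, 76)),
        ("snoR14_1", "snoRNA", random_seq(rng_nc, 110)),
        ("srp_1", "other_known_sRNA", random_seq(rng_nc, 95)),
    ]
    noncoding: dict[str, str] = {}
    for _, cls, seq in nc_records:
        pos = int(rng_nc.integers(0, len(seq) - 21))
        tag = seq[pos : pos + 21]
        noncoding[tag] = cls
        existing.add(tag)

    # novel precursor loci and decoy loci, verified in context
    rng_novel = child_rng(seed, "novel")
    novel: dict[str, dict] = {}
    planted_elements: list[tuple[str, str]] = []
    for i in range(n_novel):
        tag, precursor, block = _verified_novel_block(rng_novel, mature_db, existing)
        existing.add(tag)
        novel[f"lus-miR-N{i + 1}"] = {"tag": tag, "precursor": precursor}
        planted_elements.append((f"novel_{i + 1}", block))
    rng_decoy = child_rng(seed, "decoys")
    decoys: list[str] = []
    for i in range(n_decoys):
        tag, block = _verified_decoy_block(rng_decoy, mature_db, existing)
        existing.add(tag)
        decoys.append(tag)
        planted_elements.append((f"decoy_{i + 1}", block))
    for tag in conserved:
        planted_elements.append((f"conserved_{conserved[tag]['db_id']}", tag))

    rng_genome = child_rng(seed, "genome")
    contigs, coords = make_genome(rng_genome, genome_length, planted_elements, gc)
    genome_seq = contigs["chr1"]
    for i, (name, info) in enumerate(novel.items()):
        start, end, strand = coords[f"novel_{i + 1}"]
        info.update({"contig": "chr1", "start": start, "end": end, "strand": strand})

    # unmappable tags: verified absent from the genome on both strands
    rng_unmap = child_rng(seed, "unmappable")
    unmappable: list[str] = []
    while len(unmappable) < 2:
        tag = _draw_distinct_tag(rng_unmap, existing)
        if tag in genome_seq or revcomp(tag) in genome_seq:
            continue
        existing.add(tag)
        unmappable.append(tag)

    # insertion element and its flanks (not part of the reference genome)
    rng_ins = child_rng(seed, "insertion")
    insertion = random_seq(rng_ins, 2000)
    flank5 = random_seq(rng_ins, 400)
    flank3 = random_seq(rng_ins, 400)
    insertion_unique = []
    for _ in range(3):
        tag = _verified_negative_region_tag(rng_ins, insertion, existing)
        existing.add(tag)
        insertion_unique.append(tag)
    insertion_shared: list[str] = []
    while len(insertion_shared) < 9:
        pos = int(rng_ins.integers(0, len(insertion) - 21))
        tag = insertion[pos : pos + 21]
        if tag in existing:
            continue
        existing.add(tag)
        insertion_shared.append(tag)
    flank3_shared: list[str] = []
    while len(flank3_shared) < 3:
        pos = int(rng_ins.integers(0, len(flank3) - 21))
        tag = flank3[pos : pos + 21]
        if tag in existing:
            continue
        existing.add(tag)
        flank3_shared.append(tag)

    # expression profile (RPM per library); stress responses planted on
    # miR399 (up under P) and the first novel miRNA (down under P)
    by_db = {conserved[t]["db_id"]: t for t in conserved}
    profile: dict[str, dict[str, float]] = {lib: {} for lib in depths}
    base_rpm = {
        "lus-miR166a": 40_000.0,
        "lus-miR165b": 4_000.0,
        "lus-miR399": 500.0,
        "lus-miR168": 3_000.0,
        "lus-miR169": 1_500.0,
        "lus-miR395": 1_000.0,
        "lus-miR398": 2_000.0,
        "lus-miR408": 800.0,
    }
    for lib in depths:
        for db_id, tag in by_db.items():
            rpm = base_rpm[db_id]
            if db_id == "lus-miR399" and lib == "P":
                rpm *= 6.0
            profile[lib][tag] = rpm
        for tag in noncoding:
            profile[lib][tag] = 2_000.0
        for i, info in enumerate(novel.values()):
            rpm = 800.0 + 300.0 * i
            if i == 0 and lib == "P":
                rpm /= 4.0
            profile[lib][info["tag"]] = rpm
        for tag in decoys:
            profile[lib][tag] = 600.0
        for tag in unmappable:
            profile[lib][tag] = 500.0
        for tag in insertion_shared + flank3_shared:
            profile[lib][tag] = 300.0
    for tag in insertion_unique:
        profile["P"][tag] = 300.0

    # sequencing reads
    for lib, depth in depths.items():
        rng_lib = child_rng(seed, f"library:{lib}")
        reads = sample_library(
            profile[lib], depth, adapter, rng_lib, genome=genome_seq, library=lib
        )
        write_fastq(reads, outdir / f"{lib}.fastq")

    # qPCR dataset
    design = default_qpcr_design()
    rng_qpcr = child_rng(seed, "qpcr")
    ct_df = make_qpcr_dataset(design, qpcr_n, replicate_sd, rng_qpcr)
    ct_df.to_csv(outdir / "ct.tsv", sep="\t", index=False)

    write_fasta([("chr1", genome_seq)], outdir / "genome.fa")
    write_fasta(mature_records, outdir / "mature.fa")
    # ncRNA class labels live in the FASTA description field
    with open(outdir / "ncrna.fa", "w") as out:
        for rid, cls, seq in nc_records:
            out.write(f">{rid} class={cls}\n{seq}\n")
    write_fasta([("LIS-1", insertion)], outdir / "lis1.fa")
    write_fasta([("LIS-1_flank5", flank5)], outdir / "flank5.fa")
    write_fasta([("LIS-1_flank3", flank3)], outdir / "flank3.fa")

    truth = SyntheticTruth(
        seed=seed,
        conserved=conserved,
        noncoding=noncoding,
        novel=novel,
        decoys=decoys,
        unmappable=unmappable,
        insertion_unique=insertion_unique,
        insertion_shared=insertion_shared,
        flank3_shared=flank3_shared,
        present_libs=["P"],
        absent_libs=["N", "NPK"],
        profile=profile,
        depths=depths,
        adapter=adapter,
        qpcr={
            "replicate_sd": replicate_sd,
            "n_per_condition": qpcr_n,
            "transcripts": {
                t.name: {
                    "efficiency": t.efficiency,
                    "baseline_ct": t.baseline_ct,
                    "condition_effects": t.condition_effects,
                    "sample_sd": t.sample_sd,
                }
                for t in design
            },
        },
    )
    truth.to_json(outdir / "truth.json")
    return truth
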