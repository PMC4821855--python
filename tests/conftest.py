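import pytest

from flaxsrna import (
    annotate,
    genome_map,
    hairpin,
    read_processing,
    synthetic_data,
)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One complete synthetic fixture shared across the session."""
    outdir = tmp_path_factory.mktemp("fixture")
    truth = synthetic_data.make_fixture(outdir, seed=FIXTURE_SEED)
    return outdir, truth


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir):
    """Full sRNA pipeline products on the session fixture."""
    outdir, truth = fixture_dir
    table = None
    for lib in ("N", "P", "NPK"):
        reads = read_processing.read_fastq(outdir / f"{lib}.fastq")
        lib_table, _ = read_processing.process_library(reads, lib, truth.adapter)
        table = lib_table if table is None else table.merge(lib_table)
    filtered = read_processing.filter_abundance(table, 6)
    index = genome_map.GenomeIndex.from_fasta(outdir / "genome.fa")
    mature_db = annotate.load_mature_db(outdir / "mature.fa")
    ncrna_db = annotate.load_ncrna_db(outdir / "ncrna.fa")
    records = annotate.annotate_table(filtered, mature_db, ncrna_db)
    hits = genome_map.map_table(filtered, index)
    unannotated = [
        t
        for t in filtered.tags
        if records.at[t, "category"] == "unannotated" and hits[t].hits
    ]
    novel_found = hairpin.discover_novel(unannotated, hits, index)
    return {
        "truth": truth,
        "outdir": outdir,
        "raw_table": table,
        "table": filtered,
        "index": index,
        "records": records,
        "hits": hits,
        "novel": novel_found,
    }
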