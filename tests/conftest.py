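import pandas as pd
import pytest

from spliceimpact import pipeline, synth
from spliceimpact.models import GenomeInterval, TranscriptModel


def make_transcript(
    tid="T1",
    gene="G1",
    symbol="GENE1",
    chrom="chr1",
    strand="+",
    exons=(),
    cds=(),
):
    t = TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        exons=[GenomeInterval(chrom, s, e, strand) for s, e in exons],
        cds=[GenomeInterval(chrom, s, e, strand) for s, e in cds],
    )
    t.validate()
    return t


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """A mid-sized generated dataset shared by integration tests."""
    out = tmp_path_factory.mktemp("fixture")
    spec = synth.FixtureSpec(n_genes=60, seed=11)
    return synth.generate(spec, out)


@pytest.fixture(scope="session")
def pipeline_run(fixture_paths, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = {
        "genome": str(fixture_paths.genome),
        "gtf": str(fixture_paths.gtf),
        "events": str(fixture_paths.events),
        "domains": str(fixture_paths.domains),
        "go": str(fixture_paths.go),
        "gmt": str(fixture_paths.gmt),
        "out_dir": str(out),
    }
    report, records, results = pipeline.run(cfg)
    truth = pd.read_csv(fixture_paths.truth, sep="\t")
    return {
        "out_dir": out,
        "config": cfg,
        "report": report,
        "records": records,
        "results": results,
        "truth": truth,
    }
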