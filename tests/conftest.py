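import pytest

from tcrscreen.pipeline import run_suite
from tcrscreen.vdj import ContigRecord


@pytest.fixture(scope="session")
def suite_run(tmp_path_factory):
    """Simulate, screen and validate all six fixtures once per session."""
    work = tmp_path_factory.mktemp("fixtures")
    summaries, pooled, results = run_suite(work_dir=work)
    return {"summaries": summaries, "pooled": pooled, "results": results,
            "work_dir": work}


def contig(barcode="AAAC-1", chain="TRB", cdr3_nt="TGTGCTTTC",
           umis=5, productive=True, contig_id="c1", v="TRBV9",
           j="TRBJ1-1") -> ContigRecord:
    from tcrscreen.vdj import translate_cdr3
    return ContigRecord(
        barcode=barcode, chain=chain, v_gene=v, j_gene=j,
        cdr3_aa=translate_cdr3(cdr3_nt), cdr3_nt=cdr3_nt,
        umis=umis, productive=productive, contig_id=contig_id,
    )
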