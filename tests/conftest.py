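"""Shared fixtures: programmatic VCF/TSV builders, call factories."""

from __future__ import annotations

import textwrap

import pytest

from svld.model import MergedSV, SVCall


def make_call(
    chrom="chr1",
    start=1000,
    end=2000,
    svtype="DEL",
    length=None,
    genotype="0/1",
    sample="S000",
    caller="pbsv",
    platform=None,
    record_id="",
):
    if length is None:
        length = 300 if svtype == "INS" else end - start
    if svtype == "INS":
        end = start + 1
    if platform is None:
        platform = "pacbio_clr" if caller in ("pbsv", "sniffles") else "tenx_linked"
    return SVCall(
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        length=length,
        genotype=genotype,
        sample_id=sample,
        caller=caller,
        platform=platform,
        source_record_id=record_id,
    )


def make_merged(
    chrom="chr1",
    start=1000,
    end=2000,
    svtype="DEL",
    length=None,
    genotypes=None,
):
    if length is None:
        length = 300 if svtype == "INS" else end - start
    if svtype == "INS":
        end = start + 1
    return MergedSV(
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        length=length,
        genotypes=genotypes or {"S000": "0/1"},
    )


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##contig=<ID=chr2>
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
    ##INFO=<ID=END,Number=1,Type=Integer,Description="e">
    ##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
    """
)


@pytest.fixture
def vcf_writer(tmp_path):
    """Write raw VCF body lines under a standard header; returns the path."""

    def _write(body_lines, samples=("S000",), name="test.vcf"):
        path = tmp_path / name
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        path.write_text(VCF_HEADER + cols + "\n" + "\n".join(body_lines) + "\n")
        return path

    return _write
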