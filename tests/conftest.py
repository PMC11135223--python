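import random

import pytest

from snpmpc import Panel, ProtocolConfig, ToyReference, VariantKey


@pytest.fixture
def toy_panel() -> Panel:
    """The 4-entry worked-example panel."""
    return Panel(
        (
            VariantKey.snp("1", 100, "A", "G"),
            VariantKey.snp("1", 250, "C", "T"),
            VariantKey.snp("2", 40, "G", "A"),
            VariantKey.snp("X", 7, "T", "C"),
        )
    )


@pytest.fixture
def toy_panel_file(tmp_path, toy_panel):
    path = tmp_path / "panel.tsv"
    toy_panel.to_tsv(path)
    return path


def write_vcf_text(path, records, sample="S1", contigs=(("1", 10_000), ("2", 10_000), ("X", 10_000))):
    """Write a minimal VCF 4.2 file from (chrom, pos, ref, alt[, filter, gt]) rows."""
    lines = ["##fileformat=VCFv4.2"]
    for label, length in contigs:
        lines.append(f"##contig=<ID={label},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for rec in records:
        chrom, pos, ref, alt = rec[:4]
        filt = rec[4] if len(rec) > 4 else "PASS"
        gt = rec[5] if len(rec) > 5 else "0/1"
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT\t{gt}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def worked_example_vcf(tmp_path):
    """Two records matching panel entries 0 and 2 of the toy panel."""
    return write_vcf_text(tmp_path / "a.vcf", [("1", 100, "A", "G"), ("2", 40, "G", "A")])


@pytest.fixture
def shamir_config() -> ProtocolConfig:
    return ProtocolConfig(scheme="shamir", n_parties=3, threshold=1, seed=101)


@pytest.fixture
def additive_config() -> ProtocolConfig:
    return ProtocolConfig(scheme="additive", n_parties=2, seed=202)


@pytest.fixture
def small_reference() -> ToyReference:
    return ToyReference((("1", 50_000), ("2", 50_000)))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(12345)
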