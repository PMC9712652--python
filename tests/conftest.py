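import pytest

from tinvar import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """Study-sized cohorts over a small gene panel; fast enough for every test."""
    return sim.SimulationConfig(seed=7, n_genes=30)


@pytest.fixture(scope="session")
def study(small_config):
    """A complete simulated study shared (read-only) across tests."""
    sites = sim.simulate_sites(small_config)
    panel = sim.generate_reference_panel(small_config, sites=sites)
    cohort = sim.generate_case_cohort(small_config, panel, "discovery", sites=sites)
    return {
        "config": small_config,
        "sites": sites,
        "panel": panel,
        "cohort": cohort,
        "constraint": sim.generate_constraint_table(small_config),
    }


@pytest.fixture()
def toy_vcf(tmp_path):
    """Hand-written 3-sample VCF: one het/het/hom-alt site, one multiallelic site."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        "##panel=<ID=REF,AN=2000>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">',
        '##INFO=<ID=CSQ,Number=A,Type=String,Description="c">',
        '##INFO=<ID=CADD,Number=A,Type=Float,Description="d">',
        '##INFO=<ID=AC_PANEL_REF,Number=A,Type=Integer,Description="pc">',
        '##INFO=<ID=AN_PANEL_REF,Number=1,Type=Integer,Description="pn">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
        "chr1\t100\t.\tA\tT\t.\tPASS\t"
        "GENE=GENE1;CSQ=missense_variant;CADD=25.1;AC_PANEL_REF=4;AN_PANEL_REF=2000\t"
        "GT\t0/1\t1/1\t0/0",
        "chr1\t200\t.\tG\tT,C\t.\tPASS\t"
        "GENE=GENE1;CSQ=stop_gained,missense_variant;AC_PANEL_REF=1,2;AN_PANEL_REF=2000\t"
        "GT\t1/2\t0/1\t0/0",
    ]) + "\n"
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
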