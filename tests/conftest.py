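import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def star_config():
    from cyp2c9pgx.star_model import load_star_config

    return load_star_config()


@pytest.fixture(scope="session")
def star_space(star_config):
    from cyp2c9pgx.phasing_em import HaplotypeSpace

    return HaplotypeSpace.star_restricted(star_config)


@pytest.fixture(scope="session")
def full_space(star_config):
    from cyp2c9pgx.phasing_em import HaplotypeSpace

    return HaplotypeSpace.full_enumeration(star_config)


@pytest.fixture(scope="session")
def fixtures():
    from cyp2c9pgx.synthetic_data import table1_fixtures

    return table1_fixtures()


def write_vcf(path, genotypes, config, drop_rsids=(), phased=False):
    """Write records as a minimal VCF v4.2 for reader round-trip tests."""
    sep = "|" if phased else "/"
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=10>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.sample_id for g in genotypes),
    ]
    for i, locus in enumerate(config.loci):
        if locus.rsid in drop_rsids:
            continue
        cells = []
        for g in genotypes:
            if g.missing[i]:
                cells.append("./.")
            else:
                d = g.dosage[i]
                alleles = ["0"] * (2 - d) + ["1"] * d
                cells.append(sep.join(alleles))
        lines.append(
            f"10\t{locus.position}\t{locus.rsid}\t{locus.ref_allele}\t"
            f"{locus.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")
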