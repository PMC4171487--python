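"""Shared fixtures: tiny hand-built cohorts and text-file writers."""

import numpy as np
import pytest

from ovpdt.families import Cohort, NuclearFamily, VariantRecord


def make_variants(n, chrom="1", maf=None):
    maf = maf if maf is not None else [0.25] * n
    return [
        VariantRecord(f"v{j+1}", chrom, 100 * (j + 1), "T", "A", float(maf[j]))
        for j in range(n)
    ]


def trio(fid, father, mother, child, affected=True):
    return NuclearFamily(
        fid,
        np.asarray(father, np.int8),
        np.asarray(mother, np.int8),
        [(np.asarray(child, np.int8), affected)],
    )


@pytest.fixture
def trio_cohort_factory():
    """Build a trio cohort from per-family (father, mother, child) dosage
    tuples; every child is affected."""

    def build(genotypes, chrom="1"):
        fams = [
            trio(f"F{i+1}", f, m, c) for i, (f, m, c) in enumerate(genotypes)
        ]
        n_var = len(genotypes[0][0])
        return Cohort.from_families(fams, make_variants(n_var, chrom))

    return build


@pytest.fixture
def write_trio_vcf(tmp_path):
    """Write a small VCF + FAM for given sample genotype columns."""

    def build(records, samples, fam_rows, name="toy"):
        # records: list of (chrom, pos, vid, ref, alt, [gt strings per sample])
        vcf = tmp_path / f"{name}.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for chrom, pos, vid, ref, alt, gts in records:
                fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")
        fam = tmp_path / f"{name}.fam"
        with open(fam, "w") as fh:
            for row in fam_rows:
                fh.write("\t".join(map(str, row)) + "\n")
        return str(vcf), str(fam)

    return build
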