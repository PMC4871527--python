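from __future__ import annotations

import pytest

from neoburden.records import MutationRecord, ProteinRecord, VariantClass
from neoburden.simulate import make_id8_fixture


def make_mutation(
    sample_id="S1",
    gene="GENE",
    protein_id="P1",
    variant_class=VariantClass.MISSENSE,
    position=5,
    ref_aa="A",
    alt_aa="V",
    rna_reads_ref=10,
    rna_reads_alt=4,
    in_dbsnp=False,
    somatic=True,
    annotations=None,
):
    return MutationRecord(
        sample_id=sample_id,
        gene=gene,
        protein_id=protein_id,
        variant_class=variant_class,
        position=position,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        rna_reads_ref=rna_reads_ref,
        rna_reads_alt=rna_reads_alt,
        in_dbsnp=in_dbsnp,
        somatic=somatic,
        annotations=annotations or {},
    )


@pytest.fixture
def mut_factory():
    return make_mutation


@pytest.fixture
def toy_protein():
    # 40 residues; any interior position has full flanks for 8-11mers.
    return ProteinRecord(
        protein_id="P1",
        gene="GENE",
        sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRV",
    )


@pytest.fixture(scope="session")
def id8():
    """Shared instance of the constructed single-sample funnel fixture."""
    return make_id8_fixture(seed=7)
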