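import pytest

from neoprio.io import VariantTableRow


@pytest.fixture
def make_row():
    """Factory for variant rows with sensible defaults, overridable per
    field (counts chosen so the row passes all six filters)."""

    def _make(**kwargs) -> VariantTableRow:
        defaults = dict(
            patient_id="P01", chrom="chr1", pos=1000,
            ref_allele="A", alt_allele="T", gene="G1",
            hgvs_protein="p.Ala5Thr",
            tumor_dna_depth=100, tumor_dna_alt=20,
            normal_dna_depth=100, normal_dna_alt=0,
            rna_depth=50, rna_alt=10,
            tpm=50.0, tumor_genotype="het",
        )
        defaults.update(kwargs)
        return VariantTableRow(**defaults)

    return _make
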