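import numpy as np
import pytest

from savpath import fixtures
from savpath.variant_data import Label, ProteinRecord, Source, VariantRecord


@pytest.fixture
def toy_proteins():
    return {
        "P1": ProteinRecord("P1", "ACDEFGHIKL"),
        "P2": ProteinRecord("P2", "MKVLYWSTNQ"),
    }


@pytest.fixture
def small_bundle():
    return fixtures.make_fixture(
        fixtures.FixtureSpec(
            n_proteins=12,
            n_variants=60,
            mean_length=40,
            plp_fraction=0.5,
            embedding_separation=3.0,
            go_signal=0.0,
            seed=11,
        )
    )


def make_variant(acc="P1", pos=1, wt="A", mut="V", label=Label.PLP, somatic=False,
                 disease_ids=("OMIM:1",), source=Source.HUMSAVAR):
    return VariantRecord(
        protein_accession=acc,
        position=pos,
        wt_residue=wt,
        mut_residue=mut,
        label=label,
        somatic=somatic,
        disease_ids=frozenset(disease_ids),
        source=source,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
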