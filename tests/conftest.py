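import pytest
from hypothesis import settings

import metaprint2d as mp

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def corpus():
    """A moderate mixed Phase I corpus shared across the suite."""
    spec = mp.FixtureSpec(n_records=120, seed=5)
    return mp.generate_corpus(spec)


@pytest.fixture(scope="session")
def corpus_db(corpus):
    records, _ = corpus
    return mp.build_database(records)


def make_reaction(reactant_smi: str, product_smi: str, species: str = "",
                  record_id: str = "r0") -> mp.TransformationRecord:
    """Build a TransformationRecord from hand-mapped reaction SMILES halves."""
    from rdkit import Chem

    return mp.TransformationRecord(
        reactant=mp.prepare(Chem.MolFromSmiles(reactant_smi)),
        product=mp.prepare(Chem.MolFromSmiles(product_smi)),
        species=species,
        record_id=record_id,
    )
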