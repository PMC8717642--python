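import numpy as np
import pytest

from skeog.corpus_io import read_pubtator
from skeog.synthetic_data import GeneratorConfig, generate_benchmark

PUBTATOR_3DOC = """\
100|t|Naloxone causes hypertension.
100|a|We studied Naloxone in rats. Hypertension followed.
100\t0\t8\tNaloxone\tChemical\tC001
100\t16\t28\thypertension\tDisease\tD001
100\t41\t49\tNaloxone\tChemical\tC001
100\t59\t71\tHypertension\tDisease\tD001
100\tCID\tC001\tD001

200|t|Lidocaine study.
200|a|Lidocaine was given. No seizure occurred.
200\t0\t9\tLidocaine\tChemical\tC002
200\t17\t26\tLidocaine\tChemical\tC002
200\t41\t48\tseizure\tDisease\tD002

300|t|A trial of phenytoin.
300|a|Phenytoin reduced arrhythmia. Rash was seen.
300\t11\t20\tphenytoin\tChemical\tC003
300\t22\t31\tPhenytoin\tChemical\tC003
300\t40\t50\tarrhythmia\tDisease\tD003
300\t52\t56\tRash\tDisease\tD004
300\tCID\tC003\tD004
"""


@pytest.fixture
def pubtator_file(tmp_path):
    path = tmp_path / "corpus.pubtator"
    path.write_text(PUBTATOR_3DOC)
    return path


@pytest.fixture
def small_corpus(pubtator_file):
    return read_pubtator(pubtator_file)


@pytest.fixture(scope="session")
def benchmark():
    """A 12-document synthetic benchmark shared by structural tests."""
    cfg = GeneratorConfig(n_docs=12, seed=5)
    corpus, manifest, triples, hierarchy, descriptions = generate_benchmark(cfg)
    return {"config": cfg, "corpus": corpus, "manifest": manifest,
            "triples": triples, "hierarchy": hierarchy,
            "descriptions": descriptions}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
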