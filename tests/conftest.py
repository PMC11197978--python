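import numpy as np
import pytest

from littrends.corpus import Corpus, Document
from littrends.preprocess import Tokenized


@pytest.fixture
def tiny_corpus():
    """Five hand-written records spanning years and tags."""
    return Corpus([
        Document("1", 2013, "HPV status drives oropharyngeal cancer prognosis",
                 frozenset({"Humans", "Prognosis"})),
        Document("2", 2014, "Radiotherapy outcomes in oropharyngeal cancer",
                 frozenset({"Humans", "Radiotherapy"})),
        Document("3", 2015, "Immunotherapy response and TP53 mutations",
                 frozenset({"Immunotherapy", "Humans"})),
        Document("4", 2015, "Surgical margins and survival analysis",
                 frozenset({"Survival Analysis"})),
        Document("5", 2016, "HPV vaccination and cancer prevention",
                 frozenset({"Humans", "Vaccination"})),
    ])


@pytest.fixture
def disjoint_two_docs():
    """Two documents over disjoint 2-word vocabularies (a,b) and (c,d)."""
    return Tokenized(
        doc_tokens=[np.array([0, 1, 0, 1, 0, 1]), np.array([2, 3, 2, 3, 2, 3])],
        vocab=["a", "b", "c", "d"],
        doc_ids=["1", "2"],
        years=[2015, 2016],
    )


MEDLINE_SAMPLE = """\
PMID- 101
DP  - 2015 Mar-Apr
TI  - Oropharyngeal cancer and HPV: a
      review.
AB  - Background text about
      prognosis.
MH  - Humans
MH  - Prognosis/methods
MH  - *Papillomavirus Infections/complications

PMID- 102
DP  - 2016
TI  - Second title
AB  - Second abstract
MH  - Radiotherapy

DP  - 2017
TI  - Record without an identifier
AB  - Should be rejected

PMID- 104
DP  - Spring
TI  - Record with unusable date
AB  - Should be rejected too
"""


@pytest.fixture
def medline_file(tmp_path):
    path = tmp_path / "records.medline"
    path.write_text(MEDLINE_SAMPLE, encoding="utf-8")
    return str(path)
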