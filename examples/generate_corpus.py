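"""Generate a synthetic literature corpus with known ground truth.

Samples documents from an LDA generative process with 6 topics, two of
which are planted junk (a uniform word distribution and a copy of the
corpus word marginal), plus topic-enriched MeSH-like tags and embedded
gene symbols, then writes the corpus in the tabular dialect.
"""

import numpy as np

from littrends import GenerativeSpec, generate
from littrends.corpus import write_corpus

spec = GenerativeSpec(K_true=6, V=240, M=300, alpha=0.1, beta=0.02,
                      doc_length_mean=50, junk_plants=("uniform", "vacuous"),
                      gene_lexicon=("TP53", "EGFR", "CD69", "CXCL9"),
                      gene_rate=0.4, seed=42)
corpus, truth = generate(spec)
write_corpus(corpus, "synthetic_corpus.tsv")
truth.to_json("synthetic_corpus.truth.json")

dom = truth.dominant_topics()
print(f"documents: {corpus.M}, years {min(corpus.years())}-{max(corpus.years())}")
print(f"planted junk topic indices: {list(truth.junk_ids)}")
print("documents dominated by each topic:", np.bincount(dom, minlength=6).tolist())
print("first document:", corpus.documents[0].text[:70], "...")
# The bincount shows roughly balanced topic usage; the junk topics own real
# documents too, which is what makes ranking them low a meaningful test.
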