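"""Fixed English stopword list shipped with the package.

A versioned, self-contained list (classic information-retrieval stopwords)
so preprocessing is reproducible without external resources; user lists are
appended via the ``stopwords`` argument of :func:`littrends.preprocess.prune`.
Matching happens after cleaning and stemming, so stems of stopwords are
also removed.
"""

STOPWORDS = frozenset("""
a about above after again against all am an and any are aren as at be because
been before being below between both but by can cannot could couldn did didn
do does doesn doing don down during each few for from further had hadn has
hasn have haven having he her here hers herself him himself his how i if in
into is isn it its itself just me more most mustn my myself no nor not of off
on once only or other ought our ours ourselves out over own same shan she
should shouldn so some such than that the their theirs them themselves then
there these they this those through to too under until up very was wasn we
were weren what when where which while who whom why will with won would
wouldn you your yours yourself yourselves
""".split())
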