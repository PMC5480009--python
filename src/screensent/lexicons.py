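"""Built-in vocabularies: sentiment-loaded lexicons, neutral vocabulary, stopwords.

The loaded lexicons emulate the lexical signature of health-screening chatter:
positive tweets lean on early-detection and encouragement vocabulary, negative
tweets on pain, fear and preparation complaints.  The three sets are pairwise
disjoint by construction (asserted at import time).
"""

from __future__ import annotations

POSITIVE_LEXICON: tuple[str, ...] = (
    "health", "awareness", "screening", "detection", "recommend", "saves",
    "lives", "early", "prevent", "prevention", "proud", "brave", "encourage",
    "benefit", "lifesaving", "protect", "important", "schedule", "peace",
    "relief", "grateful", "easy", "quick", "support", "survivor",
)

NEGATIVE_LEXICON: tuple[str, ...] = (
    "painful", "hurts", "worried", "fear", "dread", "dreading", "scared",
    "anxiety", "awful", "horrific", "uncomfortable", "embarrassing",
    "dehydration", "preparing", "prep", "invasive", "terrified", "hate",
    "worst", "nervous", "miserable", "agony", "unpleasant", "humiliating",
    "squeezed",
)

NEUTRAL_VOCABULARY: tuple[str, ...] = (
    "doctor", "appointment", "today", "tomorrow", "week", "year", "clinic",
    "hospital", "results", "scheduled", "morning", "afternoon", "office",
    "nurse", "waiting", "room", "time", "going", "getting", "done", "first",
    "next", "last", "new", "people", "women", "men", "age", "cancer",
    "breast", "colon", "cervical", "exam", "procedure", "medical", "insurance",
    "cost", "free", "news", "article", "read", "study", "report", "guidelines",
    "changed", "recommendations", "update", "patients", "care", "visit",
    "checkup", "routine", "annual", "birthday", "turning", "fifty", "forty",
    "mother", "father", "friend", "family", "sister", "brother", "told",
    "said", "asked", "think", "know", "need", "want", "remember", "question",
)

# Function words excluded from frequency rankings (small built-in list,
# overridable by file at the reporting layer).
STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are aren as at be because
been before being below between both but by can cannot could couldn did didn
do does doesn doing don down during each few for from further had hadn has
hasn have haven having he her here hers herself him himself his how i if in
into is isn it its itself just let ll me more most mustn my myself no nor not
now of off on once only or other ought our ours ourselves out over own re
same shan she should shouldn so some such than that the their theirs them
themselves then there these they this those through to too under until up
very was wasn we were weren what when where which while who whom why will
with won would wouldn you your yours yourself yourselves ve
""".split())

# Search keywords that defined each sub-corpus; always excluded from word
# frequency rankings so the query terms do not dominate their own corpus.
MODALITY_QUERY_TERMS: dict[str, frozenset[str]] = {
    "colonoscopy": frozenset({"colonoscopy"}),
    "mammography": frozenset({"mammogram", "mammography"}),
    "pap_smear": frozenset({"pap", "smear", "paptest", "papanicolaou", "hpv"}),
}

_pos, _neg, _neu = set(POSITIVE_LEXICON), set(NEGATIVE_LEXICON), set(NEUTRAL_VOCABULARY)
assert not (_pos & _neg) and not (_pos & _neu) and not (_neg & _neu), (
    "built-in lexicons must be pairwise disjoint"
)
del _pos, _neg, _neu
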