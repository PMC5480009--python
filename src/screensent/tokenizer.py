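"""Tweet tokenization: a minimal, deterministic bag-of-words normalizer.

Rules: lowercase; URLs and @-mentions removed; '#' stripped from hashtags
(keeping the word); remaining text split on runs of non-alphanumeric
characters; tokens shorter than 2 characters dropped.
"""

from __future__ import annotations

import re

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_SPLIT_RE = re.compile(r"[^a-z0-9]+")

__all__ = ["tokenize"]


def tokenize(text: str) -> list[str]:
    """Normalize free text into a list of lowercase tokens.

    Parameters
    ----------
    text : str
        Raw message text; may be empty.

    Returns
    -------
    list of str
        Tokens in original order, each lowercase, length >= 2, containing
        only ``[a-z0-9]``.  Empty input yields an empty list.
    """
    if not text:
        return []
    text = text.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    # '#' is non-alphanumeric, so splitting strips it while keeping the word
    return [tok for tok in _SPLIT_RE.split(text) if len(tok) >= 2]
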