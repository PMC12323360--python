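"""Taxon-name normalization shared by the classification and panel lookups."""

import re

_WS = re.compile(r"[\s_]+")


def normalize_taxon_name(name: str) -> str:
    """Case-fold a taxon name and unify underscores/whitespace to single spaces.

    Matching elsewhere in the package is exact after this normalization;
    no synonym resolution is attempted.
    """
    return _WS.sub(" ", name.strip()).casefold()
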