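"""Registry of studied opioids and brand/spelling synonyms.

The analysis covers oral/sublingual prescription opioids commonly diverted
to the US black market. Three independent report streams will not share
spellings, so every inbound drug string is normalized case-insensitively
against this registry; unknown names are rejected upstream, never guessed.
"""

from __future__ import annotations

#: Canonical drug identifiers, in the conventional descending-potency order.
DRUGS: tuple[str, ...] = (
    "hydromorphone",
    "buprenorphine",
    "oxymorphone",
    "methadone",
    "oxycodone",
    "hydrocodone",
    "morphine",
    "tramadol",
)

#: Brand names and common variants -> canonical generic name.
SYNONYMS: dict[str, str] = {
    "dilaudid": "hydromorphone",
    "exalgo": "hydromorphone",
    "suboxone": "buprenorphine",
    "subutex": "buprenorphine",
    "opana": "oxymorphone",
    "dolophine": "methadone",
    "methadose": "methadone",
    "oxycontin": "oxycodone",
    "roxicodone": "oxycodone",
    "percocet": "oxycodone",
    "vicodin": "hydrocodone",
    "norco": "hydrocodone",
    "lortab": "hydrocodone",
    "ms contin": "morphine",
    "msir": "morphine",
    "ultram": "tramadol",
}


def normalize_drug(name: str) -> str | None:
    """Map a raw drug string to its canonical identifier, or None if unknown."""
    if not isinstance(name, str):
        return None
    key = name.strip().lower()
    if key in DRUGS:
        return key
    return SYNONYMS.get(key)
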