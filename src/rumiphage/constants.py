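"""Shared label vocabularies for ruminant gut phage catalogs.

Animal hosts are the eight ruminant species sampled along the
gastrointestinal tract (GIT); GIT sites run from the rumen to the
rectum/feces. Methanogen genera follow GTDB-style naming, where a
suffixed genus (``Methanobrevibacter_A``) is a distinct genus.
"""

ANIMAL_HOSTS: tuple[str, ...] = (
    "buffalo",
    "camel",
    "cattle",
    "cow",
    "deer",
    "goat",
    "sheep",
    "yak",
)

GIT_SITES: tuple[str, ...] = (
    "rumen",
    "reticulum",
    "omasum",
    "abomasum",
    "duodenum",
    "jejunum",
    "ileum",
    "cecum",
    "colon",
    "rectum_feces",
)

METHANOGEN_GENERA: frozenset[str] = frozenset(
    {
        "ISO4",
        "Methanobrevibacter",
        "Methanobrevibacter_A",
        "Methanobrevibacter_B",
        "Methanocorpusculum",
        "Methanosphaera",
    }
)

DNA_ALPHABET = "ACGT"
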