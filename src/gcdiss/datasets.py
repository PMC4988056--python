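"""Packaged miniature datasets used in docs and tests."""

from __future__ import annotations

from importlib.resources import files

from .profiles import ProfileTable


def table1_profiles() -> ProfileTable:
    """The two-strain worked example: 9 and 11 genes over five OGs.

    Strain I maps gene counts (1, 2, 4, 0, 2) and strain J (1, 4, 2, 2, 2)
    onto OG1..OG5; their Bray-Curtis gene-content dissimilarity is 0.3.
    """
    path = files("gcdiss").joinpath("data/table1_profiles.tsv")
    return ProfileTable.from_tsv(str(path))
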