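"""Bundled worked-example genotype tables.

Only variants whose full cell counts are available in plain text ship as
fixtures.  v1 bundles rs2398162, a hypertension-associated variant from
the Wellcome Trust Case Control Consortium study in which the minor
allele was suggested to act dominantly.
"""

from __future__ import annotations

from .contingency import GenotypeTable

__all__ = ["FIXTURES", "get_fixture", "list_fixtures"]

FIXTURES: dict[str, GenotypeTable] = {
    "rs2398162": GenotypeTable(
        r=(1205, 624, 111),
        s=(1608, 1121, 194),
        label="rs2398162",
    ),
}


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


def get_fixture(name: str) -> GenotypeTable:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {list_fixtures()}"
        ) from None
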