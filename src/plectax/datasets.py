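"""Packaged study tables.

Two small TSV files ship with the package: the specimen collection table
(group assignment, site, marker, accession for every barcoded specimen) and
the voucher-image morphometric table for the Prairie Corridor specimens.
They were transcribed once, by hand, from the published study so that the
in-study checks run without any sequence download.
"""

from __future__ import annotations

from importlib.resources import files

from .io import MorphTable, SpecimenTable, read_morph_table, read_specimen_table

_DATA = files("plectax.data")


def specimen_table_path() -> str:
    return str(_DATA / "table1_specimens.tsv")


def morph_table_path() -> str:
    return str(_DATA / "table2_morphometrics.tsv")


def load_specimen_table() -> SpecimenTable:
    """The full specimen collection table (COI and 18S barcoded specimens)."""
    return read_specimen_table(specimen_table_path())


def load_morph_table() -> MorphTable:
    """Voucher measurements for the 40 imaged Prairie Corridor specimens."""
    return read_morph_table(morph_table_path())
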