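"""Packaged fixtures: the curated 72-variant table, the 63-patient clinical
table, and a frozen DNA-repair gene panel snapshot.

Each loader verifies a SHA-256 checksum before parsing, so silent fixture
corruption surfaces as a :class:`FixtureIntegrityError` rather than as a
mysteriously shifted statistic. Loaders are pure: repeated loads return
equal objects.
"""

from __future__ import annotations

import hashlib
import io
from importlib import resources

from .annotation_io import read_variant_table
from .cohort_stats import PatientRecord, read_patient_table
from .errors import FixtureIntegrityError
from .gene_panel import PanelGene, load_panel
from .variants import AnnotatedVariant

_CHECKSUMS = {
    "table1_variants.tsv": "bee8ab07d26472d03ff28c6d157b983d2c8656ba8c1ed57c60bc86de321668aa",
    "table2_patients.tsv": "ce14829c9205137fcd1d2af56511c85b3ead4a21d9d68b61a516fffc876a7853",
    "dna_repair_panel.txt": "74c0359fb346dddaf21ac2009d062fa36d80008882e9c31664cb8d6edd4b7306",
    "panel_aliases.tsv": "c4e647013f974012654fbd8859758c00f27c848207016284447cc75a58532d23",
}


def _read_fixture(name: str) -> str:
    text = (resources.files("repairvar") / "data" / name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = _CHECKSUMS[name]
    if expected != "dev" and digest != expected:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {expected}")
    return text


def load_table1_fixture() -> list[AnnotatedVariant]:
    """The 72 retained variants of the index cohort, as published."""
    return read_variant_table(io.StringIO(_read_fixture("table1_variants.tsv")))


def load_table2_fixture() -> list[PatientRecord]:
    """The 63 index-cohort patients with ages, family-history flag,
    bilateral status and carried variant ids."""
    return read_patient_table(io.StringIO(_read_fixture("table2_patients.tsv")))


def load_default_panel() -> set[PanelGene]:
    """The frozen DNA-repair gene panel snapshot with its alias map."""
    return load_panel(io.StringIO(_read_fixture("dna_repair_panel.txt")),
                      io.StringIO(_read_fixture("panel_aliases.tsv")))
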