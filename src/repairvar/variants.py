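"""Core variant domain types.

The unit flowing through the prioritization cascade is an
:class:`AnnotatedVariant`: one genomic change, the transcript annotation
chosen for it, its pathogenicity scores (CADD PHRED, REVEL, SIFT,
PolyPhen) and its gnomAD allele frequencies (exome/genome, global and
Finnish). Missingness is represented as ``None`` and is semantically
distinct from a reported value of 0: a frequency printed as 0 is a
*reported* frequency and keeps a variant out of the ultra-rare stratum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError

_ALLELE_RE = re.compile(r"^([ACGTN]+|-)$")


def normalize_contig(chrom: str) -> str:
    """Strip a ``chr`` prefix and uppercase; ``chr14`` and ``14`` are equal."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def _check_allele(a: str) -> str:
    a = a.strip().upper()
    if not _ALLELE_RE.match(a):
        raise InputError(f"invalid allele {a!r}: expected [ACGTN]+ or '-'")
    return a


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate allele: contig, 1-based position, ref, alt.

    Contig names are stored without the ``chr`` prefix; alleles are upper
    case. ``N`` is accepted as a placeholder base, and ``-`` denotes a
    table-dialect insertion/deletion side with no anchor base (curated
    tables print e.g. ``-/T``); VCF-derived keys never contain either.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_contig(self.chrom))
        object.__setattr__(self, "ref", _check_allele(self.ref))
        object.__setattr__(self, "alt", _check_allele(self.alt))
        if self.pos < 1:
            raise InputError(f"position must be >= 1, got {self.pos}")

    def normalized(self) -> "VariantKey":
        """Minimal representation: trim the common suffix, then the common
        prefix (keeping at least one base on each side), shifting ``pos``.

        Different callers may emit the same indel padded differently; this
        puts both on a shared footing before intersection. Full left
        alignment against the reference is not attempted.
        """
        ref, alt, pos = self.ref, self.alt, self.pos
        if "-" in (ref, alt) or "N" in ref or "N" in alt:
            return self
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return VariantKey(self.chrom, pos, ref, alt)

    def __str__(self) -> str:
        return f"chr{self.chrom}:{self.pos} {self.ref}/{self.alt}"


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript's view of a variant, as emitted by an annotator."""

    gene_symbol: str
    consequence_terms: frozenset[str]
    is_canonical: bool = False
    gene_id: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    sift_score: Optional[float] = None
    polyphen_score: Optional[float] = None

    def __post_init__(self):
        if not self.consequence_terms:
            raise InputError("consequence_terms must be non-empty")
        for name in ("sift_score", "polyphen_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InputError(f"{name} outside [0,1]: {v}")


def _check_freq(name: str, v: Optional[float]) -> None:
    if v is not None and not (0.0 <= v <= 1.0):
        raise InputError(f"{name} outside [0,1]: {v}")


@dataclass
class AnnotatedVariant:
    """A variant with its chosen annotation, scores, frequencies, carriers."""

    key: VariantKey
    annotation: TranscriptAnnotation
    identifier: Optional[str] = None  # dbSNP rs-number when known
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    af_exome_global: Optional[float] = None
    af_genome_global: Optional[float] = None
    af_exome_fin: Optional[float] = None
    af_genome_fin: Optional[float] = None
    carriers: set[str] = field(default_factory=set)
    hom_carriers: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise InputError(f"CADD PHRED must be >= 0, got {self.cadd_phred}")
        _check_freq("revel", self.revel)
        for name in ("af_exome_global", "af_genome_global",
                     "af_exome_fin", "af_genome_fin"):
            _check_freq(name, getattr(self, name))

    @property
    def gene(self) -> str:
        return self.annotation.gene_symbol

    @property
    def allele_frequencies(self) -> tuple[Optional[float], ...]:
        """The four gnomAD frequency slots, in a fixed order."""
        return (self.af_exome_global, self.af_genome_global,
                self.af_exome_fin, self.af_genome_fin)

    @property
    def uid(self) -> str:
        """Stable display identifier: the rs-number when present, else the
        curated-table style ``chrN:pos REF/ALT`` string."""
        if self.identifier:
            return self.identifier
        if "variant_id" in self.metadata:
            return self.metadata["variant_id"]
        return str(self.key)
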