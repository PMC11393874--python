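"""Reading and writing annotated variant data.

Three dialects are supported:

* VCF 4.2 with a VEP-style ``CSQ`` INFO field (pipe-separated fields, one
  comma-separated entry per transcript), read through :mod:`cyvcf2` and
  written as plain text;
* the curated-table TSV dialect (tab-separated, ``NA`` = absent) used for
  published variant tables;
* bare callsets of :class:`~repairvar.variants.VariantKey` for the
  dual-caller consensus intersection.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
from cyvcf2 import VCF

from .errors import MergeError, RecordError, SchemaError, TableError
from .variants import AnnotatedVariant, TranscriptAnnotation, VariantKey, normalize_contig

log = logging.getLogger(__name__)

#: CSQ fields the reader understands, in canonical order for writing.
SUPPORTED_CSQ_FIELDS = (
    "Allele", "Consequence", "SYMBOL", "Gene", "CANONICAL", "HGVSc", "HGVSp",
    "SIFT", "PolyPhen", "REVEL", "CADD_PHRED",
    "gnomADe_AF", "gnomADg_AF", "gnomADe_FIN_AF", "gnomADg_FIN_AF",
)

_REQUIRED_CSQ = ("Consequence", "SYMBOL", "CANONICAL")

# Display names used by curated tables <-> Sequence Ontology terms.
_DISPLAY_TO_TERM = {
    "stop gained": "stop_gained",
    "start lost": "start_lost",
    "splice acceptor": "splice_acceptor_variant",
    "splice donor": "splice_donor_variant",
    "splice region": "splice_region_variant",
    "splice polypyrimidine tract": "splice_polypyrimidine_tract_variant",
    "intron": "intron_variant",
    "missense": "missense_variant",
    "frameshift": "frameshift_variant",
    "in-frame deletion": "inframe_deletion",
    "in-frame insertion": "inframe_insertion",
    "downstream gene": "downstream_gene_variant",
    "upstream gene": "upstream_gene_variant",
    "intergenic": "intergenic_variant",
    "synonymous": "synonymous_variant",
    "non coding transcript exon": "non_coding_transcript_exon_variant",
    "protein altering": "protein_altering_variant",
}
_TERM_TO_DISPLAY = {v: k for k, v in _DISPLAY_TO_TERM.items()}

TABLE_COLUMNS = (
    "variant_id", "gene", "location", "nucleotide_change", "protein_change",
    "consequence", "subcategory", "af_exome_fin", "af_genome_fin",
    "af_exome_global", "af_genome_global", "sift", "polyphen", "revel",
    "cadd_phred",
)


def parse_csq_schema(header_text: str) -> list[str]:
    """Extract the ordered CSQ field names from a VCF ``##INFO=<ID=CSQ...``
    meta-line. The annotator records its field layout in a ``Format:``
    clause; at least Consequence, SYMBOL and CANONICAL must be present.
    """
    m = re.search(r"Format:\s*([A-Za-z0-9_|]+)", header_text)
    if not m:
        raise SchemaError("CSQ meta-line has no 'Format:' clause")
    fields = m.group(1).strip().strip("|").split("|")
    for req in _REQUIRED_CSQ:
        if req not in fields:
            raise SchemaError(f"CSQ schema lacks required field {req!r}")
    return fields


def _opt_float(text: str, what: str, where: str) -> Optional[float]:
    text = text.strip()
    if text in ("", ".", "NA"):
        return None
    # VEP SIFT/PolyPhen may come as "deleterious(0.02)"
    m = re.match(r"^[A-Za-z_]+\(([0-9.eE+-]+)\)$", text)
    if m:
        text = m.group(1)
    try:
        return float(text)
    except ValueError:
        raise RecordError(f"unparseable {what} value {text!r} at {where}") from None


def read_annotated_variants(
    vcf_source: str,
    schema: Optional[Sequence[str]] = None,
) -> list[AnnotatedVariant]:
    """Read a (possibly multi-sample) annotated VCF into AnnotatedVariants.

    One record is produced per (variant key, gene) after transcript
    selection; multi-allelic sites are decomposed per alternate allele and
    CSQ entries are matched on their ``Allele`` field. Empty CSQ strings map
    to absent values. Samples with a non-reference genotype for the allele
    populate ``carriers`` (homozygous alternates additionally populate
    ``hom_carriers``; zygosity is recorded, never enforced).
    """
    from .prioritization import transcript_filter

    vcf = VCF(vcf_source)
    if schema is None:
        raw = vcf.raw_header
        m = re.search(r'##INFO=<ID=CSQ,[^\n]*', raw)
        if not m:
            raise SchemaError("VCF has no INFO/CSQ meta-line")
        schema = parse_csq_schema(m.group(0))
    schema = list(schema)
    idx = {name: i for i, name in enumerate(schema)}
    samples = list(vcf.samples)

    out: list[AnnotatedVariant] = []
    for rec_no, rec in enumerate(vcf, start=1):
        csq_raw = rec.INFO.get("CSQ")
        if csq_raw is None:
            continue
        entries = []
        for entry in str(csq_raw).split(","):
            parts = entry.split("|")
            if len(parts) != len(schema):
                raise RecordError(
                    f"CSQ entry with {len(parts)} fields (expected {len(schema)}) "
                    f"in record {rec_no} at {rec.CHROM}:{rec.POS}")
            entries.append(parts)

        genotypes = rec.genotypes or []
        for alt_i, alt in enumerate(rec.ALT):
            key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt).normalized()
            where = f"record {rec_no} ({key})"
            carriers, homs = set(), set()
            for s_i, gt in enumerate(genotypes):
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if (alt_i + 1) in alleles:
                    carriers.add(samples[s_i])
                    if all(a == alt_i + 1 for a in alleles):
                        homs.add(samples[s_i])

            def fld(parts, name):
                return parts[idx[name]].strip() if name in idx else ""

            per_gene: dict[str, list] = {}
            for parts in entries:
                if "Allele" in idx and fld(parts, "Allele") not in ("", alt):
                    continue
                terms = frozenset(
                    t.strip() for t in fld(parts, "Consequence").split("&") if t.strip())
                if not terms:
                    continue
                ann = TranscriptAnnotation(
                    gene_symbol=fld(parts, "SYMBOL") or "",
                    consequence_terms=terms,
                    is_canonical=fld(parts, "CANONICAL").upper() in ("YES", "1"),
                    gene_id=fld(parts, "Gene") or None,
                    hgvs_c=fld(parts, "HGVSc") or None,
                    hgvs_p=fld(parts, "HGVSp") or None,
                    sift_score=_opt_float(fld(parts, "SIFT"), "SIFT", where),
                    polyphen_score=_opt_float(fld(parts, "PolyPhen"), "PolyPhen", where),
                )
                per_gene.setdefault(ann.gene_symbol, []).append((ann, parts))

            for gene, anns in sorted(per_gene.items()):
                chosen = transcript_filter([a for a, _ in anns])
                if chosen is None:
                    continue
                parts = next(p for a, p in anns if a is chosen)
                rsid = rec.ID if rec.ID not in (None, ".", "") else None
                out.append(AnnotatedVariant(
                    key=key,
                    annotation=chosen,
                    identifier=rsid,
                    cadd_phred=_opt_float(fld(parts, "CADD_PHRED"), "CADD_PHRED", where),
                    revel=_opt_float(fld(parts, "REVEL"), "REVEL", where),
                    af_exome_global=_opt_float(fld(parts, "gnomADe_AF"), "gnomADe_AF", where),
                    af_genome_global=_opt_float(fld(parts, "gnomADg_AF"), "gnomADg_AF", where),
                    af_exome_fin=_opt_float(fld(parts, "gnomADe_FIN_AF"), "gnomADe_FIN_AF", where),
                    af_genome_fin=_opt_float(fld(parts, "gnomADg_FIN_AF"), "gnomADg_FIN_AF", where),
                    carriers=set(carriers),
                    hom_carriers=set(homs),
                ))
    return out


def read_caller_keys(vcf_source: str) -> list[VariantKey]:
    """Read only the variant keys from one caller's VCF (for consensus)."""
    vcf = VCF(vcf_source)
    keys = []
    for rec in vcf:
        for alt in rec.ALT:
            keys.append(VariantKey(rec.CHROM, rec.POS, rec.REF, alt).normalized())
    return keys


def reference_build(vcf_source: str) -> Optional[str]:
    """The declared reference build of a VCF, if any (##reference=...)."""
    m = re.search(r"##reference=(\S+)", VCF(vcf_source).raw_header)
    return m.group(1) if m else None


# ---------------------------------------------------------------- TSV dialect

def _parse_location(loc: str) -> tuple[str, int]:
    m = re.match(r"^(chr)?([0-9XYM]+):(\d+)", loc.strip())
    if m is None:
        raise TableError(f"unparseable location {loc!r}")
    return m.group(2), int(m.group(3))


def _key_from_row(variant_id: str, location: str, hgvs_c: str) -> VariantKey:
    """Best-effort genomic key for a curated-table row.

    Novel rows print their alleles (``chr4:2490336 G/T``); substitution rows
    yield coding-strand alleles from HGVS c.; indel rows without printed
    alleles fall back to ``N`` placeholders (identity then rests on the
    position and the rs-number).
    """
    chrom, pos = _parse_location(location)
    m = re.match(r"^(chr)?[0-9XYM]+:\d+\s+([ACGTN-]+)/([ACGTN-]+)$", variant_id.strip())
    if m:
        return VariantKey(chrom, pos, m.group(2), m.group(3))
    m = re.search(r"(\d+)([ACGT])>([ACGT])$", hgvs_c)
    if m:
        return VariantKey(chrom, pos, m.group(2), m.group(3))
    return VariantKey(chrom, pos, "N", "N")


def _consequence_terms(text: str, where: str) -> frozenset[str]:
    terms = []
    for part in text.split(","):
        part = part.strip().lower()
        if not part:
            continue
        if part in _DISPLAY_TO_TERM:
            terms.append(_DISPLAY_TO_TERM[part])
        elif re.match(r"^[a-z0-9_]+$", part):  # already an SO-style term
            terms.append(part)
        else:
            raise TableError(f"unknown consequence {part!r} at {where}")
    if not terms:
        raise TableError(f"empty consequence at {where}")
    return frozenset(terms)


def _cell_float(text, what: str, where: str) -> Optional[float]:
    if text is None:
        return None
    text = str(text).strip()
    if text in ("", "NA"):
        return None
    try:
        return float(text)
    except ValueError:
        raise TableError(f"non-numeric {what} {text!r} at {where}") from None


def read_variant_table(tsv_source: Union[str, TextIO]) -> list[AnnotatedVariant]:
    """Parse the curated-table TSV dialect into AnnotatedVariants.

    Rows whose first column is a chromosomal position (no rs-number) get an
    absent identifier; ``NA`` cells map to absent; the printed subcategory
    label and raw location/consequence strings are kept as metadata so the
    table round-trips field-for-field through :func:`write_variant_table`.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in TABLE_COLUMNS]
    if unknown:
        raise TableError(f"unknown column(s): {unknown}")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"missing column(s): {missing}")

    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        where = f"row {i}"
        vid = row.variant_id.strip()
        is_rs = vid.startswith("rs")
        hgvs_c = None if row.nucleotide_change.strip() in ("", "NA") else row.nucleotide_change.strip()
        hgvs_p = None if row.protein_change.strip() in ("", "NA") else row.protein_change.strip()
        ann = TranscriptAnnotation(
            gene_symbol=row.gene.strip(),
            consequence_terms=_consequence_terms(row.consequence, where),
            is_canonical=True,  # curated tables publish the chosen transcript
            hgvs_c=hgvs_c,
            hgvs_p=hgvs_p,
            sift_score=_cell_float(row.sift, "sift", where),
            polyphen_score=_cell_float(row.polyphen, "polyphen", where),
        )
        out.append(AnnotatedVariant(
            key=_key_from_row(vid, row.location, hgvs_c or ""),
            annotation=ann,
            identifier=vid if is_rs else None,
            cadd_phred=_cell_float(row.cadd_phred, "cadd_phred", where),
            revel=_cell_float(row.revel, "revel", where),
            af_exome_fin=_cell_float(row.af_exome_fin, "af_exome_fin", where),
            af_genome_fin=_cell_float(row.af_genome_fin, "af_genome_fin", where),
            af_exome_global=_cell_float(row.af_exome_global, "af_exome_global", where),
            af_genome_global=_cell_float(row.af_genome_global, "af_genome_global", where),
            metadata={
                "variant_id": vid,
                "location": row.location.strip(),
                "consequence_text": row.consequence.strip(),
                "printed_subcategory": row.subcategory.strip(),
            },
        ))
    return out


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return "NA"
    return f"{v:.6g}"


def variant_to_row(v: AnnotatedVariant) -> dict:
    md = v.metadata
    if "consequence_text" in md:
        cons = md["consequence_text"]
    else:
        cons = ", ".join(sorted(
            _TERM_TO_DISPLAY.get(t, t) for t in v.annotation.consequence_terms))
    return {
        "variant_id": v.uid,
        "gene": v.gene,
        "location": md.get("location", f"chr{v.key.chrom}:{v.key.pos}"),
        "nucleotide_change": v.annotation.hgvs_c or "NA",
        "protein_change": v.annotation.hgvs_p or "NA",
        "consequence": cons,
        "subcategory": md.get("printed_subcategory", ""),
        "af_exome_fin": _fmt(v.af_exome_fin),
        "af_genome_fin": _fmt(v.af_genome_fin),
        "af_exome_global": _fmt(v.af_exome_global),
        "af_genome_global": _fmt(v.af_genome_global),
        "sift": _fmt(v.annotation.sift_score),
        "polyphen": _fmt(v.annotation.polyphen_score),
        "revel": _fmt(v.revel),
        "cadd_phred": _fmt(v.cadd_phred),
    }


def write_variant_table(variants: Iterable[AnnotatedVariant], dest) -> None:
    """Write variants back out in the curated-table TSV dialect."""
    df = pd.DataFrame([variant_to_row(v) for v in variants], columns=TABLE_COLUMNS)
    df.to_csv(dest, sep="\t", index=False)


# ------------------------------------------------------------------- merging

def consensus_merge(
    callset_a: Iterable[VariantKey],
    callset_b: Iterable[VariantKey],
    build_a: Optional[str] = None,
    build_b: Optional[str] = None,
) -> list[VariantKey]:
    """Intersection of two callers' callsets for the same sample.

    Keys are compared after contig normalization and minimal-representation
    trimming, so differently padded indels still match. The result is the
    set of keys both callers report, sorted by (chrom, pos, ref, alt).
    """
    if build_a and build_b and build_a != build_b:
        raise MergeError(f"mixed reference builds: {build_a!r} vs {build_b!r}")
    a = {k.normalized() for k in callset_a}
    b = {k.normalized() for k in callset_b}
    return sorted(a & b)


def merge_cohort(
    per_patient: Mapping[str, Iterable[AnnotatedVariant]],
) -> list[AnnotatedVariant]:
    """Combine per-patient variant lists into one cohort-level list.

    Variants with equal (key, gene) are unified; carriers become the union
    of the patients carrying the variant. Disagreeing annotation or score
    fields keep the first-seen value and log a warning.
    """
    merged: dict[tuple[VariantKey, str], AnnotatedVariant] = {}
    for patient_id in sorted(per_patient):
        for v in per_patient[patient_id]:
            k = (v.key, v.gene)
            if k not in merged:
                merged[k] = AnnotatedVariant(
                    key=v.key, annotation=v.annotation, identifier=v.identifier,
                    cadd_phred=v.cadd_phred, revel=v.revel,
                    af_exome_global=v.af_exome_global,
                    af_genome_global=v.af_genome_global,
                    af_exome_fin=v.af_exome_fin, af_genome_fin=v.af_genome_fin,
                    carriers={patient_id} if not v.carriers else set(v.carriers),
                    hom_carriers=set(v.hom_carriers),
                    metadata=dict(v.metadata),
                )
            else:
                kept = merged[k]
                for fname in ("cadd_phred", "revel", "af_exome_global",
                              "af_genome_global", "af_exome_fin", "af_genome_fin"):
                    if getattr(v, fname) != getattr(kept, fname):
                        log.warning("disagreeing %s for %s: keeping first-seen %r",
                                    fname, kept.uid, getattr(kept, fname))
                if v.annotation != kept.annotation:
                    log.warning("disagreeing annotation for %s: keeping first-seen",
                                kept.uid)
                kept.carriers |= v.carriers or {patient_id}
                kept.hom_carriers |= v.hom_carriers
    return sorted(merged.values(), key=lambda v: (v.key, v.gene))


# ---------------------------------------------------------------- VCF output

def write_vcf(variants: Sequence[AnnotatedVariant], dest,
              sample_ids: Optional[Sequence[str]] = None) -> None:
    """Serialize variants to a VCF 4.2 text stream with a full CSQ field.

    Carrier sets become heterozygous sample genotypes (homozygous where the
    variant records the sample in ``hom_carriers``). Placeholder alleles
    (``-``) from curated tables cannot be represented and raise RecordError.
    """
    if sample_ids is None:
        sample_ids = sorted({s for v in variants for s in v.carriers})
    fields = "|".join(SUPPORTED_CSQ_FIELDS)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
        f'annotations. Format: {fields}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_ids:
        header += ["FORMAT", *sample_ids]
    lines.append("\t".join(header))

    def csq_num(v):
        return "" if v is None else f"{v:.10g}"

    for v in sorted(variants, key=lambda v: (v.key, v.gene)):
        k = v.key
        if "-" in (k.ref, k.alt):
            raise RecordError(f"cannot serialize placeholder alleles for {v.uid}")
        a = v.annotation
        csq = "|".join([
            k.alt, "&".join(sorted(a.consequence_terms)), a.gene_symbol,
            a.gene_id or "", "YES" if a.is_canonical else "",
            a.hgvs_c or "", a.hgvs_p or "",
            csq_num(a.sift_score), csq_num(a.polyphen_score),
            csq_num(v.revel), csq_num(v.cadd_phred),
            csq_num(v.af_exome_global), csq_num(v.af_genome_global),
            csq_num(v.af_exome_fin), csq_num(v.af_genome_fin),
        ])
        row = [f"chr{k.chrom}", str(k.pos), v.identifier or ".", k.ref, k.alt,
               ".", "PASS", f"CSQ={csq}"]
        if sample_ids:
            row.append("GT")
            for s in sample_ids:
                if s in v.hom_carriers:
                    row.append("1/1")
                elif s in v.carriers:
                    row.append("0/1")
                else:
                    row.append("0/0")
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
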