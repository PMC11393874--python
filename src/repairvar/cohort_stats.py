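"""Per-patient aggregation and cohort-level summaries.

Ties the retained variants back to the patients carrying them: who carries
what, how many carry more than one candidate allele, which retained
variants are novel (no rs-number and no reported population frequency),
and the clinical margins of the cohort (ages at first diagnosis, bilateral
disease, family-history status).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd

from .errors import CohortError, TableError
from .prioritization import PriorityCall
from .variants import AnnotatedVariant, VariantKey

PATIENT_COLUMNS = ("patient_id", "lund_negative", "age1", "age2",
                   "triple_negative", "histology", "variant_ids")


@dataclass
class PatientRecord:
    """One cohort member. ``lund_negative`` marks patients qualifying by
    young onset alone (no family history under the modified Lund criteria);
    two diagnosis ages mean bilateral disease."""

    patient_id: str
    ages_at_diagnosis: list[int]
    lund_negative: bool = False
    triple_negative: Optional[bool] = None
    histology_text: str = ""
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.ages_at_diagnosis)
        if not 1 <= n <= 2:
            raise CohortError(
                f"patient {self.patient_id}: expected 1-2 diagnosis ages, got {n}")
        for a in self.ages_at_diagnosis:
            if not 15 <= a <= 100:
                raise CohortError(
                    f"patient {self.patient_id}: implausible age {a}")

    @property
    def bilateral(self) -> bool:
        return len(self.ages_at_diagnosis) == 2

    @property
    def age_first(self) -> int:
        return self.ages_at_diagnosis[0]


@dataclass
class CohortSummary:
    n_patients: int
    n_with_variant: int
    n_without_variant: int
    n_multi_variant: int
    max_variants_per_patient: int
    n_retained_variants: int
    n_novel_variants: int
    n_known_variants: int
    n_distinct_genes_known: int
    carriers_per_variant: dict[str, int]
    min_age: int
    median_age: float
    mean_age: float
    n_bilateral: int
    n_lund_negative: int

    def as_text(self) -> str:
        lines = [
            f"patients: {self.n_patients}",
            f"  with >=1 retained variant: {self.n_with_variant}",
            f"  without retained variant:  {self.n_without_variant}",
            f"  with >1 retained variant:  {self.n_multi_variant}",
            f"  max variants per patient:  {self.max_variants_per_patient}",
            f"  bilateral: {self.n_bilateral}",
            f"  family-history negative (Lund): {self.n_lund_negative}",
            f"  age at first diagnosis: min {self.min_age}, "
            f"median {self.median_age:g}, mean {self.mean_age:.2f}",
            f"retained variants: {self.n_retained_variants}",
            f"  novel (no rsID, no reported AF): {self.n_novel_variants}",
            f"  known: {self.n_known_variants} "
            f"in {self.n_distinct_genes_known} genes",
        ]
        return "\n".join(lines)


def is_novel(variant: AnnotatedVariant) -> bool:
    """Novel = never catalogued: no dbSNP identifier AND no frequency
    reported in any gnomAD slot. A printed frequency of 0 counts as
    reported, so a known allele absent from a sub-population stays known."""
    return variant.identifier is None and all(
        f is None for f in variant.allele_frequencies)


def variants_per_patient(patients: Sequence[PatientRecord]) -> dict[str, int]:
    seen = set()
    for p in patients:
        if p.patient_id in seen:
            raise CohortError(f"duplicate patient id {p.patient_id}")
        seen.add(p.patient_id)
    return {p.patient_id: len(p.variant_ids) for p in patients}


def _median_lower(values: Sequence[float]) -> float:
    """Median using the lower-middle element for even counts."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def summarize_cohort(
    patients: Sequence[PatientRecord],
    calls: Sequence[PriorityCall],
    variants: Sequence[AnnotatedVariant],
) -> CohortSummary:
    """Aggregate the cascade output over a patient table.

    Every variant id a patient lists must resolve to a retained variant;
    ages use the age at first diagnosis; the median uses the lower-middle
    element for even cohort sizes.
    """
    per_patient = variants_per_patient(patients)
    by_uid = {v.uid: v for v in variants}
    retained_uids = {c.uid for c in calls if c.retained}

    carriers: dict[str, int] = {}
    for p in patients:
        for vid in p.variant_ids:
            if vid not in by_uid:
                raise CohortError(
                    f"patient {p.patient_id} references unknown variant {vid!r}")
            if vid not in retained_uids:
                raise CohortError(
                    f"patient {p.patient_id} references non-retained variant {vid!r}")
            carriers[vid] = carriers.get(vid, 0) + 1

    retained_vars = [by_uid[u] for u in sorted(retained_uids) if u in by_uid]
    novel = [v for v in retained_vars if is_novel(v)]
    known = [v for v in retained_vars if not is_novel(v)]
    counts = list(per_patient.values())
    ages = [p.age_first for p in patients]

    return CohortSummary(
        n_patients=len(patients),
        n_with_variant=sum(1 for c in counts if c > 0),
        n_without_variant=sum(1 for c in counts if c == 0),
        n_multi_variant=sum(1 for c in counts if c > 1),
        max_variants_per_patient=max(counts, default=0),
        n_retained_variants=len(retained_uids),
        n_novel_variants=len(novel),
        n_known_variants=len(retained_uids) - len(novel),
        n_distinct_genes_known=len({v.gene for v in known}),
        carriers_per_variant=carriers,
        min_age=min(ages) if ages else 0,
        median_age=_median_lower(ages) if ages else 0.0,
        mean_age=sum(ages) / len(ages) if ages else 0.0,
        n_bilateral=sum(1 for p in patients if p.bilateral),
        n_lund_negative=sum(1 for p in patients if p.lund_negative),
    )


def validation_overlap(
    index_variants: Sequence[AnnotatedVariant],
    validation_cohort: Mapping[str, Iterable[Union[VariantKey, str]]],
) -> tuple[list[VariantKey], dict[str, int], set[str]]:
    """Look up index variants in an independent cohort's genotypes.

    Matching is on the genomic key so novel variants (no rsID) remain
    comparable; entries given as strings fall back to rsID/uid matching.
    Returns the shared keys, per-variant validation carrier counts (by
    uid), and the set of validation patients carrying >= 1 index variant.
    """
    by_key = {v.key.normalized(): v for v in index_variants}
    by_id = {v.uid: v for v in index_variants}
    counts: dict[str, int] = {}
    patients_hit: set[str] = set()
    shared: set[VariantKey] = set()
    for patient in sorted(validation_cohort):
        hit_here = set()
        for entry in validation_cohort[patient]:
            v = None
            if isinstance(entry, VariantKey):
                v = by_key.get(entry.normalized())
            else:
                v = by_id.get(str(entry))
            if v is not None:
                hit_here.add(v.uid)
                shared.add(v.key)
        for uid in hit_here:
            counts[uid] = counts.get(uid, 0) + 1
        if hit_here:
            patients_hit.add(patient)
    return sorted(shared), counts, patients_hit


# ------------------------------------------------------------------- fixture IO

def _opt_int(text: str) -> Optional[int]:
    text = str(text).strip()
    if text in ("", "NA"):
        return None
    try:
        return int(text)
    except ValueError:
        raise TableError(f"non-integer age {text!r}") from None


def read_patient_table(source: Union[str, TextIO]) -> list[PatientRecord]:
    """Read the patient TSV dialect (patient_id, lund_negative, age1, age2,
    triple_negative, histology, comma-separated variant_ids)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    df = df.fillna("")  # rows may omit trailing empty cells
    unknown = [c for c in df.columns if c not in PATIENT_COLUMNS]
    if unknown:
        raise TableError(f"unknown patient column(s): {unknown}")
    out = []
    for row in df.itertuples(index=False):
        ages = [a for a in (_opt_int(row.age1), _opt_int(row.age2)) if a is not None]
        tn_raw = str(row.triple_negative).strip()
        tn = None if tn_raw in ("", "NA") else bool(int(tn_raw))
        vids = [v.strip() for v in str(row.variant_ids).split(",") if v.strip()]
        out.append(PatientRecord(
            patient_id=str(row.patient_id).strip(),
            ages_at_diagnosis=ages,
            lund_negative=bool(int(str(row.lund_negative).strip() or "0")),
            triple_negative=tn,
            histology_text=str(row.histology).strip(),
            variant_ids=vids,
        ))
    return out


def write_patient_table(patients: Iterable[PatientRecord], dest) -> None:
    rows = []
    for p in patients:
        rows.append({
            "patient_id": p.patient_id,
            "lund_negative": int(p.lund_negative),
            "age1": p.ages_at_diagnosis[0],
            "age2": p.ages_at_diagnosis[1] if p.bilateral else "NA",
            "triple_negative": ("NA" if p.triple_negative is None
                                else int(p.triple_negative)),
            "histology": p.histology_text,
            "variant_ids": ",".join(p.variant_ids),
        })
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(dest, sep="\t", index=False)
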