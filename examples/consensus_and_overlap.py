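"""Dual-caller consensus intersection and validation-cohort overlap.

Builds two small discordant callsets (as two variant callers would emit),
intersects them, then looks the consensus variants up in a toy validation
cohort keyed by genomic position.
"""

from repairvar import VariantKey, consensus_merge, validation_overlap
from repairvar.variants import AnnotatedVariant, TranscriptAnnotation

caller_a = [VariantKey("1", 100, "A", "G"),
            VariantKey("1", 200, "CAA", "C"),      # deletion, trimmed form
            VariantKey("2", 50, "T", "C")]
caller_b = [VariantKey("chr1", 100, "A", "G"),     # chr prefix normalized away
            VariantKey("1", 200, "CAAA", "CA"),    # same deletion, padded
            VariantKey("3", 9, "G", "A")]

consensus = consensus_merge(caller_a, caller_b)
print("consensus keys:", [str(k) for k in consensus])
# two shared calls survive: the SNV and the (differently padded) deletion

index = [AnnotatedVariant(key=k,
                          annotation=TranscriptAnnotation(
                              gene_symbol="WRN",
                              consequence_terms=frozenset({"missense_variant"}),
                              is_canonical=True),
                          identifier=f"rs{k.pos}")
         for k in consensus]
validation = {"H1": [VariantKey("1", 100, "A", "G")],
              "H2": [VariantKey("1", 100, "A", "G"),
                     VariantKey("1", 200, "CAA", "C")],
              "H3": [VariantKey("9", 1, "A", "T")]}
shared, counts, patients = validation_overlap(index, validation)
print(f"shared with validation cohort: {len(shared)} variants, "
      f"{len(patients)} validation carriers")
print("per-variant validation carrier counts:", counts)
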