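"""Synthetic annotated cohorts with planted truth.

Real genotypes for cohorts like this are not shareable, so every pipeline
stage must be testable against generated data. The generator emulates the
statistical shape the cascade assumes — a DNA-repair panel restriction,
CADD/REVEL/AF values in configured strata, representation-level
missingness (unscored indels, unreported frequencies), heterozygous
carriers over a small patient set — and plants, per variant, an *intended
fate*: the stratum of the cascade that should decide it. Attribute values
are sampled strictly inside the relevant threshold interval with a margin,
so the fate is guaranteed by construction and a correct cascade must
recover every planted label exactly.

Randomness uses one seeded generator with splittable per-variant
substreams keyed by index, so enlarging a cohort never reshuffles the
variants already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .cohort_stats import PatientRecord
from .prioritization import FilterConfig
from .variants import AnnotatedVariant, TranscriptAnnotation, VariantKey

#: Planted fates: the cascade stratum that should decide each variant.
FATES = ("OFF_PANEL", "LOW_CADD", "COMMON_AF", "FAIL_REVEL",
         "STRICT_GROUP1", "STRICT_SUB1", "RELAXED_SUB2")

RETAINED_FATES = frozenset({"STRICT_GROUP1", "STRICT_SUB1", "RELAXED_SUB2"})

_MARGIN = 1e-6

_GROUP1_POOL = ("splice_acceptor_variant", "splice_donor_variant",
                "stop_gained", "start_lost")
_GROUP2_SNV = ("missense_variant",)
_GROUP2_INDEL = ("frameshift_variant", "inframe_deletion")

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: a 63-patient cohort screened over a gene
    panel, a minority of variants surviving each filter, indel-like CADD
    missingness and a small ultra-rare (AF-unreported) stratum."""

    n_patients: int = 63
    n_variants: int = 200
    fraction_off_panel: float = 0.30
    fraction_low_cadd: float = 0.15
    fraction_common_af: float = 0.15
    fraction_fail_revel: float = 0.10
    fraction_group1: float = 0.08          # strict-round Group 1 retainees
    fraction_relaxed_sub2: float = 0.07    # reachable only in round 2
    # remainder of the partition -> STRICT_SUB1
    fraction_missing_cadd: float = 0.10
    fraction_missing_revel: float = 0.30
    fraction_missing_af: float = 0.10      # ultra-rare stratum
    fraction_novel: float = 0.8            # ultra-rare variants without an rsID
    af_log10_range: tuple[float, float] = (-5.0, -2.2)
    carriers_per_variant_weights: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    seed: int = 0
    panel_symbols: Optional[tuple[str, ...]] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def fate_counts(self) -> dict[str, int]:
        """Integer counts per fate (largest-remainder rounding; the
        remainder of the partition goes to STRICT_SUB1)."""
        fracs = {
            "OFF_PANEL": self.fraction_off_panel,
            "LOW_CADD": self.fraction_low_cadd,
            "COMMON_AF": self.fraction_common_af,
            "FAIL_REVEL": self.fraction_fail_revel,
            "STRICT_GROUP1": self.fraction_group1,
            "RELAXED_SUB2": self.fraction_relaxed_sub2,
        }
        total = sum(fracs.values())
        if total > 1 + 1e-9:
            raise ConfigError(f"fate fractions sum to {total} > 1")
        counts = {k: int(math.floor(f * self.n_variants)) for k, f in fracs.items()}
        remainders = sorted(fracs, key=lambda k: (fracs[k] * self.n_variants) % 1,
                            reverse=True)
        short = round(total * self.n_variants) - sum(counts.values())
        for k in remainders[:max(short, 0)]:
            counts[k] += 1
        counts["STRICT_SUB1"] = self.n_variants - sum(counts.values())
        return counts

    def __post_init__(self):
        if self.n_patients < 1 or self.n_variants < 0:
            raise ConfigError("need n_patients >= 1 and n_variants >= 0")
        for name in ("fraction_off_panel", "fraction_low_cadd",
                     "fraction_common_af", "fraction_fail_revel",
                     "fraction_group1", "fraction_relaxed_sub2",
                     "fraction_missing_cadd", "fraction_missing_revel",
                     "fraction_missing_af", "fraction_novel"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} outside [0,1]: {v}")
        lo, hi = self.af_log10_range
        if not lo <= hi or 10 ** hi >= self.filter_config.af_strict:
            raise ConfigError("af_log10_range must lie below log10(af_strict)")
        w = self.carriers_per_variant_weights
        if not w or abs(sum(w) - 1) > 1e-9:
            raise ConfigError("carrier weights must sum to 1")
        counts = self.fate_counts()
        if counts["RELAXED_SUB2"] > 0 and \
                counts["STRICT_SUB1"] + counts["STRICT_GROUP1"] == 0:
            raise ConfigError(
                "RELAXED_SUB2 fates need at least one strict-round variant "
                "to anchor the affected-gene set")


def _default_panel_symbols() -> tuple[str, ...]:
    from .fixtures import load_default_panel
    return tuple(sorted(g.symbol for g in load_default_panel()))


def _rng_for(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, index])


def _rare_af(rng, cfg: SimulationConfig) -> float:
    lo, hi = cfg.af_log10_range
    return float(10 ** rng.uniform(lo, hi))


def _sample_afs(rng, cfg: SimulationConfig, value_fn) -> dict:
    """Fill the four gnomAD slots; each slot independently reported or not,
    but at least one reported (the ultra-rare stratum is planted separately)."""
    slots = ["af_exome_global", "af_genome_global", "af_exome_fin", "af_genome_fin"]
    present = rng.random(4) > 0.3
    if not present.any():
        present[int(rng.integers(4))] = True
    return {s: (value_fn() if p else None) for s, p in zip(slots, present)}


def generate_cohort(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[AnnotatedVariant], list[PatientRecord], dict[str, str]]:
    """Generate (variants, patients, truth) with planted per-variant fates.

    Deterministic for a fixed seed. ``truth`` maps each variant's uid to
    its fate label; the counts per fate follow
    :meth:`SimulationConfig.fate_counts` exactly.
    """
    cfg = config
    fc = cfg.filter_config
    panel = cfg.panel_symbols or _default_panel_symbols()
    counts = cfg.fate_counts()

    # Deterministic fate layout: fates in blocks, then values per variant
    # from its own substream.
    fate_list: list[str] = []
    for fate in FATES:
        fate_list.extend([fate] * counts[fate])

    # genes hosting strict-round variants anchor the RELAXED_SUB2 fates
    strict_idx = [i for i, f in enumerate(fate_list)
                  if f in ("STRICT_GROUP1", "STRICT_SUB1")]
    anchor_genes = [panel[i % len(panel)] for i in strict_idx]

    patient_ids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    variants: list[AnnotatedVariant] = []
    truth: dict[str, str] = {}
    strict_seen = 0

    for i, fate in enumerate(fate_list):
        rng = _rng_for(cfg.seed, i)
        chrom = str(1 + i % 22)
        pos = 10_000 + i * 37
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]

        if fate == "OFF_PANEL":
            gene = f"NONREPAIR{i}"
        elif fate == "RELAXED_SUB2":
            gene = anchor_genes[int(rng.integers(len(anchor_genes)))]
        elif fate in ("STRICT_GROUP1", "STRICT_SUB1"):
            gene = panel[strict_idx[strict_seen] % len(panel)]
            strict_seen += 1
        else:
            gene = panel[int(rng.integers(len(panel)))]

        cadd = float(rng.uniform(fc.cadd_min, 45.0))
        if fate == "LOW_CADD":
            cadd = float(rng.uniform(0.0, fc.cadd_min - _MARGIN))
        elif fate in RETAINED_FATES and rng.random() < cfg.fraction_missing_cadd:
            cadd = None

        terms = (_GROUP1_POOL[int(rng.integers(len(_GROUP1_POOL)))]
                 if fate == "STRICT_GROUP1"
                 else _GROUP2_SNV[0] if rng.random() < 0.8
                 else _GROUP2_INDEL[int(rng.integers(len(_GROUP2_INDEL)))])

        revel: Optional[float] = float(rng.uniform(fc.revel_strict + _MARGIN, 1.0))
        if fate == "FAIL_REVEL":
            revel = float(rng.uniform(0.0, fc.revel_relaxed - _MARGIN))
        elif fate == "STRICT_GROUP1":
            revel = None  # truncating alleles carry no missense score
        elif fate == "STRICT_SUB1" and rng.random() < cfg.fraction_missing_revel:
            revel = None

        identifier = f"rs{9_000_000 + i}"
        afs = _sample_afs(rng, cfg, lambda: _rare_af(rng, cfg))
        if fate == "COMMON_AF":
            afs = _sample_afs(rng, cfg,
                              lambda: float(rng.uniform(fc.af_relaxed + _MARGIN, 0.5)))
        elif fate == "RELAXED_SUB2":
            if rng.random() < 0.5:
                # rare but REVEL only clears the relaxed bar
                revel = float(rng.uniform(fc.revel_relaxed + _MARGIN,
                                          fc.revel_strict - _MARGIN))
            else:
                # REVEL clears strict, AF in the relaxed-only window
                afs = _sample_afs(rng, cfg, lambda: float(
                    rng.uniform(fc.af_strict + _MARGIN, fc.af_relaxed - _MARGIN)))
        elif fate in ("STRICT_GROUP1", "STRICT_SUB1") and \
                rng.random() < cfg.fraction_missing_af:
            afs = {k: None for k in afs}
            if rng.random() < cfg.fraction_novel:
                identifier = None  # a novel allele: no rsID, no reported AF

        if fate == "STRICT_GROUP1":
            frameshifty = False
        else:
            frameshifty = terms in _GROUP2_INDEL

        k_weights = np.asarray(cfg.carriers_per_variant_weights)
        n_carriers = int(rng.choice(np.arange(1, len(k_weights) + 1), p=k_weights))
        n_carriers = min(n_carriers, cfg.n_patients)
        carriers = {str(s) for s in rng.choice(patient_ids, size=n_carriers,
                                               replace=False)}

        ann = TranscriptAnnotation(
            gene_symbol=gene,
            consequence_terms=frozenset([terms] if isinstance(terms, str) else terms),
            is_canonical=True,
            hgvs_c=f"c.{100 + i}{ref}>{alt}" if not frameshifty else f"c.{100 + i}del",
        )
        v = AnnotatedVariant(
            key=VariantKey(chrom, pos, ref, alt),
            annotation=ann,
            identifier=identifier,
            cadd_phred=cadd,
            revel=revel,
            carriers=carriers,
            **afs,
        )
        variants.append(v)
        truth[v.uid] = fate

    patients = _generate_patients(cfg, patient_ids, variants, truth)
    return variants, patients, truth


def _generate_patients(cfg: SimulationConfig, patient_ids: Sequence[str],
                       variants: Sequence[AnnotatedVariant],
                       truth: dict[str, str]) -> list[PatientRecord]:
    carried: dict[str, list[str]] = {p: [] for p in patient_ids}
    for v in variants:
        if truth[v.uid] in RETAINED_FATES:
            for p in sorted(v.carriers):
                carried[p].append(v.uid)
    out = []
    for j, pid in enumerate(patient_ids):
        rng = _rng_for(cfg.seed, 1_000_000 + j)
        ages = [int(rng.integers(23, 41))]
        if rng.random() < 0.19:
            ages.append(int(rng.integers(ages[0], min(ages[0] + 30, 80))))
        out.append(PatientRecord(
            patient_id=pid,
            ages_at_diagnosis=ages,
            lund_negative=bool(rng.random() < 0.286),
            triple_negative=bool(rng.random() < 0.19),
            histology_text="synthetic",
            variant_ids=carried[pid],
        ))
    return out
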