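"""Two-round rare-variant prioritization cascade.

The cascade screens a cohort's annotated germline variants for candidate
risk alleles in DNA-repair genes:

Round 1 (strict) — keep a variant iff it

1. lies in a panel gene,
2. has CADD PHRED >= 20 (missing scores retained: indels are often unscored),
3. is annotated on the canonical transcript (non-transcript annotations
   such as downstream-gene records are retained too),
4. is rare — every reported gnomAD frequency (exome/genome, global/FIN)
   below 0.01 — or ultra-rare (no frequency reported at all), and
5. is consequence Group 1 (truncating / splice-site-altering) or Group 2
   (missense / non-synonymous) with REVEL > 0.75 or missing.

Group 2 retainees of this round are *subcategory 1*.

Round 2 (relaxed) — to catch milder alleles in the genes the project is
about, the allele-frequency and REVEL thresholds alone are relaxed
(AF < 0.02, REVEL > 0.4) and the remaining variants in the affected genes
are re-screened; Group 2 retainees are *subcategory 2*. Which genes count
as "affected" is configurable: the published behavior re-screens every
gene surviving the general filter (panel + CADD + canonical), a stricter
alternative limits round 2 to genes hosting a round-1 retainee.

Missing-value semantics are uniform: a missing score never excludes a
variant (the data, not the variant, is deficient), while a reported value
of exactly 0 is a present value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .errors import ConfigError, InputError
from .gene_panel import PanelGene, PanelIndex
from .variants import AnnotatedVariant, TranscriptAnnotation, VariantKey

#: Consequence terms describing annotations not tied to any transcript model;
#: such variants survive the canonical-transcript rule.
NON_TRANSCRIPT_TERMS = frozenset({
    "intergenic_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "regulatory_region_variant",
})

DEFAULT_GROUP1_TERMS = frozenset({
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_polypyrimidine_tract_variant",
    "stop_gained",
    "start_lost",
    "non_coding_transcript_exon_variant",
})

DEFAULT_GROUP2_TERMS = frozenset({
    "missense_variant",
    "frameshift_variant",
    "inframe_deletion",
    "inframe_insertion",
    "protein_altering_variant",
    "downstream_gene_variant",
})


class Group(enum.Enum):
    GROUP1 = "GROUP1"
    GROUP2 = "GROUP2"
    OTHER = "OTHER"


class Subcategory(enum.Enum):
    SUB1 = "SUB1"
    SUB2 = "SUB2"
    NONE = "NONE"


class AfClass(enum.Enum):
    RARE = "RARE"
    ULTRA_RARE = "ULTRA_RARE"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and term sets of the cascade. Defaults are the published
    profile; every knob is overridable (e.g. from a YAML file)."""

    cadd_min: float = 20.0
    af_strict: float = 0.01
    af_relaxed: float = 0.02
    revel_strict: float = 0.75
    revel_relaxed: float = 0.4
    group1_terms: frozenset[str] = DEFAULT_GROUP1_TERMS
    group2_terms: frozenset[str] = DEFAULT_GROUP2_TERMS
    retain_missing_cadd: bool = True
    retain_missing_revel: bool = True
    retain_missing_af: bool = True
    #: "general_filter": round 2 re-screens every gene surviving
    #: panel+CADD+canonical (published behavior); "strict_retained":
    #: only genes hosting a round-1 retainee.
    relaxed_gene_source: str = "general_filter"

    def __post_init__(self):
        if not (0 <= self.af_strict <= self.af_relaxed <= 1):
            raise ConfigError("require 0 <= af_strict <= af_relaxed <= 1")
        if not (0 <= self.revel_relaxed <= self.revel_strict <= 1):
            raise ConfigError("require 0 <= revel_relaxed <= revel_strict <= 1")
        if self.cadd_min < 0:
            raise ConfigError("cadd_min must be >= 0")
        # frozensets survive YAML round-trips as lists
        object.__setattr__(self, "group1_terms", frozenset(self.group1_terms))
        object.__setattr__(self, "group2_terms", frozenset(self.group2_terms))
        if self.group1_terms & self.group2_terms:
            raise ConfigError("group1_terms and group2_terms must be disjoint")
        if self.relaxed_gene_source not in ("general_filter", "strict_retained"):
            raise ConfigError(f"unknown relaxed_gene_source {self.relaxed_gene_source!r}")

    @classmethod
    def published(cls) -> "FilterConfig":
        """The profile reproducing the published screen."""
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["group1_terms"] = sorted(self.group1_terms)
        d["group2_terms"] = sorted(self.group2_terms)
        return d


@dataclass
class PriorityCall:
    """The cascade's verdict for one variant, with its full rule trail."""

    key: VariantKey
    gene: str
    retained: bool
    group: Group
    subcategory: Subcategory
    af_class: AfClass
    rule_trace: list[tuple[str, str, object]] = field(default_factory=list)
    uid: str = ""
    #: which round retained the variant: "strict", "relaxed" or "" (rejected)
    round: str = ""

    def trace_text(self) -> str:
        return ";".join(f"{r}={o}({v})" for r, o, v in self.rule_trace)


# ------------------------------------------------------------ rule functions

def cadd_pass(score: Optional[float], config: FilterConfig) -> bool:
    """CADD rule: scores below ``cadd_min`` are excluded; a score of exactly
    ``cadd_min`` and missing scores are retained."""
    if score is None:
        return config.retain_missing_cadd
    if score < 0:
        raise InputError(f"negative CADD score {score}")
    return score >= config.cadd_min


def transcript_filter(
    annotations: Sequence[TranscriptAnnotation],
) -> Optional[TranscriptAnnotation]:
    """Choose the annotation the cascade evaluates.

    Canonical wins. Failing that, a variant annotated *only* with
    non-transcript consequences (intergenic, upstream, downstream, ...)
    keeps its first annotation. Variants with only non-canonical transcript
    annotations are dropped.
    """
    for ann in annotations:
        if ann.is_canonical:
            return ann
    if annotations and all(
            ann.consequence_terms <= NON_TRANSCRIPT_TERMS for ann in annotations):
        return annotations[0]
    return None


def af_class(variant: AnnotatedVariant, threshold: float) -> AfClass:
    """Stratify by reported gnomAD frequencies.

    ULTRA_RARE: no frequency reported in any of the four slots.
    EXCLUDED: any reported frequency at or above the threshold.
    RARE: at least one frequency reported and all below the threshold.
    """
    present = [f for f in variant.allele_frequencies if f is not None]
    if not present:
        return AfClass.ULTRA_RARE
    if any(f >= threshold for f in present):
        return AfClass.EXCLUDED
    return AfClass.RARE


def consequence_group(terms: Iterable[str], config: FilterConfig) -> Group:
    """Assign the consequence stratum; Group 1 wins on overlap."""
    terms = set(terms)
    if terms & config.group1_terms:
        return Group.GROUP1
    if terms & config.group2_terms:
        return Group.GROUP2
    return Group.OTHER


def revel_pass(score: Optional[float], threshold: float,
               config: FilterConfig) -> bool:
    """REVEL rule: strictly greater than the threshold, or missing."""
    if score is None:
        return config.retain_missing_revel
    if not (0.0 <= score <= 1.0):
        raise InputError(f"REVEL score outside [0,1]: {score}")
    return score > threshold


# --------------------------------------------------------------- the cascade

def _dedupe(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    seen, out = set(), []
    for v in variants:
        k = (v.key, v.gene)
        if k not in seen:
            seen.add(k)
            out.append(v)
    return out


def passes_general_filter(v: AnnotatedVariant, panel: PanelIndex,
                          config: FilterConfig) -> bool:
    """Panel + CADD + canonical-transcript — the rules both rounds share."""
    return (
        panel.lookup(v.gene, v.annotation.gene_id) is not None
        and cadd_pass(v.cadd_phred, config)
        and (v.annotation.is_canonical
             or v.annotation.consequence_terms <= NON_TRANSCRIPT_TERMS)
    )


def _evaluate(v: AnnotatedVariant, panel: PanelIndex, config: FilterConfig,
              af_threshold: float, revel_threshold: float) -> PriorityCall:
    trace: list[tuple[str, str, object]] = []
    panel_ok = panel.lookup(v.gene, v.annotation.gene_id) is not None
    trace.append(("panel", "pass" if panel_ok else "fail", v.gene))
    cadd_ok = cadd_pass(v.cadd_phred, config)
    trace.append(("cadd", "pass" if cadd_ok else "fail", v.cadd_phred))
    canon_ok = (v.annotation.is_canonical
                or v.annotation.consequence_terms <= NON_TRANSCRIPT_TERMS)
    trace.append(("canonical", "pass" if canon_ok else "fail",
                  v.annotation.is_canonical))
    cls = af_class(v, af_threshold)
    af_ok = cls is not AfClass.EXCLUDED
    trace.append(("af", "pass" if af_ok else "fail",
                  f"{cls.value}@{af_threshold:g}"))
    group = consequence_group(v.annotation.consequence_terms, config)
    trace.append(("group", group.value,
                  "&".join(sorted(v.annotation.consequence_terms))))
    if group is Group.GROUP2:
        rv_ok = revel_pass(v.revel, revel_threshold, config)
        trace.append(("revel", "pass" if rv_ok else "fail",
                      f"{v.revel}@{revel_threshold:g}"))
    else:
        rv_ok = True
        trace.append(("revel", "skip", v.revel))
    retained = (panel_ok and cadd_ok and canon_ok and af_ok
                and group is not Group.OTHER and rv_ok)
    sub = Subcategory.NONE
    return PriorityCall(key=v.key, gene=v.gene, retained=retained, group=group,
                        subcategory=sub, af_class=cls, rule_trace=trace,
                        uid=v.uid)


def run_strict(
    variants: Iterable[AnnotatedVariant],
    panel: Iterable[PanelGene],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[PriorityCall], set[str]]:
    """Round 1. Returns the retained calls (Group 2 retainees marked
    subcategory 1) and the set of gene symbols they affect."""
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    retained = []
    for v in _dedupe(variants):
        call = _evaluate(v, index, config, config.af_strict, config.revel_strict)
        if call.retained:
            call.round = "strict"
            if call.group is Group.GROUP2:
                call.subcategory = Subcategory.SUB1
            retained.append(call)
    return retained, {c.gene for c in retained}


def run_relaxed(
    all_variants: Iterable[AnnotatedVariant],
    affected_genes: set[str],
    config: FilterConfig = FilterConfig(),
    panel: Iterable[PanelGene] = (),
    already_retained: Iterable[tuple[VariantKey, str]] = (),
) -> list[PriorityCall]:
    """Round 2: re-screen variants in the affected genes with the relaxed
    AF and REVEL thresholds (panel, CADD and canonical rules unchanged).
    Variants already retained by round 1 are excluded from the output;
    Group 2 retainees are marked subcategory 2."""
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    done = set(already_retained)
    out = []
    for v in _dedupe(all_variants):
        if v.gene not in affected_genes or (v.key, v.gene) in done:
            continue
        call = _evaluate(v, index, config, config.af_relaxed, config.revel_relaxed)
        if call.retained:
            call.round = "relaxed"
            if call.group is Group.GROUP2:
                call.subcategory = Subcategory.SUB2
            out.append(call)
    return out


def classify(
    variants: Sequence[AnnotatedVariant],
    panel: Iterable[PanelGene],
    config: FilterConfig = FilterConfig(),
) -> list[PriorityCall]:
    """Run the full two-round cascade; one call per distinct (key, gene).

    The returned list follows the (deduplicated) input order and contains a
    call for every variant, retained or not, with the strict-round rule
    trail (plus the relaxed trail when round 2 re-evaluated the variant).
    The retained set is independent of input order.
    """
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    uniq = _dedupe(variants)

    strict_calls = {}
    for v in uniq:
        call = _evaluate(v, index, config, config.af_strict, config.revel_strict)
        if call.retained:
            call.round = "strict"
            if call.group is Group.GROUP2:
                call.subcategory = Subcategory.SUB1
        strict_calls[(v.key, v.gene)] = call

    if config.relaxed_gene_source == "strict_retained":
        affected = {c.gene for c in strict_calls.values() if c.retained}
    else:
        affected = {v.gene for v in uniq if passes_general_filter(v, index, config)}

    out = []
    for v in uniq:
        call = strict_calls[(v.key, v.gene)]
        if not call.retained and v.gene in affected:
            relaxed = _evaluate(v, index, config,
                                config.af_relaxed, config.revel_relaxed)
            if relaxed.retained:
                relaxed.round = "relaxed"
                if relaxed.group is Group.GROUP2:
                    relaxed.subcategory = Subcategory.SUB2
                relaxed.rule_trace = call.rule_trace + relaxed.rule_trace
                call = relaxed
            else:
                call.rule_trace = call.rule_trace + relaxed.rule_trace
        out.append(call)
    return out


def retained(calls: Iterable[PriorityCall]) -> list[PriorityCall]:
    return [c for c in calls if c.retained]
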