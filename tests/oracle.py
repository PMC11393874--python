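"""Independent brute-force re-statement of the cascade.

Each round's retention predicate is written as one flat boolean expression
over the raw attribute values, with no shared code with the package's
cascade; used to cross-check `classify` variant-for-variant.
"""

from repairvar import FilterConfig
from repairvar.prioritization import NON_TRANSCRIPT_TERMS


def _afs(v):
    return [f for f in (v.af_exome_global, v.af_genome_global,
                        v.af_exome_fin, v.af_genome_fin) if f is not None]


def _keep(v, panel_symbols, cfg: FilterConfig, af_thr, revel_thr):
    terms = set(v.annotation.consequence_terms)
    return (
        v.gene.upper() in panel_symbols
        and (v.cadd_phred is None or v.cadd_phred >= cfg.cadd_min)
        and (v.annotation.is_canonical or terms <= NON_TRANSCRIPT_TERMS)
        and all(f < af_thr for f in _afs(v))
        and (
            bool(terms & cfg.group1_terms)
            or (bool(terms & cfg.group2_terms)
                and (v.revel is None or v.revel > revel_thr))
        )
    )


def oracle_retained(variants, panel, cfg: FilterConfig):
    """Set of uids the cascade must retain, by brute-force enumeration."""
    symbols = {g.symbol.upper() for g in panel} | {
        a.upper() for g in panel for a in g.aliases}
    seen, uniq = set(), []
    for v in variants:
        if (v.key, v.gene) not in seen:
            seen.add((v.key, v.gene))
            uniq.append(v)
    strict = {v.uid for v in uniq
              if _keep(v, symbols, cfg, cfg.af_strict, cfg.revel_strict)}
    if cfg.relaxed_gene_source == "strict_retained":
        genes = {v.gene for v in uniq if v.uid in strict}
    else:
        genes = {v.gene for v in uniq
                 if v.gene.upper() in symbols
                 and (v.cadd_phred is None or v.cadd_phred >= cfg.cadd_min)
                 and (v.annotation.is_canonical
                      or set(v.annotation.consequence_terms) <= NON_TRANSCRIPT_TERMS)}
    relaxed = {v.uid for v in uniq
               if v.uid not in strict and v.gene in genes
               and _keep(v, symbols, cfg, cfg.af_relaxed, cfg.revel_relaxed)}
    return strict | relaxed
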