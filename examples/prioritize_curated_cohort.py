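"""Run the two-round cascade on the packaged curated cohort.

Loads the 72-variant curated table and the frozen DNA-repair panel, runs
the published filtering profile, and prints the retention breakdown.
"""

from collections import Counter

from repairvar import FilterConfig, classify, load_default_panel, load_table1_fixture, retained

variants = load_table1_fixture()
panel = load_default_panel()
calls = classify(variants, panel, FilterConfig.published())
kept = retained(calls)

print(f"input variants:    {len(variants)}")
print(f"retained:          {len(kept)}")
by_group = Counter(c.group.value for c in kept)
by_sub = Counter(c.subcategory.value for c in kept)
print(f"by consequence group: {dict(by_group)}")
print(f"by subcategory:       {dict(by_sub)}")

# GROUP1 = truncating / splice-site-altering alleles (no REVEL filter);
# SUB1 = strict-round missense retainees (AF<0.01, REVEL>0.75 or missing);
# SUB2 = relaxed-round retainees (AF<0.02, REVEL>0.4) in already-hit genes.
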