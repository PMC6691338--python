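"""Prioritize cancer indications from a published target-enrichment screen.

Loads the bundled berberine screen (18 raw one-sided Fisher P-values, one
per cancer type), applies the single-step multiplicative correction over the
24 cancer types originally tested, and reports significance and literature
validation — reproducing the screen's printed arithmetic.
"""

import math

from netpharm import CorrectionConfig, correct_pvalues, load_indication_fixture

table = load_indication_fixture()
qs = correct_pvalues(list(table["p_raw"]), CorrectionConfig("multiplicative", m=24))

print(f"{'cancer':8s} {'raw P':>10s} {'adj P':>10s} {'-log10(q)':>9s}  validated")
n_sig = n_val = 0
for (_, row), q in zip(table.iterrows(), qs):
    significant = q < 0.05
    validated = row["pmids"] != "N/A"
    n_sig += significant
    n_val += significant and validated
    print(f"{row['cancer_type']:8s} {row['p_raw']:10.2e} {q:10.2e} "
          f"{-math.log10(q):9.2f}  {'yes' if validated else 'no'}")

print(f"\nsignificant at q < 0.05 : {n_sig}")
print(f"literature-validated    : {n_val}")
print(f"success rate            : {100 * n_val / n_sig:.1f}%")
# A cancer type is "significant" when the drug's targets overlap its
# significantly mutated genes more than chance after multiplicity correction;
# "validated" means at least one published study supports the indication.
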