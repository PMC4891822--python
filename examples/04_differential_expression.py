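"""TPM normalisation, the exact count test and regulation classes.

Demonstrates the conditional point mass p(y|x), the doubled-tail p-value,
and the five-way classification on hand-picked count pairs.
"""

from srnakit.diffexpr import (
    DiffExprPair,
    audic_point_mass,
    audic_pvalue,
    classify,
    profile_table,
    tpm_normalize,
)

N1 = N2 = 1_000_000  # total clean reads per library

print("point mass p(5|5), equal totals:", audic_point_mass(5, 5, N1, N2))  # 252/2048
print("two-sided p for 100 vs 200 reads:", f"{audic_pvalue(DiffExprPair(100, 200, N1, N2)):.3g}")

print("\nTPM: 2 reads in a 1M-read library ->", tpm_normalize(2, N1), "TPM")

cases = {
    "strong_down": (800, 150),   # |log2FC| >= 1 and p < 0.05
    "slight_up": (600, 840),     # 0.25 <= |log2FC| < 1
    "control_only": (120, 0),    # zero treatment count -> 0.01 TPM substitute
    "flat": (500, 505),          # |log2FC| < 0.25
    "low_abundance": (1, 1),     # below the 2-TPM floor in both libraries
}
df = profile_table({k: v for k, v in cases.items()}, N1, N2)
print("\n" + df.to_string(index=False))
# Sequences under 2 TPM in both libraries are dropped before the category
# tallies; the 0.01 substitution only feeds log2FC, never the p-value.
p = classify("demo", 2, 0, N1, N2)
print(f"\n2 vs 0 reads: log2FC={p.log2fc:.2f} but p={p.p_value:.2f} -> {p.category}")
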