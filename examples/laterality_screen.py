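"""Score laterality phenotypes and compare frequencies against a control.

Draws 100 embryos from a mutant-like phenotype mix (40% normal, 35%
inverse, 25% no laterality), classifies each from the lateral offset of
the proventriculus–midgut joint, and runs a chi-square test against
control (wild-type-like) frequencies.
"""

from ribcage import chi_square_frequencies, classify_laterality, generate_laterality_sample

sample = generate_laterality_sample(
    p_normal=0.40, p_inverse=0.35, p_none=0.25, n=100, seed=11, overlap_halfwidth_um=2.0
)
calls = [classify_laterality(offset, overlap_halfwidth_um=2.0) for offset, _ in sample]
counts = {cat: calls.count(cat) for cat in ("normal", "no_laterality", "inverse")}
print("observed phenotype counts:", counts)

control = [95, 3, 2]  # control cohort: almost all embryos have normal situs
observed = [counts["normal"], counts["no_laterality"], counts["inverse"]]
result = chi_square_frequencies(observed, control)
print(f"chi-square vs control frequencies: statistic = {result.statistic:.2f}, "
      f"df = {result.df[0]}, p = {result.p:.2e}")
# A small p-value says the mutant-like phenotype frequencies differ from
# the control cohort's — i.e. laterality is randomized.
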