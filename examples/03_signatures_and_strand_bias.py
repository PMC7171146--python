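"""Refit a mutation catalog against reference signatures; test strand bias.

Draws a 10,000-mutation catalog from a planted 0.6/0.3/0.1 mixture of
synthetic signature profiles, applies the standard somatic-SNV filter
(autosomal, not in population resources, alt support >= 10), collapses to
the 96-channel spectrum and solves the non-negative least squares refit.
A second catalog is drawn with a planted transcriptional strand asymmetry
and tested with the exact conditional (binomial) form of the Poisson test.
"""

from uvmtk import PipelineConfig
from uvmtk.signatures import (
    build_96_vector, filter_for_signatures, fit_signatures, strand_bias_table,
)
from uvmtk.simulate import simulate_mutation_catalog, synthetic_signature_set

config = PipelineConfig()
sigs = synthetic_signature_set(3, seed=0)

catalog = simulate_mutation_catalog([0.6, 0.3, 0.1], 10_000, sigs, seed=1)
kept = filter_for_signatures(catalog, config)
fit = fit_signatures(build_96_vector(kept), sigs)
print("relative contributions (planted 0.6 / 0.3 / 0.1):")
print(fit.relative.round(4).to_string())

biased = simulate_mutation_catalog(
    [1.0, 0.0, 0.0], 3000, sigs, seed=2, transcribed_fraction=0.3
)
bias = strand_bias_table(biased)
print("\nstrand bias per substitution class (planted 30% transcribed):")
print(bias.round(4).to_string(index=False))
# Relative contributions recover the planted mixture to ~1% L1 error at
# this catalog size; classes with enough stranded mutations show q < 0.05
# for the planted untranscribed-strand excess.
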