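"""In-silico PCR: score a groundwater amplicon primer pair against a
reference database with planted mismatch patterns."""

from cprkit.primer_silico import BAKT341F, BAKT785R, coverage_by_class
from cprkit.synthetic import PrimerSiteDesign, SynthConfig, simulate_reference_db

# per class: 8 perfect sites, 1 with two internal mismatches (still
# amplifiable at budget 2), 1 with a broken 3' dinucleotide -> 90% truth
config = SynthConfig(seed=7)
seqs, taxonomy, truth = simulate_reference_db(config)

report = coverage_by_class(seqs, taxonomy, BAKT341F, BAKT785R, budget=2)
print(report.to_string(index=False))
print("\nplanted coverage per class:", truth.primer_coverage)
print("A sequence counts as amplifiable when both primers place with at most")
print("two mismatches and a perfect two-base 3' anchor, in amplifiable order.")
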