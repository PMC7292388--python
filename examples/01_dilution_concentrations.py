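"""Compute a log10 E. coli concentration from a multi-dilution plate series.

A drain-water sample was plated at two ten-fold dilutions.  The countable
plates imply concentrations per 100 mL; averaging on the log10 scale gives
the sample's concentration estimate.
"""

from sanipath import DilutionReading, EnvironmentalSample, combine_dilutions, \
    default_config

sample = EnvironmentalSample(
    sample_id="drain-001",
    sample_type="drain_water",
    neighborhood="demo-town",
    readings=(
        DilutionReading(dilution_factor=1e-2, amount_assayed=1.0, count=45),
        DilutionReading(dilution_factor=1e-3, amount_assayed=1.0, count=5),
    ),
    denominator_unit="per_100mL",
)

est = combine_dilutions(sample, default_config())
print(f"sample {est.sample_id}: {est.log10_concentration:.3f} "
      f"log10 E. coli per 100 mL ({est.censoring})")
print(f"readings used: {est.readings_used}, conflicts: {list(est.conflicts)}")
# Only the 45-colony plate falls in the countable range (20-200), so the
# selection step uses it alone: 45 / (1 mL x 1e-2) x 100 = 4.5e5 CFU/100 mL,
# i.e. 5.653 on the log10 scale. The 5-colony plate still participates in
# the between-dilution consistency check (no conflict here: it implies
# 5.0e5, well within the 10x factor).
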