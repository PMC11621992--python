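"""Build a small job-exposure matrix from source measurements.

The matrix cell for an occupation holds a dimensionless intensity — the
squared ratio of the mean field level to the frequency-specific
occupational reference level, proportional to SAR above 100 kHz — and the
prevalence of exposure among workers holding that occupation.
"""

from rfjem import (
    Jem,
    JemEntry,
    SourceMeasurement,
    icnirp_squared_ratio,
    median_prevalence_threshold,
)

# two RF sources measured at different frequencies (E field, V/m)
dielectric_heater = SourceMeasurement("dielectric_heater", 27e6, "E",
                                      mean_field=45.0, reference_level=61.0)
plastic_welder = SourceMeasurement("plastic_welder", 13.56e6, "E",
                                   mean_field=90.0, reference_level=61.0)

for src in (dielectric_heater, plastic_welder):
    ratio = icnirp_squared_ratio(src)
    print(f"{src.source_id}: ({src.mean_field}/{src.reference_level})^2 "
          f"= {ratio:.3f}  (dimensionless, ~ SAR)")

# a matrix over three occupations; zero prevalence means unexposed
jem = Jem([
    JemEntry("8253", "E", intensity=icnirp_squared_ratio(plastic_welder),
             prevalence=0.21, n_basis=6),   # plastic products machine operators
    JemEntry("7341", "E", intensity=icnirp_squared_ratio(dielectric_heater),
             prevalence=0.04, n_basis=3),
    JemEntry("4115", "E", intensity=0.0, prevalence=0.0, n_basis=0),  # secretaries
])

threshold = median_prevalence_threshold(jem, "E")
print(f"\nmedian prevalence among exposed occupations: {threshold:.3f}")
print("under the prevalence-restricted linkage (Method 2), occupations below")
print(f"this threshold are treated as unexposed: 7341 gated out "
      f"({jem.prevalence('7341', 'E'):.2f} < {threshold:.3f}), 8253 kept")
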