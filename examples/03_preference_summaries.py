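"""Turn posterior part-worths into reporting summaries.

Uses a small fitted posterior to compute the three standard outputs:
utilities scaled to -10..+10, relative importance of each attribute (sums
to 100), and the marginal rate of substitution — how many extra percentage
points of remission chance patients would need to accept each undesirable
attribute.
"""

import partworth as pw

schema = pw.crohn_schema()
coding = pw.CodingMap.from_schema(schema)
design = pw.generate_design(schema, n_versions=25, seed=1)
prefs = pw.simulate_population(pw.crohn_population(n_respondents=80), seed=2)
choices = pw.simulate_choices(design, prefs, coding, seed=3)
settings = pw.MCMCSettings(n_chains=3, n_burnin=800, n_monitor=1600, thin=4, seed=4)
posterior = pw.fit_hb(choices, design, coding, settings)

scaled = pw.scale_utilities(posterior, schema, coding)
print("scaled utilities (-10 strong aversion ... +10 strong preference):")
print(scaled.table.round(2).to_string(index=False))

ri = pw.relative_importance(posterior, schema, coding)
print("\nrelative importance (% of total utility range, sums to 100):")
print(ri.round(1).to_string(index=False))

table = pw.mrs(posterior, schema, coding)
print("\nmarginal rates of substitution (remission points required):")
print(table.round(1).to_string(index=False))

# Example reading: an MRS of 13 for infection/cancer means the average
# respondent would accept that risk only for a treatment offering a 13-point
# higher absolute chance of remission.
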