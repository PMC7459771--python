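# Default method profile: the Slovak Ca/Mg case-study configuration.
# Exposure: 70 kg adult, 2 L/day, year-round; UF 2.0; table-reproducing
# cause-of-death weights; transform-of-summary group convention.

uf = 2.0
display_rounding = true
summary_convention = "transform-of-summary"
mrc_source_group = "soft"
elements = ["Ca", "Mg", "Ca+Mg"]

[exposure]
body_weight = 70.0
intake_rate = 2.0
exposure_frequency = 365.0
exposure_duration = 1.0
averaging_time = 365.0

[weights]
ReC = 0.50
ReI = 0.25
ReJ = 0.06
ReK = 0.07

# National reference health indicators (deaths per 100,000, Slovak Republic).
[national_reference]
rec = 212.79
rei = 531.05
rej = 58.08
rek = 45.83
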