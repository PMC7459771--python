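# Published cause-specific relative mortality (deaths per 100,000, 15-year
# Bayesian average) for the soft- and hard-water municipality groups and the
# Slovak Republic national baseline; le = life expectancy at birth, years.
group,le,rec,rei,rej,rek
soft,69.40,282.53,852.42,100.92,82.65
hard,74.68,171.11,455.11,45.37,34.27
Slovak Republic,72.60,212.79,531.05,58.08,45.83
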