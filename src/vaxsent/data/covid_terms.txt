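# Stage-1 thematic filter: COVID-related terms (editable default).
# One term per line; '#' starts a comment. Matching is word-bounded and
# case-insensitive by default, so inflected forms must be listed explicitly.
covid
covid-19
covid19
coronavirus
sars-cov-2
pandemic
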