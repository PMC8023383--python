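# Stage-2 thematic filter: vaccine-related terms.
vaccine
vaccination
immunise
immunize
immunisation
immunization
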