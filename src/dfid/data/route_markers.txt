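# Route-indicating marker terms for monograph-title segmentation.
# One term per line; matching is whole-token and case-insensitive.
nasal
ophthalmic
otic
oral
rectal
vaginal
topical
transdermal
injection
inhalation
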