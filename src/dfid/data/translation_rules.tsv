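phrase	replacement
by mouth	oral
into nose	nasal
into the nose	nasal
in nose	nasal
into ear	otic
into the ear	otic
into the ears	otic
in ear	otic
in the ear	otic
in the ears	otic
on skin	topical
on the skin	topical
to the skin	topical
in eye	ophthalmic
in the eye	ophthalmic
in the eyes	ophthalmic
to the eye	ophthalmic
to the eyes	ophthalmic
into the eye	ophthalmic
into the eyes	ophthalmic
into the rectum	rectal
into the vagina	vaginal
under the skin	subcutaneous
into a vein	intravenous
into a muscle	intramuscular
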