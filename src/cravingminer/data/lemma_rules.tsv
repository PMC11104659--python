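# Deterministic suffix-stripping lemmatizer rule table.
# Lines: keep <word>          -- word is never altered (lexicalized -ing nouns etc.)
#        rule <suffix> <replacement|-> <min_stem_len> [flag]
# Rules are tried in file order; the first applicable rule fires, once.
# Flags: sibilant  -- only strip when the stem ends in s/x/z/ch/sh
#        nosui     -- skip when the token ends in ss/us/is
#        undouble  -- collapse a trailing doubled consonant (except ll/ss/ff/zz)
keep craving
keep feeling
keep feelings
keep meeting
keep morning
keep evening
keep wedding
keep thing
keep things
keep something
keep nothing
keep anything
keep everything
keep bring
keep king
keep ring
keep sing
keep spring
keep string
keep swing
keep during
keep boring
keep pregaming
keep quarantining
keep networking
rule ies y 3
rule es - 3 sibilant
rule s - 3 nosui
rule ing - 3 undouble
rule ed - 3 undouble
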