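group,category,terms
substance,nicotine,nicotine;smoking;smoke;cigarette;cigarettes;vape;vaping;tobacco;juul
emotion,depression,depression;depressive;depressed
emotion,anxiety,anxiety;panic;worry;worrying;nervous
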