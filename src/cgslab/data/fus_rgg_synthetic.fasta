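>FUS_RGG_SYNTHETIC synthetic RGG-style 50-mer, charge-composition matched (6 negative, 9 positive)
GGRGGDRGGFRGGERGGYSGRGGDRGGYGGDRGGFRGGERGGYGGDMGSY
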