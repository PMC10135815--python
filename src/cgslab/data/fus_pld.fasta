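>FUS_PLD FUS residues 1-50 (prion-like domain N-terminal fragment)
MASNDYTQQATQSYGAYPTQPGQGYSQQSSQPYGQQSYSGYSQSTDTSGY
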