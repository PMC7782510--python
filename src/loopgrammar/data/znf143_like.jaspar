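>ZNF143_like
A [ 5 5 5 5 5 85 15 85 85 5 5 15 85 5 ]
C [ 5 5 85 85 85 5 10 5 5 5 5 55 5 5 ]
G [ 5 5 5 5 5 5 60 5 5 5 85 15 5 5 ]
T [ 85 85 5 5 5 5 15 5 5 85 5 15 5 85 ]
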