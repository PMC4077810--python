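year,rest,graze,walk,relocate
2008,34.7,42.3,20.2,2.8
2009,30.8,43.0,22.6,3.6
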