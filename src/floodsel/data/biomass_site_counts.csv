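year,secondary_floodplain,tertiary_floodplain,grassland,riparian_woodland
2008,36,50,37,34
2009,10,30,30,31
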