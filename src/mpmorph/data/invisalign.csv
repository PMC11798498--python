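source_id,particle_id,area_um2,major_um,minor_um
invisalign,7a,153.32,12.02,6.33
invisalign,7b,441.05,20.89,9.15
invisalign,7c,144.29,16.05,7.20
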