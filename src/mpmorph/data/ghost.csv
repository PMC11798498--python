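source_id,particle_id,area_um2,major_um,minor_um
ghost,10a,1011.41,44.67,28.78
ghost,10b,4383.42,80.72,71.51
ghost,10c,652.08,34,24
ghost,10d,2255.40,,
ghost,10e,1256.21,39.81,7.49
ghost,10f,179.65,17.29,10.07
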