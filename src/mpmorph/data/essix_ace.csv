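source_id,particle_id,area_um2,major_um,minor_um
essix_ace,8a,1225.76,62.34,35.49
essix_ace,8b,684.62,56.34,14.47
essix_ace,8c,591.34,33.39,23.75
essix_ace,8d,700.15,34.70,26.91
essix_ace,8e,5097.38,111.82,61.56
essix_ace,8f,864.91,51.22,25.70
essix_ace,8g,2116.66,65.14,46.28
essix_ace,8h,3055.08,67.22,63.06
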