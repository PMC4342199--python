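gene	allele	sites
CYP2C19	*1	
CYP2C19	*2	rs4244285
CYP2C19	*3	rs4986893
CYP2C19	*4	rs28399504
CYP2C19	*5	rs56337013
CYP2C19	*6	rs72552267
CYP2C19	*7	rs72558186
CYP2C19	*8	rs41291556
CYP2C19	*17	rs12248560
CYP2C9	*1	
CYP2C9	*2	rs1799853
CYP2C9	*3	rs1057910
CYP2C9	*5	rs28371686
CYP2C9	*6	rs9332131
CYP2C9	*8	rs7900194
CYP2C9	*11	rs28371685
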