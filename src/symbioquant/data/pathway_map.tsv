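pathway	tag
CBB	CBB
energy_storage	energy_storage
nitrogen	nitrogen
rTCA	rTCA
sulfur	sulfur_oxidation
sulfur	thiosulfate_oxidation
thiosulfate	thiosulfate_oxidation
transport	transport
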