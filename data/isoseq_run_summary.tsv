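read_class	total_bases	read_count
polymerase	83450000000	806926
subreads	79880000000	46605450
ccs		318019
flnc		108170
unigenes		25434
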