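term	variant_class
stop_gained	LOF
stop_lost	LOF
start_lost	LOF
frameshift_variant	LOF
splice_donor_variant	LOF
splice_acceptor_variant	LOF
missense_variant	MISSENSE
synonymous_variant	SYNONYMOUS
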