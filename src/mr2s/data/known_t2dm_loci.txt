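rs9939609
rs7498665
rs7138803
rs10938397
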