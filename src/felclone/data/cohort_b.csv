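mutation,count,n_total
MED12:c.131G>T,13,176
MED12:c.131G>A,37,176
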