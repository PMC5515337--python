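# Synthetic stand-in tumor cell content per lesion for the packaged
# five-lesion worked example.
FA1: 0.60
FA2: 0.55
FA3: 0.65
BenignPT: 0.50
MalignantPT: 0.70
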