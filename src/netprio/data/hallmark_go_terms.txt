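# Editable list of cancer-hallmark-related GO biological-process terms.
# These nine defaults cover the classic hallmark capabilities (sustained
# proliferation, evading apoptosis, angiogenesis, invasion, genome
# instability, ...); replace with your own curation as needed.
GO:0008283
GO:0006915
GO:0007049
GO:0001525
GO:0016477
GO:0007155
GO:0006281
GO:0006955
GO:0000723
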