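31def7c04811470c749ed94443d0146991b14ea855d497d8007a9e8f502ce456
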