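# Keyword fallback for the juice category (one canonical name per line).
juice
smoothie
lemonade
cider
nectar
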