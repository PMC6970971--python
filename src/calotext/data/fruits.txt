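# Keyword fallback for the fruit category (one canonical name per line).
apple
apricot
banana
blackberry
blueberry
cantaloupe
cherry
cranberry
date
fig
fruit
grape
grapefruit
kiwi
lemon
lime
mango
melon
nectarine
orange
papaya
peach
pear
pineapple
plum
pomegranate
raspberry
strawberry
watermelon
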