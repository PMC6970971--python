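# Keyword fallback for the vegetable category (one canonical name per line).
# Membership is an approximation used when the lexicon table carries no
# category column.
asparagus
avocado
bean
beet
broccoli
cabbage
carrot
cauliflower
celery
chickpea
corn
cucumber
eggplant
garlic
kale
lentil
lettuce
mushroom
onion
pea
pepper
potato
pumpkin
radish
spinach
squash
tomato
turnip
veggie
vegetable
yam
zucchini
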