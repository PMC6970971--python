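# Gold-standard multiword-expression inventory: one phrase per line,
# optional tab-separated tag (idiom | compound). Idioms containing food or
# activity words are the ones whose mentions must be masked from caloric
# counting; compounds are genuine multiword food/activity names.
piece of cake	idiom
apple of my eye	idiom
smart cookie	idiom
bring home the bacon	idiom
crying over spilled milk	idiom
cup of tea	idiom
big cheese	idiom
couch potato	idiom
cool as a cucumber	idiom
spill the beans	idiom
bad egg	idiom
good egg	idiom
hard nut to crack	idiom
tough cookie	idiom
bread and butter	idiom
butter someone up	idiom
cream of the crop	idiom
icing on the cake	idiom
have bigger fish to fry	idiom
sell like hot cakes	idiom
take with a grain of salt	idiom
walking on eggshells	idiom
egg on my face	idiom
full of beans	idiom
gravy train	idiom
cherry on top	idiom
go bananas	idiom
top banana	idiom
second banana	idiom
carrot and stick	idiom
two peas in a pod	idiom
pie in the sky	idiom
easy as pie	idiom
humble pie	idiom
finger in every pie	idiom
hot potato	idiom
small potatoes	idiom
bun in the oven	idiom
bigger fish to fry	idiom
packed like sardines	idiom
butter fingers	idiom
milk it for all its worth	idiom
cry over spilled milk	idiom
land of milk and honey	idiom
bite the bullet	idiom
break the ice	idiom
chew the fat	idiom
food for thought	idiom
eat humble pie	idiom
have your cake and eat it	idiom
that takes the cake	idiom
flat as a pancake	idiom
nutty as a fruitcake	idiom
salt of the earth	idiom
worth your salt	idiom
sugar coat it	idiom
sour grapes	idiom
run out of steam	idiom
jump the gun	idiom
hit the ground running	idiom
run in the family	idiom
run of the mill	idiom
sweet potato	compound
sweet potatoes	compound
french fries	compound
french toast	compound
orange juice	compound
apple juice	compound
ice cream	compound
hot dog	compound
hot chocolate	compound
peanut butter	compound
chicken masala	compound
penne arrabiata	compound
butter chicken	compound
green tea	compound
black coffee	compound
iced coffee	compound
fried rice	compound
fried chicken	compound
mashed potatoes	compound
scrambled eggs	compound
spring rolls	compound
chicken wings	compound
cheese burger	compound
veggie burger	compound
vegan burger	compound
apple pie	compound
carrot cake	compound
chocolate cake	compound
cheese cake	compound
fruit salad	compound
caesar salad	compound
club sandwich	compound
grilled cheese	compound
maple syrup	compound
ice skating	compound
rock climbing	compound
weight lifting	compound
horseback riding	compound
cross country skiing	compound
mountain biking	compound
table tennis	compound
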