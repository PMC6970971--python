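# symbol <TAB> textual name
# Western emoticons (names follow the conventional emoticon glossary) plus a
# few food/activity-relevant emoji. Longest symbol wins on overlap.
:-)	Happy face smiley
:)	Happy face smiley
:-]	Happy face smiley
:]	Happy face smiley
:-D	Laughing
:D	Laughing
:-(	Frown sad
:(	Frown sad
:'-(	Crying
:'(	Crying
:'-)	Tears of happiness
:')	Tears of happiness
;-)	Wink
;)	Wink
:-P	Tongue sticking out
:P	Tongue sticking out
:-p	Tongue sticking out
:p	Tongue sticking out
:-O	Surprise
:O	Surprise
:-o	Surprise
:o	Surprise
:-|	Straight face
:-*	Kiss
:*	Kiss
:-/	Skeptical
:/	Skeptical
:-\	Skeptical
<3	Heart
</3	Broken heart
8-)	Smiley with glasses
B-)	Smiley with glasses
:-X	Sealed lips
:X	Sealed lips
xD	Laughing
XD	Laughing
😀	Grinning face
😂	Face with tears of joy
😊	Smiling face with smiling eyes
😍	Smiling face with heart eyes
🍕	Pizza
🍔	Hamburger
🍟	French fries
🍰	Shortcake
☕	Hot beverage
🍵	Teacup without handle
🍎	Red apple
🥦	Broccoli
🏃	Runner
🚴	Bicyclist
🏋	Weight lifter
🏊	Swimmer
⚽	Soccer ball
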