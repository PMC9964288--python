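ugly
dirty
noisy
crowded
boring
smelly
moldy
broken
unpleasant
dull
messy
bad
poor
disappointing
neglected
bleak
gloomy
dusty
stinky
awful
barren
rundown
unsafe
littered
harsh
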