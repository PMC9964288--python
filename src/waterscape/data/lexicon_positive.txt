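beautiful
wonderful
bright
fresh
sweet
quiet
peaceful
happy
comfortable
pleasant
charming
spectacular
colorful
tranquil
lovely
serene
delightful
refreshing
scenic
enjoyable
calm
impressive
poetic
natural
clean
good
great
nice
relaxing
vibrant
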