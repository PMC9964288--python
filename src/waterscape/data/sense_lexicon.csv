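sense,term
vision,beautiful
vision,bright
vision,colorful
vision,scenic
vision,green
vision,golden
vision,spectacular
vision,view
smell,fragrant
smell,fragrance
smell,aroma
smell,scent
smell,moldy
smell,smelly
hearing,quiet
hearing,silent
hearing,birdsong
hearing,noisy
hearing,tranquil
touch,smooth
touch,soft
touch,breeze
touch,cool
touch,warm
taste,delicious
taste,tasty
taste,sweet
taste,bitter
feeling,happy
feeling,comfortable
feeling,relaxing
feeling,pleasant
feeling,peaceful
feeling,leisurely
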