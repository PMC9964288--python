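park_id,recreation_time_h,recreation_number,recreation_frequency,purposes
QCP,1.5,2128,4,eating;square dancing;passage;fairs;walking
QEP,2,536,4,viewing;running;basketball;badminton;tennis;walking
YWP,1.5,336,3,viewing;chatting;walking the dog;picnicking;playing
NWMC,1,384,1,chatting;accompanying the family
YP,1.5,384,2,running;cycling;chatting;playing table tennis;walking
CP,3,2160,3,sightseeing;photography;playing;cycling;running;chatting;playing cards;walking
WP,0.5,680,1,rope skipping;dog walking;square dancing;taiji
BTP,2.5,1008,2,sightseeing;photography;playing;spending time with family
BP,1.5,728,2,running;cycling;chatting;walking the dog;rope skipping;walking;daze
LCP,1.5,784,1,viewing;photography;mountaineering;accompanying family
WRP,1.5,552,2,photography;playing;running;square dancing
UBP,0.5,2208,2,sightseeing;playing;square dance;taiji;chatting;walking
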