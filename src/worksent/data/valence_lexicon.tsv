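abandoned	-2.0
abuse	-3.2
abusive	-3.2
accomplish	1.9
accomplished	2.0
ache	-2.0
admire	2.1
adorable	2.6
adore	2.8
afraid	-2.2
aggressive	-1.9
agony	-3.3
alone	-1.4
amazing	2.8
angry	-2.7
annoyed	-1.9
annoying	-2.0
anxiety	-2.5
anxious	-2.2
appreciate	1.9
appreciated	2.0
arrogant	-2.1
ashamed	-2.2
attack	-2.1
awesome	3.1
awful	-3.1
bad	-2.5
balance	0.9
beautiful	2.9
benefit	1.5
best	3.2
better	1.9
bitter	-1.9
blessed	2.9
bliss	2.9
bonus	1.8
boring	-1.5
bother	-1.5
brave	2.1
breakdown	-2.6
brilliant	2.8
broke	-1.9
broken	-2.0
bully	-2.9
bullying	-2.9
burden	-1.9
burnout	-2.8
calm	1.6
care	1.5
careless	-1.6
celebrate	2.4
champion	2.4
chaos	-2.1
cheerful	2.5
cheer	2.0
comfort	1.8
comfortable	1.7
confident	2.2
confused	-1.3
congrats	2.5
congratulations	2.6
crap	-2.4
crash	-1.8
crazy	-1.2
cried	-2.2
crisis	-2.5
cruel	-2.9
cry	-2.2
crying	-2.3
damage	-1.9
danger	-2.3
dangerous	-2.3
dead	-2.8
death	-2.9
defeat	-1.9
delight	2.6
delighted	2.7
demoralization	-2.4
demoralized	-2.4
depressed	-3.0
depressing	-2.8
depression	-3.0
desperate	-2.3
destroy	-2.6
devastated	-3.1
die	-2.9
difficult	-1.5
dirty	-1.6
disappointed	-2.2
disappointing	-2.2
disaster	-2.9
disgusting	-2.9
dishonest	-2.3
dismal	-2.2
distress	-2.5
disturbing	-2.2
dread	-2.4
dreadful	-2.8
dream	1.8
dying	-2.9
eager	1.5
easy	1.2
efficient	1.6
elegant	1.9
embarrassed	-1.9
embarrassing	-1.9
empty	-1.2
encourage	1.8
encouraging	1.9
energetic	1.9
enjoy	2.1
enjoyable	2.2
enjoyed	2.1
enjoyment	2.2
enthusiastic	2.2
evil	-3.2
excellent	3.0
excited	2.4
exciting	2.3
exhausted	-2.1
exhausting	-2.1
exhaustion	-2.2
fail	-2.3
failed	-2.3
failure	-2.5
fair	1.4
faith	1.6
fantastic	2.9
fatigue	-1.9
fear	-2.3
fearful	-2.3
fired	-2.4
flawless	2.6
fraud	-2.8
free	1.5
fresh	1.3
friendly	2.1
frustrated	-2.3
frustrating	-2.3
frustration	-2.4
fun	2.3
funny	1.9
generous	2.2
gentle	1.8
glad	2.0
gloomy	-2.0
good	1.9
gorgeous	2.8
grateful	2.3
great	3.1
grief	-2.8
gross	-2.1
guilt	-2.2
guilty	-2.2
happiness	2.8
happy	2.7
harass	-2.9
harassment	-2.9
hard	-1.1
harm	-2.3
harmful	-2.3
hate	-2.9
hated	-2.8
hazard	-2.0
headache	-1.9
healthy	1.8
heartbroken	-3.0
hell	-2.6
helpful	1.9
helpless	-2.1
honest	2.1
hope	1.8
hopeful	2.0
hopeless	-2.6
horrible	-2.9
horrific	-3.1
hurt	-2.3
hurts	-2.3
ideal	2.1
idiot	-2.5
ill	-2.0
illness	-2.2
improve	1.7
improved	1.8
inadequate	-1.8
inefficiency	-1.7
inefficient	-1.7
insecure	-1.8
insomnia	-2.2
inspire	2.2
inspiring	2.3
insult	-2.4
interesting	1.7
irritated	-2.0
irritating	-2.0
jealous	-1.8
joy	2.8
joyful	2.8
kind	2.0
kindness	2.2
laugh	2.2
laughed	2.1
lazy	-1.5
lonely	-2.1
lose	-1.7
loser	-2.4
losing	-1.8
loss	-1.9
lost	-1.6
lousy	-2.2
love	3.2
loved	2.9
lovely	2.8
loving	2.7
lucky	2.4
mad	-2.2
marvelous	2.7
mean	-1.7
mess	-1.6
miserable	-2.8
misery	-2.9
miss	-1.2
missed	-1.3
mistake	-1.7
motivated	2.0
nasty	-2.5
nervous	-1.9
nice	1.8
nightmare	-2.8
offend	-2.1
optimistic	2.1
outstanding	2.9
overload	-1.9
overwhelmed	-2.0
overworked	-2.2
pain	-2.5
painful	-2.5
panic	-2.6
passion	2.2
passionate	2.3
pathetic	-2.4
peace	2.2
peaceful	2.3
perfect	2.9
pleasant	2.2
pleased	2.1
pleasure	2.5
poor	-1.9
positive	1.9
pressure	-1.4
problem	-1.6
problematic	-1.8
productive	1.9
progress	1.6
promotion	2.0
proud	2.2
quit	-1.4
reassuring	1.8
rejected	-2.2
relaxed	1.9
relief	1.8
relieved	1.9
resent	-2.1
respect	2.0
rude	-2.2
ruin	-2.4
sad	-2.4
sadness	-2.5
safe	1.6
satisfaction	2.1
satisfied	2.0
scared	-2.3
scary	-2.2
shame	-2.2
shocking	-2.0
sick	-2.1
smart	1.9
smile	2.2
sorrow	-2.6
sorry	-1.1
strain	-1.8
strength	1.8
stress	-2.2
stressed	-2.3
stressful	-2.5
strong	1.9
struggle	-2.0
struggling	-2.1
stupid	-2.3
succeed	2.2
success	2.6
successful	2.6
suck	-2.3
sucks	-2.3
suffer	-2.6
suffering	-2.6
suicide	-3.3
super	2.1
support	1.7
supportive	2.0
sweet	2.1
terrible	-2.9
terrific	2.7
terror	-3.0
thank	1.8
thankful	2.3
thanks	1.9
threat	-2.4
thrilled	2.7
tired	-1.6
tiring	-1.7
torture	-3.1
toxic	-2.6
tragedy	-3.0
trauma	-2.9
trouble	-1.9
trust	1.9
ugly	-2.3
unfair	-2.2
unhappy	-2.4
unlucky	-1.9
unsafe	-2.1
upset	-2.2
useless	-2.2
victory	2.5
vibrant	2.1
violence	-3.0
warm	1.7
weak	-1.5
wealth	1.8
welcome	1.9
well	1.3
win	2.4
winner	2.5
winning	2.3
wonderful	2.9
worn	-1.3
worried	-2.0
worry	-2.1
worse	-2.6
worst	-3.2
worthless	-2.6
wow	2.3
wrong	-1.8
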