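ain't	is not
aren't	are not
can't	cannot
can't've	cannot have
could've	could have
couldn't	could not
didn't	did not
doesn't	does not
don't	do not
hadn't	had not
hasn't	has not
haven't	have not
he'd	he would
he'll	he will
he's	he is
here's	here is
how'd	how did
how'll	how will
how's	how is
i'd	i would
i'll	i will
i'm	i am
i've	i have
isn't	is not
it'd	it would
it'll	it will
it's	it is
let's	let us
ma'am	madam
mightn't	might not
might've	might have
mustn't	must not
must've	must have
needn't	need not
o'clock	of the clock
oughtn't	ought not
shan't	shall not
she'd	she would
she'll	she will
she's	she is
should've	should have
shouldn't	should not
that'd	that would
that's	that is
there'd	there would
there's	there is
they'd	they would
they'll	they will
they're	they are
they've	they have
wasn't	was not
we'd	we would
we'll	we will
we're	we are
we've	we have
weren't	were not
what'll	what will
what're	what are
what's	what is
what've	what have
when's	when is
where'd	where did
where's	where is
who'll	who will
who's	who is
who've	who have
why's	why is
won't	will not
would've	would have
wouldn't	would not
y'all	you all
you'd	you would
you'll	you will
you're	you are
you've	you have
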