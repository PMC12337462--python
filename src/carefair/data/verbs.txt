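# carefair verb list v1: base-form verbs used to disambiguate "her"
# ("her" + verb => objective pronoun; "her" + noun => possessive determiner)
accept
access
agree
allow
answer
arrive
ask
attend
be
become
begin
believe
bring
build
buy
call
care
carry
change
choose
clean
climb
close
come
complete
cook
cope
count
cry
decide
describe
do
dress
drink
drive
eat
enjoy
explain
fall
feed
feel
find
finish
follow
forget
get
give
go
happen
have
hear
help
hold
keep
know
laugh
learn
leave
let
like
listen
live
look
lose
make
manage
meet
mention
mobilise
mobilize
move
need
open
pay
phone
play
prepare
put
read
receive
refuse
remember
remain
report
require
rest
return
ring
rise
run
say
see
seem
sell
send
shop
shout
show
sing
sit
sleep
smile
speak
stand
start
stay
stop
struggle
support
take
talk
tell
think
travel
try
turn
understand
use
visit
wait
wake
walk
want
wash
watch
wear
work
write
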