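# carefair dictionary snapshot v1 (lemma forms only; versioned for stable vocabularies)
ability
able
abusive
accept
access
accommodation
activity
additionally
administer
advocate
afternoon
age
aged
aggressive
agitated
agree
allocate
allocated
allow
alone
always
alzheimer
anaemia
angina
answer
anxiety
anxious
aphasia
appear
appearance
application
army
arrangement
arrive
arthritis
ask
assessment
assistance
asthma
attend
basic
be
become
bedroom
begin
behalf
believe
blister
book
breathless
bring
british
bronchitis
build
buy
call
calm
cancer
capable
care
carer
carry
case
cataract
catheter
cellulitis
change
charming
cheerful
choose
chronic
cirrhosis
clean
climb
close
clothes
coat
cognitive
come
comfortable
community
complete
complex
concern
conclude
confused
confusion
content
continence
continue
cook
copd
cope
count
cover
cream
cry
current
daily
day
decide
decision
decline
delirium
demanding
dementia
depression
deputyship
describe
despite
deteriorate
diabetes
diagnosis
difficult
direct
dirty
disable
disabled
discuss
dishevelled
disorientated
distressed
district
dizzy
do
document
dog
dress
drink
drive
dysphagia
eat
eczema
emotional
emphasize
emphysema
engaged
enjoy
environmental
epilepsy
episode
evening
excessive
exist
explain
fall
family
feed
feel
fibrillation
finance
find
fine
finish
flat
floor
follow
forget
forgetful
fracture
frail
friend
friendly
further
gardening
gaunt
gentleman
get
give
glaucoma
go
good
gout
ground
hallucination
happen
happy
have
health
hear
help
hernia
highlight
history
hold
home
hostile
hot
hypertension
hyperthyroidism
hypotension
hypothyroidism
immobile
impairment
improve
include
incontinence
independent
independently
insomnia
instal
isolated
issue
jaundice
keep
kind
kitchen
knee
know
lady
land
language
last
laugh
learn
leave
let
like
limitation
listen
live
look
lose
lost
low
make
malnutrition
manage
matter
meal
medication
meet
memory
meningitis
mental
mention
migraine
mobilise
mobility
mobilize
month
mood
morning
move
nearby
necessitate
need
neglect
neighbour
neuropathy
noise
note
number
nurse
obesity
often
old
open
osteoarthritis
osteoporosis
outdoors
overall
overweight
own
package
pain
pale
paranoid
parkinson
patient
pay
payment
people
person
personal
phone
physical
physically
plan
play
pleasant
pneumonia
poor
positive
prepare
presentable
pride
primary
provide
psoriasis
psychosis
put
radio
rash
read
receive
recent
recently
reduce
reduced
refuse
regular
reluctant
rely
remain
remember
repeatedly
report
require
resident
rest
return
review
ring
rise
risk
routine
rude
run
safe
saturday
say
schizophrenia
sciatica
scoliosis
scruffy
see
seem
sell
send
sepsis
settle
settled
sheltered
shingles
shop
shopping
shout
show
sight
sing
singing
sit
situation
sleep
smart
smile
social
society
sometimes
speak
stable
staff
stair
stairs
stand
start
state
status
stay
stop
stroke
struggle
stubborn
subjective
summary
support
supporting
supportive
swallow
take
talk
teacher
tearful
tell
term
text
theme
thin
think
thrombosis
tinnitus
tired
travel
try
turn
twice
ulcer
unable
uncooperative
understand
underweight
unexpectedly
unhappy
unkempt
unsafe
unwashed
unwell
unwise
urine
use
usually
verbally
vertigo
visit
visitor
vocal
wait
wake
walk
want
warm
wash
watch
wear
week
weekend
weight
well
wellbeing
wheelchair
white
withdrawn
without
work
worker
worried
wound
write
year
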