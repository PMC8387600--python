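a
able
about
above
act
add
afraid
after
afternoon
again
against
age
ago
agree
air
all
almost
alone
along
already
also
always
am
among
an
and
animal
another
answer
any
anyone
anything
appear
apple
are
arm
around
arrive
art
as
ask
at
away
baby
back
bad
ball
bank
base
be
bear
beautiful
became
because
become
bed
been
before
began
begin
behind
being
believe
bell
belong
below
beside
best
better
between
big
bird
bit
black
blue
board
boat
body
book
both
box
boy
bread
break
bright
bring
brother
brought
brown
build
built
busy
but
buy
by
call
came
can
car
care
careful
carry
case
cat
catch
cause
center
chance
change
child
children
choose
city
class
clean
clear
close
cloth
cold
color
come
common
company
cook
cool
corner
could
count
country
course
cover
cross
cry
cut
dark
day
dear
decide
deep
did
die
different
dinner
do
doctor
does
dog
done
door
down
draw
dream
dress
drink
drive
drop
dry
during
each
ear
early
earth
easy
eat
edge
egg
eight
either
else
end
enough
even
evening
ever
every
everyone
everything
eye
face
fact
fall
family
far
farm
fast
father
fear
feed
feel
feet
fell
felt
few
field
fight
fill
find
fine
finger
finish
fire
first
fish
five
fly
follow
food
foot
for
forget
form
found
four
free
fresh
friend
from
front
full
fun
game
garden
gave
get
girl
give
glad
glass
go
gold
gone
good
got
grass
great
green
grew
ground
group
grow
guess
had
hair
half
hand
happen
happy
hard
has
hat
have
he
head
hear
heard
heart
heavy
held
hello
help
her
here
herself
high
hill
him
himself
his
hold
home
hope
horse
hot
hour
house
how
hundred
hungry
hurry
hurt
i
ice
idea
if
important
in
indeed
inside
into
is
it
its
itself
job
join
jump
just
keep
kept
kind
king
knew
know
land
large
last
late
laugh
lay
lead
learn
leave
left
leg
let
letter
life
light
like
line
list
listen
little
live
long
look
lost
lot
loud
love
low
made
make
man
many
mark
matter
may
me
mean
meant
measure
meet
men
middle
might
mile
milk
mind
mine
minute
miss
moment
money
month
moon
more
morning
most
mother
mountain
mouth
move
much
music
must
my
myself
name
near
neck
need
never
new
next
nice
night
nine
no
nor
north
nose
not
note
nothing
now
number
of
off
office
often
oh
old
on
once
one
only
open
or
order
other
our
out
outside
over
own
page
paint
pair
paper
part
party
pass
past
pay
people
person
pick
picture
piece
place
plan
plant
play
please
point
poor
post
pull
push
put
question
quick
quiet
quite
rain
ran
reach
read
ready
real
red
remember
rest
rich
ride
right
ring
river
road
rock
roll
room
round
run
sad
safe
said
same
sat
save
saw
say
school
sea
seat
second
see
seem
seen
self
sell
send
sent
set
seven
several
shall
shape
she
ship
shoe
shop
short
should
show
side
sign
simple
since
sing
sister
sit
six
size
sky
sleep
slow
small
smile
snow
so
soft
sold
some
someone
something
song
soon
sound
south
space
speak
spell
spend
spot
spring
stand
star
start
stay
step
still
stone
stop
store
story
street
strong
such
summer
sun
sure
table
take
talk
tall
teach
teacher
tell
ten
than
thank
that
the
their
them
then
there
these
they
thing
think
third
this
those
though
thought
three
through
time
to
today
together
told
too
took
top
touch
town
tree
true
try
turn
two
under
until
up
upon
us
use
very
visit
voice
wait
walk
want
warm
was
watch
water
way
we
wear
week
well
went
were
what
when
where
which
while
white
who
whole
why
wide
will
win
wind
window
wish
with
woman
women
wonder
wood
word
work
world
would
write
wrong
year
yellow
yes
yet
you
young
your
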