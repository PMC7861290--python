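please
call
stella
ask
her
to
bring
these
things
with
her
from
the
store
six
spoons
of
fresh
snow
peas
five
thick
slabs
of
blue
cheese
and
maybe
a
snack
for
her
brother
bob
we
also
need
a
small
plastic
snake
and
a
big
toy
frog
for
the
kids
she
can
scoop
these
things
into
three
red
bags
and
we
will
go
meet
her
wednesday
at
the
train
station
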