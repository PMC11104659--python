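# Fixed English stopword list, versioned with the package for reproducibility.
# Deliberately excludes every term that appears in the default context
# registry or craving lexicon (e.g. "alone", "ex", "bed", "mad").
a
about
above
after
again
against
all
also
am
an
and
any
are
aren
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
couldn
did
didn
do
does
doesn
doing
don
down
during
each
few
for
from
further
get
got
had
hadn
has
hasn
have
haven
having
he
her
here
hers
herself
him
himself
his
how
if
im
in
into
is
isn
it
its
itself
just
ll
ma
me
mightn
more
most
mustn
my
myself
needn
no
nor
not
now
of
off
on
once
only
or
other
our
ours
ourselves
out
over
own
re
really
same
shan
she
should
shouldn
so
some
such
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
too
under
until
up
ve
very
was
wasn
we
were
weren
what
when
where
which
while
who
whom
why
will
with
won
would
wouldn
you
your
yours
yourself
yourselves
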