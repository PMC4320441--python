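# Default stopword list: English conjunctions, prepositions and articles.
# One token per line; lines starting with '#' are ignored.
a
an
the
and
or
but
nor
so
yet
for
although
because
since
unless
until
while
whereas
whether
if
than
that
though
when
whenever
where
wherever
once
as
of
in
to
on
at
by
with
from
into
onto
over
under
between
among
through
during
before
after
above
below
up
down
off
out
about
against
along
around
behind
beneath
beside
besides
beyond
near
toward
towards
upon
within
without
via
per
across
amid
despite
except
inside
outside
past
regarding
concerning
like
unto
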