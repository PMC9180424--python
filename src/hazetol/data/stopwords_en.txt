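me
you
he
she
it
we
they
i
a
an
the
and
or
but
of
in
on
at
to
is
are
was
were
be
been
this
that
these
those
with
for
as
by
from
so
very
just
not
no
do
does
did
have
has
had
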