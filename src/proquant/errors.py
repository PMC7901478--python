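"""Exception hierarchy with CLI exit codes."""


class ProquantError(Exception):
    """Base class; ``exit_code`` is used by the command-line wrapper."""

    exit_code = 1


class AnnotationError(ProquantError):
    """Malformed or inconsistent GFF3 input."""

    exit_code = 3


class AlignmentError(ProquantError):
    """Unreadable or malformed SAM/BAM input."""

    exit_code = 4


class OutputError(ProquantError):
    """Output path cannot be written."""

    exit_code = 5
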