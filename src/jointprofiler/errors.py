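"""Exception hierarchy.

``FormatError`` covers malformed input files (exit code 1 from the CLI);
``DataError`` covers internally inconsistent but well-formed inputs, e.g.
dangling contig references. Bad arguments raise plain ``ValueError``.
"""


class JointProfilerError(Exception):
    """Base class for all data-level errors raised by this package."""


class FormatError(JointProfilerError):
    """A file does not conform to its declared format."""


class DataError(JointProfilerError):
    """Inputs are well-formed but mutually inconsistent."""
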