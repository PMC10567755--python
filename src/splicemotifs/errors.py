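"""Exception hierarchy.

All input/usage problems derive from :class:`SpliceMotifsError` so the CLI
can distinguish user errors (exit 1) from internal failures (exit 2).
"""


class SpliceMotifsError(Exception):
    """Base class for all errors raised by this package on bad input."""


class GenomeError(SpliceMotifsError):
    """Malformed FASTA, unknown contig, or out-of-bounds interval."""


class AnnotationError(SpliceMotifsError):
    """Malformed GTF/BED12 or inconsistent exon structure."""


class MotifError(SpliceMotifsError):
    """Bad motif catalog or non-IUPAC consensus."""


class EventTableError(SpliceMotifsError):
    """Malformed skipped-exon event table."""
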