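"""Exception hierarchy shared across the package."""


class MeshIndexError(Exception):
    """Base class for all package-specific errors."""


class ThesaurusParseError(MeshIndexError, ValueError):
    """A thesaurus source row could not be parsed."""


class IntegrityError(MeshIndexError, ValueError):
    """A uniqueness or consistency constraint was violated."""


class UnknownDescriptorError(MeshIndexError, KeyError):
    """A descriptor id was not found in the thesaurus."""


class UnknownDocumentError(MeshIndexError, KeyError):
    """A document id was not found in the index label store."""
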