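"""Exception hierarchy shared across the package."""


class PhylotasteError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhylotasteError):
    """A required column or field is missing from an input table."""


class IntegrityError(PhylotasteError):
    """Duplicate identifiers or broken cross-references."""


class RangeError(PhylotasteError):
    """A value lies outside its documented domain (e.g. score not in 0..3)."""


class VocabularyError(PhylotasteError):
    """An unknown chemosensory quality label."""


class MappingError(PhylotasteError):
    """The use-to-category map is not total over the uses."""


class TreeError(PhylotasteError):
    """Tree parsing, ultrametricity, or grafting failures."""


class UnresolvableTaxonError(TreeError):
    """A taxon whose genus and family are both absent from the tree."""


class ModelError(PhylotasteError):
    """Degenerate designs or invalid model specifications."""


class ScenarioError(PhylotasteError):
    """Inconsistent simulation scenario settings."""
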