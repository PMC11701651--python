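"""Exception hierarchy.

Every error raised by the library derives from :class:`OntoexprError`, so
callers (and the CLI) can distinguish validation failures from bugs.
"""


class OntoexprError(Exception):
    """Base class for all ontoexpr errors."""


# --- ontology ---------------------------------------------------------------

class MalformedStanza(OntoexprError):
    """An OBO [Term] stanza is missing its id."""


class DanglingParent(OntoexprError):
    """A term references a parent that is not defined in the ontology."""


class CycleDetected(OntoexprError):
    """The is_a/part_of edge set contains a cycle."""


class UnknownTerm(OntoexprError):
    """A term id is not present in the ontology / vocabulary."""


class EmptyOntology(OntoexprError):
    """Taxon filtering removed every term."""


# --- conditions -------------------------------------------------------------

class TermNotInSpecies(OntoexprError):
    """A term fails the taxon constraints for the requested species."""


class NoSpeciesOrExperiment(OntoexprError):
    """An annotation query must anchor on a species or an experiment."""


class GraphSizeExceeded(OntoexprError):
    """Inferred-condition count exceeded the configured cap."""


# --- calls ------------------------------------------------------------------

class AllRegionsDubious(OntoexprError):
    """The stringent intergenic selection would return an empty set."""


class TooFewRegions(OntoexprError):
    """Fewer intergenic regions than the minimum required."""


class GeneNotDetectable(OntoexprError):
    """The gene is not in the sample's detectable set."""


class EmptyReference(OntoexprError):
    """The reference intergenic set is empty or too small."""


class UnknownBarcode(OntoexprError):
    """A clustered barcode does not exist in the count matrix."""


class EmptyCluster(OntoexprError):
    """An annotated cluster has no member barcodes."""


class EmptyList(OntoexprError):
    """A p-value list to combine is empty."""


class OutOfRange(OntoexprError):
    """A numeric argument violates its documented range."""


class NoData(OntoexprError):
    """No sample contributes data to the requested gene/condition."""


# --- scores -----------------------------------------------------------------

class EmptySample(OntoexprError):
    """A sample has no detectable gene to rank."""


class UnknownGene(OntoexprError):
    """The gene has no expression call."""


# --- enrichment -------------------------------------------------------------

class InvalidCounts(OntoexprError):
    """Hypergeometric counts are inconsistent."""


class EmptyForeground(OntoexprError):
    """The foreground gene list is empty (after background intersection)."""


class ForegroundNotInBackground(OntoexprError):
    """Strict mode: foreground genes missing from the background."""


# --- io ---------------------------------------------------------------------

class SchemaMismatch(OntoexprError):
    """A TSV file does not match the expected column schema."""


class ValidationError(OntoexprError):
    """Aggregated referential-integrity failures for a dataset bundle.

    Carries the full list of issues so that all problems are reported at
    once rather than first-failure.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "bundle validation failed with %d issue(s):\n%s"
            % (len(self.issues), "\n".join("  - " + i for i in self.issues))
        )


# --- synth ------------------------------------------------------------------

class InvalidConfig(OntoexprError):
    """A synthetic-data configuration violates its invariants."""


class KeyMismatch(OntoexprError):
    """Calls and ground truth do not refer to the same genes/conditions."""
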