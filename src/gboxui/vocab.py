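"""RDF vocabulary used for project and GBox serializations.

The store model names five entity kinds (Project, Collection, Item, Rule,
Statement) but prescribes no namespace IRIs, so a package-local namespace is
used.  Schema edges (rules) carry ``subject``/``verb``/``object`` (or
``value`` for a literal type tag); assertions (statements) carry
``subject``/``instanceOf`` and either ``object`` (an item) or ``value``
(a literal).
"""

from rdflib import Namespace

VOCAB = Namespace("https://gboxui.invalid/vocab#")
RESOURCE = Namespace("https://gboxui.invalid/resource/")

# node classes
PROJECT = VOCAB.Project
COLLECTION = VOCAB.Collection
ITEM = VOCAB.Item
RULE = VOCAB.Rule
STATEMENT = VOCAB.Statement
GUI_RULE = VOCAB.GuiRule

# properties
LABEL = VOCAB.label
ACCESS_KEY = VOCAB.accessKey
IN_PROJECT = VOCAB.inProject
IN_COLLECTION = VOCAB.inCollection
IDENTIFIER = VOCAB.identifier
SUBJECT = VOCAB.subject
VERB = VOCAB.verb
OBJECT = VOCAB.object
VALUE = VOCAB.value
INSTANCE_OF = VOCAB.instanceOf

# GBox instance slots
DOMAIN = VOCAB.domain
RANGE = VOCAB.range
ACTION = VOCAB.action
TRIGGER = VOCAB.trigger
ORDER = VOCAB.order

KNOWN_PREDICATES = frozenset(
    {
        LABEL,
        ACCESS_KEY,
        IN_PROJECT,
        IN_COLLECTION,
        IDENTIFIER,
        SUBJECT,
        VERB,
        OBJECT,
        VALUE,
        INSTANCE_OF,
        DOMAIN,
        RANGE,
        ACTION,
        TRIGGER,
        ORDER,
    }
)


def resource_iri(project_id: str, resource_id: str):
    """IRI for a resource scoped to its project."""
    return RESOURCE[f"{project_id}/{resource_id}"]
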