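import pytest
from hypothesis import HealthCheck, settings
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF

from semcms import Engine, FixtureSpec, Vocabulary, build_basic_ontology, build_min_max_fixture

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

USER = URIRef("https://semcms.dev/user/alice")
OTHER_USER = URIRef("https://semcms.dev/user/bob")
SESSION = "session-1"


class Clock:
    """Deterministic injectable UTC clock."""

    def __init__(self, start: str = "2019-08-08T09:00:00+00:00"):
        self._i = -1
        self._prefix = start[: len("2019-08-08T09:")]

    def __call__(self) -> str:
        self._i += 1
        return f"{self._prefix}{self._i // 60:02d}:{self._i % 60:02d}+00:00"


@pytest.fixture
def clock() -> Clock:
    return Clock()


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary()


def make_minmax_engine() -> Engine:
    engine = Engine()
    engine.load_ontology(build_basic_ontology(engine.vocab))
    engine.load_ontology(build_min_max_fixture(FixtureSpec(), engine.vocab))
    return engine


@pytest.fixture
def engine() -> Engine:
    return make_minmax_engine()


def make_plain_engine() -> Engine:
    """Engine with a minimal one-field 'plain' document type: no required
    fields, so every life-cycle path is open."""
    engine = Engine()
    engine.load_ontology(build_basic_ontology(engine.vocab))
    g = Graph()
    cmd = engine.vocab.cmd
    ns = "https://semcms.dev/sco/plain/"
    root_cls, field_cls = URIRef(ns + "form-class"), URIRef(ns + "field-class")
    root, fld = URIRef(ns + "form"), URIRef(ns + "field")
    g.add((root_cls, RDF.type, OWL.Class))
    g.add((field_cls, RDF.type, OWL.Class))
    g.add((root, RDF.type, root_cls))
    g.add((fld, RDF.type, field_cls))
    g.add((root, cmd("entry form template of document type"), Literal("plain")))
    g.add((fld, cmd("entry component of"), root))
    g.add((fld, cmd("has position in entry component"), Literal("1")))
    engine.load_ontology(g)
    return engine


@pytest.fixture
def plain_engine() -> Engine:
    return make_plain_engine()


@pytest.fixture
def doc(engine, clock):
    """A fresh specimen document with its min/max field components."""
    record = engine.create_document("specimen", USER, clock())
    tree = engine.compose_view(record)
    min_field = next(n for n in tree.walk() if n.info_text == "min")
    max_field = next(n for n in tree.walk() if n.info_text == "max")
    return record, min_field.component, max_field.component
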