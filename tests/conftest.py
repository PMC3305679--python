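import pytest
from hypothesis import settings

from dfid.fixtures import FixtureSpec, _build_tree, generate_terminology
from dfid.monograph_io import Monograph
from dfid.normalizer import default_translation_rules
from dfid.terminology import (
    DFTree,
    DosageFormConcept,
    TreeNumber,
    stem_concept_name,
)

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

USAGE = "How should this medicine be used?"


def make_concept(cid, name, *numbers):
    return DosageFormConcept(
        concept_id=cid,
        name=name,
        tree_numbers=tuple(TreeNumber.parse(n) for n in numbers),
        stems=stem_concept_name(name),
    )


@pytest.fixture(scope="session")
def mini_tree() -> DFTree:
    """The fixture terminology: hierarchy backbone plus extra leaves."""
    rows = generate_terminology(FixtureSpec(seed=0, n_forms=23))
    return _build_tree(*rows)


@pytest.fixture(scope="session")
def rules():
    return default_translation_rules()


@pytest.fixture(scope="session")
def oracle_tree() -> DFTree:
    """Small 8-node tree (with one multi-parent node) for exhaustive
    brute-force comparisons."""
    return DFTree([
        make_concept("A", "Alpha", "F1"),
        make_concept("B", "Beta", "F1.1"),
        make_concept("C", "Gamma", "F1.1.1"),
        make_concept("D", "Delta", "F1.1.2"),
        make_concept("E", "Epsilon", "F1.2"),
        make_concept("F", "Zeta", "F1.2.1", "F1.1.3"),
        make_concept("G", "Eta", "F2"),
        make_concept("H", "Theta", "F2.1"),
    ])


def usage_monograph(monograph_id, title, text, brands=()):
    """Monograph with one usage section (and optional brand section)."""
    sections = {USAGE: text}
    if brands:
        sections["Brand names"] = " ".join(brands)
    return Monograph(
        monograph_id=monograph_id,
        title=title,
        sections=sections,
        brand_names=list(brands),
    )
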