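import pytest

from medikb.fixtures import FixtureSpec, generate
from medikb.terminology import ConceptRecord, MedConcept, RxGraph


@pytest.fixture(scope="session")
def mini_lexicon():
    """Hand-built lexicon with overlapping names and mixed semantic types."""
    records = [
        ConceptRecord(
            cui="C0000001",
            preferred_name="hypertension",
            synonyms=("high blood pressure",),
            semantic_types=frozenset({"Disease or Syndrome"}),
        ),
        ConceptRecord(
            cui="C0000002",
            preferred_name="diabetes",
            synonyms=("diabetes mellitus",),
            semantic_types=frozenset({"Disease or Syndrome"}),
        ),
        ConceptRecord(
            cui="C0000003",
            preferred_name="cancer",
            semantic_types=frozenset({"Neoplastic Process"}),
        ),
        ConceptRecord(
            cui="C0000004",
            preferred_name="breast cancer",
            semantic_types=frozenset({"Neoplastic Process"}),
        ),
        ConceptRecord(
            cui="C0000005",
            preferred_name="potassium",
            semantic_types=frozenset({"Pharmacologic Substance"}),
        ),
    ]
    return {r.cui: r for r in records}


@pytest.fixture(scope="session")
def mini_rxgraph():
    """acetaminophen + codeine world: ingredients, a brand, a combo generic,
    a combo product without a generic, and a non-prescribable drug."""
    g = RxGraph()
    g.add(MedConcept(rxcui="161", name="acetaminophen", term_type="INGREDIENT"))
    g.add(MedConcept(rxcui="2670", name="codeine", term_type="INGREDIENT"))
    g.add(MedConcept(rxcui="29046", name="lisinopril", term_type="INGREDIENT",
                     synonyms=("prinivil generic",)))
    g.add(MedConcept(rxcui="7052", name="morphine", term_type="INGREDIENT"))
    g.add(
        MedConcept(rxcui="202433", name="Tylenol", term_type="BRAND"),
        ingredients=["161"],
    )
    g.add(MedConcept(rxcui="214182", name="acetaminophen / codeine",
                     term_type="MULTI_INGREDIENT"))
    g.add(
        MedConcept(rxcui="993781", name="Tylenol with codeine", term_type="CLINICAL_DRUG"),
        ingredients=["214182"],
    )
    g.add(
        MedConcept(rxcui="30236", name="morphine sulfate", term_type="CLINICAL_DRUG"),
        ingredients=["7052"],
    )
    # combo with no combined generic: splits into components
    g.add(
        MedConcept(rxcui="999001", name="acetaminophen-morphine blend",
                   term_type="CLINICAL_DRUG"),
        ingredients=["161", "7052"],
    )
    g.add(MedConcept(rxcui="999002", name="oldrug", term_type="INGREDIENT",
                     prescribable=False))
    g.validate()
    return g


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free synthetic universe."""
    return generate(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Universe with independent per-resource decoy noise."""
    return generate(FixtureSpec(seed=7, noise_rate=0.25))
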