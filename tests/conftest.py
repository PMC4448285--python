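import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from kbharvest.corpus import DictionaryEntry
from kbharvest.recognition import MatchIndex, MatchIndexParams
from kbharvest.synthetic import default_hierarchy

from .helpers import make_mention, make_sentence


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture(scope="session")
def small_dictionary():
    return [
        DictionaryEntry("E_ANEMIA", "anemia", frozenset({"symptom"})),
        DictionaryEntry("E_SARCOID", "sarcoidosis", frozenset({"disease"})),
        DictionaryEntry("E_MI", "myocardial infarction", frozenset({"disease"})),
        DictionaryEntry("E_MI", "heart attack", frozenset({"disease"}), False),
        DictionaryEntry("E_ARR", "arrythmias", frozenset({"disease"})),
        DictionaryEntry("E_ASTHMA", "asthma", frozenset({"disease"})),
        DictionaryEntry("E_DICLO", "diclofenac", frozenset({"drug"})),
        DictionaryEntry("E_BELCH", "belching", frozenset({"symptom"})),
    ]


@pytest.fixture(scope="session")
def small_index(small_dictionary):
    return MatchIndex(small_dictionary, MatchIndexParams())


@pytest.fixture
def fig2a_sentence():
    """'Anemia is a common symptom of sarcoidosis' with a standard parse:
    the copular head 'symptom' governs subject, copula, determiner and the
    amod 'common'; 'of' attaches the second entity."""
    return make_sentence(
        ["Anemia", "is", "a", "common", "symptom", "of", "sarcoidosis"],
        [
            (4, 0, "nsubj"),
            (4, 1, "cop"),
            (4, 2, "det"),
            (4, 3, "amod"),
            (4, 5, "prep"),
            (5, 6, "pobj"),
        ],
        lemmas=["anemia", "be", "a", "common", "symptom", "of", "sarcoidosis"],
    )


@pytest.fixture
def fig2a_mentions():
    return (
        make_mention(0, 1, "E_ANEMIA", frozenset({"symptom"})),
        make_mention(6, 7, "E_SARCOID", frozenset({"disease"})),
    )
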