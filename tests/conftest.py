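import numpy as np
import pytest

from conceptrank.corpus_io import AnnotatedSentence, ConceptAnnotation, Corpus, SystemRun
from conceptrank.features import FeatureSpace, Instance, Vocabulary, build_training_set
from conceptrank.rankers import RankerConfig, train
from conceptrank.synthetic import planted_utility_instances, preset_suite


def make_planted_instances(
    n_inst: int, n_sys: int, dim: int, seed: int, w_star: np.ndarray | None = None
) -> tuple[list[Instance], np.ndarray]:
    """Instances whose relevance is the dense rank of a planted linear utility."""
    return planted_utility_instances(n_inst, n_sys, dim, seed, w_star=w_star)


@pytest.fixture(scope="session")
def suite0():
    return preset_suite(0)


@pytest.fixture(scope="session")
def trained_suite0(suite0):
    """Feature space, training instances and a trained hinge ranker on suite 0."""
    vocab = Vocabulary.from_texts(s.text for s in suite0.gold)
    space = FeatureSpace(vocab=vocab)
    instances = build_training_set(suite0.gold, list(suite0.runs.values()), space)
    model = train(
        RankerConfig(kind="hinge_svm", seed=0),
        instances,
        dim=space.dim,
        systems=list(space.systems),
    )
    return space, instances, model


@pytest.fixture
def tiny_gold():
    """Three-sentence, two-document gold corpus with known annotations."""
    C = ConceptAnnotation
    return Corpus(
        [
            AnnotatedSentence(
                "d1", 0, "headache and neck stiffness",
                concepts=(C("C0018681", "T184"), C("C0151315", "T184"), C("C0560048", "T033")),
                term_lengths=(1, 2, 3),
            ),
            AnnotatedSentence("d1", 1, "no complaints", concepts=(), term_lengths=()),
            AnnotatedSentence(
                "d2", 0, "neck pain",
                concepts=(C("C0007859", "T184"),),
                term_lengths=(2,),
            ),
        ]
    )


@pytest.fixture
def tiny_runs(tiny_gold):
    C = ConceptAnnotation
    perfect = SystemRun("M1", {s.key: s.concept_set for s in tiny_gold})
    noisy = SystemRun(
        "M2",
        {
            ("d1", 0): frozenset({C("C0018681", "T184"), C("C9999999", "T047")}),
            ("d1", 1): frozenset({C("C8888888", "T046")}),
            ("d2", 0): frozenset(),
        },
    )
    return [perfect, noisy]
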