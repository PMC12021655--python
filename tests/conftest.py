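import hypothesis
import pytest

from dualinf.backend import DiseaseEntry, KnowledgeBase, MockClinicianBackend
from dualinf.dataset import SynthesisConfig, default_knowledge_base, generate_cases
from dualinf.types import DualInfConfig, Specialty

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return default_knowledge_base()


@pytest.fixture(scope="session")
def tiny_kb() -> KnowledgeBase:
    """Three respiratory diseases with one deliberately shared finding."""
    return KnowledgeBase(
        {
            "spontaneous pneumothorax": DiseaseEntry(
                Specialty.RESPIRATORY,
                [
                    "sudden onset of one sided pleuritic chest pain",
                    "absent breath sounds on the affected side",
                    "hyperresonance to percussion on the affected side",
                    "acute breathlessness in a tall thin young smoker",
                ],
            ),
            "hemothorax": DiseaseEntry(
                Specialty.RESPIRATORY,
                [
                    "one sided chest pain after blunt trauma",
                    "dullness to percussion over the lower chest",
                    "absent breath sounds on the affected side",
                    "falling hematocrit after chest injury",
                ],
            ),
            "community acquired pneumonia": DiseaseEntry(
                Specialty.RESPIRATORY,
                [
                    "productive cough with rusty sputum",
                    "fever with shaking chills",
                    "pleuritic chest pain on deep inspiration",
                    "lobar consolidation on the chest radiograph",
                ],
            ),
        }
    )


@pytest.fixture
def zero_backend(kb) -> MockClinicianBackend:
    return MockClinicianBackend(kb)


@pytest.fixture
def config() -> DualInfConfig:
    return DualInfConfig(seed=0)


def make_cases(kb, n, seed, **kwargs):
    return generate_cases(kb, SynthesisConfig(n_cases=n, seed=seed, **kwargs))


@pytest.fixture
def cases20(kb):
    return make_cases(kb, 20, seed=101)
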