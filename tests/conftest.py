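import pytest

from pbpkddi.ddi import run_ddi_study
from pbpkddi.params import default_physiology, load_drug_parameters
from pbpkddi.verification import verify_all

BUNDLED = ["zanubrutinib", "acalabrutinib", "voriconazole", "fluconazole", "itraconazole"]

DDI_CASES = [
    ("zanubrutinib", "voriconazole", "multiple"),
    ("zanubrutinib", "fluconazole", "multiple"),
    ("zanubrutinib", "itraconazole", "multiple"),
    ("acalabrutinib", "voriconazole", "multiple"),
    ("acalabrutinib", "fluconazole", "multiple"),
    ("acalabrutinib", "itraconazole", "multiple"),
    ("zanubrutinib", "voriconazole", "single"),
    ("acalabrutinib", "voriconazole", "single"),
]


@pytest.fixture(scope="session")
def physiology():
    return default_physiology()


@pytest.fixture(scope="session")
def drugs():
    return {name: load_drug_parameters(name) for name in BUNDLED}


@pytest.fixture(scope="session")
def verification_results():
    """The five single-dose verification runs (shared across tests)."""
    return {r.compound: r for r in verify_all()}


@pytest.fixture(scope="session")
def ddi_results():
    """All published DDI scenarios, simulated once per session."""
    return {case: run_ddi_study(*case) for case in DDI_CASES}
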