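import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wolfram_gp import DomainTable

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


TOY_REGISTRY = """\
patient_id\tsex\tallele1\tallele2\tonset_dm\tonset_oa\tonset_di\tonset_hl
P1\tfemale\tp.Arg558Cys\tp.Trp613*\t5\t11\t\t14
P2\tmale\tp.Arg558Cys\t\t6\t\t\t
P3\tmale\tp.Val412Serfs*29\tp.Val412Serfs*29\tchildhood\t9\t\t
P4\tfemale\t\tp.Phe883del\t4\t\t\t
P5\tmale\tp.Gly674Arg\tp.Phe883del\t7.5\t\t12\t
P6\tfemale\tp.Trp613*\tp.Gln667Pro\t4\t10\t\t
"""


@pytest.fixture
def toy_registry_path(tmp_path):
    """Six-patient fixture: two rows lack an allele, one lacks a numeric DM onset."""
    path = tmp_path / "toy_registry.tsv"
    path.write_text(TOY_REGISTRY)
    return path


@pytest.fixture
def small_domains():
    return DomainTable(
        protein_id="TESTPROT",
        ranges=((313, 333), (402, 422), (600, 650)),
        provenance="hand-written test table",
    )


@pytest.fixture
def small_domains_path(tmp_path, small_domains):
    from wolfram_gp import write_domain_table

    path = tmp_path / "domains.tsv"
    write_domain_table(small_domains, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
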