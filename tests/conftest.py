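"""Shared fixtures: substitution matrices and the synthetic reference suite."""

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

import hoxscan as hs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Seed of the synthetic reference suite used across the evaluation tests.
REFERENCE_SEED = 2024


@pytest.fixture(scope="session")
def identity_matrix() -> hs.SubstitutionMatrix:
    return hs.SubstitutionMatrix.identity()


@pytest.fixture(scope="session")
def blosum62() -> hs.SubstitutionMatrix:
    return hs.SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def default_family() -> hs.FamilySet:
    """The default 6-group family set: 20 members/group at substitution
    rate 0.15 plus 100 random decoys."""
    return hs.make_family_set(hs.default_family_spec(seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def reference_pipeline(default_family) -> SimpleNamespace:
    """Profiles, score table and labelled data for the default family set."""
    fam = default_family
    profiles = [hs.build_profile(aln, group=g) for g, aln in fam.alignments.items()]
    table = hs.score_table(profiles, fam.records)
    data = hs.LabelledScores(table=table, labels=fam.labels)
    priors = hs.make_priors(data.classes, ctl_prior=0.9)
    return SimpleNamespace(
        fam=fam, profiles=profiles, table=table, data=data, priors=priors
    )
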